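"""Domain types shared by all pipeline stages.

Allele fractions are stored as percent (0-100) throughout; conversion from
VCF-style fractions happens at ingest.  Dates carry month precision only.
Variant identity is the genomic quadruple (chrom, pos, ref, alt) when
complete, otherwise the (gene, protein-level change) pair, so that both
coordinate-bearing VCF input and protein-level tabular input can be matched.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .errors import DomainError, MalformedVariantError, ValidationError

__all__ = [
    "Consequence",
    "Tissue",
    "MetastasisTiming",
    "DetectionStatus",
    "YearMonth",
    "Variant",
    "VariantCall",
    "Specimen",
    "Treatment",
    "Case",
    "FilterConfig",
    "variant_key",
    "DEFAULT_BLACKLIST",
]


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    SPLICE = "splice"
    INFRAME = "inframe"
    OTHER = "other"


class Tissue(str, enum.Enum):
    NORMAL = "normal"
    PRIMARY = "primary"
    LIVER_MET = "liver_met"
    LUNG_MET = "lung_met"


METASTATIC_TISSUES = frozenset({Tissue.LIVER_MET, Tissue.LUNG_MET})


class MetastasisTiming(str, enum.Enum):
    SYNCHRONOUS = "synchronous"
    METACHRONOUS = "metachronous"


class DetectionStatus(str, enum.Enum):
    DETECTED = "detected"
    DETECTED_BELOW_THRESHOLD = "detected_below_threshold"
    NOT_DETECTED = "not_detected"


_YM_ISO = re.compile(r"^(\d{4})-(\d{2})$")
_YM_SHORT = re.compile(r"^(\d{1,2})/(\d{2})$")


@dataclass(frozen=True, order=True)
class YearMonth:
    """A calendar month (resection dates are printed with month precision)."""

    year: int
    month: int

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValidationError(f"month out of range: {self.month}")

    @classmethod
    def parse(cls, text: "str | YearMonth") -> "YearMonth":
        """Accept ``YYYY-MM`` or the short clinical ``MM/YY`` form."""
        if isinstance(text, YearMonth):
            return text
        s = str(text).strip()
        m = _YM_ISO.match(s)
        if m:
            return cls(int(m.group(1)), int(m.group(2)))
        m = _YM_SHORT.match(s)
        if m:
            yy = int(m.group(2))
            return cls(2000 + yy if yy < 70 else 1900 + yy, int(m.group(1)))
        raise ValidationError(f"unparseable year-month: {text!r}")

    def months_since(self, other: "YearMonth") -> int:
        """Signed difference in whole calendar months (self - other)."""
        return (self.year - other.year) * 12 + (self.month - other.month)

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"


# --------------------------------------------------------------------------- #
# Variants

_PROTEIN_CODON = re.compile(r"^p\.\(?([A-Za-z]{1,3}|\*)(\d+)")


@dataclass(frozen=True, eq=False)
class Variant:
    """An allele identity plus annotation.

    Equality and hashing are defined on :func:`variant_key`, i.e. on the
    genomic quadruple when complete and on (gene, hgvs_p) otherwise.
    """

    gene: Optional[str] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    hgvs_p: Optional[str] = None
    consequence: Consequence = Consequence.OTHER
    population_af: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos is not None and self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref is not None and self.alt is not None and self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref!r})")
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise ValidationError(
                f"population_af outside [0,1]: {self.population_af}"
            )
        if not isinstance(self.consequence, Consequence):
            object.__setattr__(
                self, "consequence", Consequence(str(self.consequence))
            )
        # must be keyable
        self.key  # noqa: B018

    @property
    def has_quadruple(self) -> bool:
        return all(x is not None for x in (self.chrom, self.pos, self.ref, self.alt))

    @property
    def key(self) -> tuple:
        return variant_key(self)

    @property
    def protein_codon(self) -> Optional[int]:
        """Codon number parsed from the protein-level change, if any."""
        if not self.hgvs_p:
            return None
        m = _PROTEIN_CODON.match(self.hgvs_p)
        return int(m.group(2)) if m else None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Variant):
            return NotImplemented
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.has_quadruple:
            loc = f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"
        else:
            loc = f"{self.gene} {self.hgvs_p}"
        return f"Variant({loc})"


def variant_key(v: Variant) -> tuple:
    """Deterministic identity key for a variant.

    The complete genomic quadruple dominates; the (gene, hgvs_p) pair is the
    fallback so that protein-level tables can be matched against each other.
    """
    if v.has_quadruple:
        return ("g", v.chrom, v.pos, v.ref, v.alt)
    if v.gene and v.hgvs_p:
        return ("p", v.gene, v.hgvs_p)
    raise MalformedVariantError(
        "variant needs a complete (chrom,pos,ref,alt) quadruple "
        "or a (gene, hgvs_p) pair"
    )


def key_to_str(key: tuple) -> str:
    """Render an identity key as a stable single-token string."""
    if key[0] == "g":
        return f"{key[1]}:{key[2]}:{key[3]}:{key[4]}"
    return f"{key[1]}|{key[2]}"


@dataclass(frozen=True)
class VariantCall:
    """A variant observed in one specimen, with allele fraction in percent."""

    variant: Variant
    specimen_id: str
    allele_fraction: float
    depth: Optional[int] = None
    alt_reads: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_fraction <= 100.0:
            raise ValidationError(
                f"allele_fraction outside [0,100]: {self.allele_fraction}"
            )
        if self.depth is not None and self.depth < 0:
            raise ValidationError(f"negative depth: {self.depth}")
        if self.alt_reads is not None and self.alt_reads < 0:
            raise ValidationError(f"negative alt_reads: {self.alt_reads}")
        if (
            self.depth is not None
            and self.alt_reads is not None
            and self.alt_reads > self.depth
        ):
            raise ValidationError(
                f"alt_reads {self.alt_reads} exceeds depth {self.depth}"
            )

    @property
    def key(self) -> tuple:
        return self.variant.key


# --------------------------------------------------------------------------- #
# Specimens / cases


@dataclass(frozen=True)
class Specimen:
    specimen_id: str
    case_id: str
    tissue: Tissue
    lesion_label: str = ""
    resection_date: Optional[YearMonth] = None
    tumour_cell_content: Optional[float] = None

    def __post_init__(self) -> None:
        if not isinstance(self.tissue, Tissue):
            object.__setattr__(self, "tissue", Tissue(str(self.tissue)))
        if self.tissue is not Tissue.NORMAL and self.resection_date is None:
            raise ValidationError(
                f"tumour specimen {self.specimen_id!r} lacks a resection date"
            )
        if self.tumour_cell_content is not None and not (
            0.0 <= self.tumour_cell_content <= 100.0
        ):
            raise ValidationError(
                f"tumour_cell_content outside [0,100]: {self.tumour_cell_content}"
            )

    @property
    def is_metastasis(self) -> bool:
        return self.tissue in METASTATIC_TISSUES


@dataclass(frozen=True)
class Treatment:
    regimen: str
    period: str = ""


@dataclass
class Case:
    """A patient: one normal, one primary and at least two metastases."""

    case_id: str
    specimens: list[Specimen] = field(default_factory=list)
    treatments: list[Treatment] = field(default_factory=list)
    attributes: dict[str, object] = field(default_factory=dict)

    def validate(self) -> None:
        for sp in self.specimens:
            if sp.case_id != self.case_id:
                raise ValidationError(
                    f"specimen {sp.specimen_id!r} carries case_id "
                    f"{sp.case_id!r}, expected {self.case_id!r}"
                )
        n_primary = sum(1 for s in self.specimens if s.tissue is Tissue.PRIMARY)
        n_normal = sum(1 for s in self.specimens if s.tissue is Tissue.NORMAL)
        if n_primary != 1:
            raise ValidationError(
                f"case {self.case_id!r}: expected exactly one primary specimen, "
                f"found {n_primary}"
            )
        if n_normal != 1:
            raise ValidationError(
                f"case {self.case_id!r}: expected exactly one normal specimen, "
                f"found {n_normal}"
            )
        if len(self.metastases) < 2:
            raise ValidationError(
                f"case {self.case_id!r}: at least two metastatic specimens "
                f"required, found {len(self.metastases)}"
            )

    @property
    def primary(self) -> Specimen:
        return next(s for s in self.specimens if s.tissue is Tissue.PRIMARY)

    @property
    def normal(self) -> Specimen:
        return next(s for s in self.specimens if s.tissue is Tissue.NORMAL)

    @property
    def tumour_specimens(self) -> list[Specimen]:
        return [s for s in self.specimens if s.tissue is not Tissue.NORMAL]

    @property
    def metastases(self) -> list[Specimen]:
        return [s for s in self.specimens if s.is_metastasis]

    def specimen(self, specimen_id: str) -> Specimen:
        for s in self.specimens:
            if s.specimen_id == specimen_id:
                return s
        raise KeyError(specimen_id)


# --------------------------------------------------------------------------- #
# Filter configuration

DEFAULT_BLACKLIST: frozenset[tuple[str, str]] = frozenset(
    {
        ("KDR", "p.Q472H"),
        ("KIT", "p.M541L"),
        ("TP53", "p.P72R"),
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the variant-filter stack.

    ``af_cutoff`` is inclusive (calls at exactly the cutoff are retained);
    ``pop_af_cutoff`` is exclusive (strictly greater is removed).  The
    blacklist names recurrent common variants at protein level.
    """

    af_cutoff: float = 10.0
    pop_af_cutoff: float = 0.05
    exclude_synonymous: bool = True
    blacklist: frozenset[tuple[str, str]] = DEFAULT_BLACKLIST
    rescue_af: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.rescue_af < self.af_cutoff <= 100.0:
            raise ValidationError(
                f"need 0 < rescue_af < af_cutoff <= 100, got "
                f"rescue_af={self.rescue_af}, af_cutoff={self.af_cutoff}"
            )
        if not 0.0 <= self.pop_af_cutoff <= 1.0:
            raise ValidationError(
                f"pop_af_cutoff outside [0,1]: {self.pop_af_cutoff}"
            )
        if not isinstance(self.blacklist, frozenset):
            object.__setattr__(
                self, "blacklist", frozenset(tuple(x) for x in self.blacklist)
            )

    def to_dict(self) -> dict:
        return {
            "af_cutoff": self.af_cutoff,
            "pop_af_cutoff": self.pop_af_cutoff,
            "exclude_synonymous": self.exclude_synonymous,
            "blacklist": sorted(f"{g}:{p}" for g, p in self.blacklist),
            "rescue_af": self.rescue_af,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterConfig":
        kwargs = dict(d)
        if "blacklist" in kwargs:
            bl = []
            for item in kwargs["blacklist"]:
                if isinstance(item, str):
                    g, p = item.split(":", 1)
                    bl.append((g, p))
                else:
                    bl.append(tuple(item))
            kwargs["blacklist"] = frozenset(bl)
        return cls(**kwargs)

    def describe(self) -> str:
        bl = ",".join(sorted(f"{g}:{p}" for g, p in self.blacklist))
        return (
            f"af_cutoff={self.af_cutoff} pop_af_cutoff={self.pop_af_cutoff} "
            f"exclude_synonymous={self.exclude_synonymous} "
            f"rescue_af={self.rescue_af} blacklist={bl}"
        )
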