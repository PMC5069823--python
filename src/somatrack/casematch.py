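"""Case-matched set algebra over specimen variant sets.

Implements germline subtraction (matched-normal removal), the truncal /
shared / lesion-private partition across all tumour specimens of a case,
de-novo derivation for metastases, the synchronous-vs-metachronous timing
rule, RAS hotspot trajectory tracking with the low-frequency rescue scan,
and concordance between co-resected lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import (
    CaseMismatchError,
    DomainError,
    IncompleteCaseError,
    ValidationError,
)
from .filtering import filter_calls
from .model import (
    Case,
    DetectionStatus,
    FilterConfig,
    MetastasisTiming,
    Specimen,
    Tissue,
    Variant,
    VariantCall,
    YearMonth,
)

__all__ = [
    "SomaticSet",
    "VennPartition",
    "RasVariantTrack",
    "RasTrajectory",
    "ConcordanceRecord",
    "subtract_germline",
    "classify_metastasis",
    "partition_shared",
    "derive_de_novo",
    "track_ras",
    "compare_colocated_lesions",
    "RAS_GENES",
    "RAS_HOTSPOT_CODONS",
    "is_ras_hotspot",
]

METACHRONOUS_AFTER_MONTHS = 6

RAS_GENES = frozenset({"KRAS", "NRAS"})
RAS_HOTSPOT_CODONS = frozenset({12, 13, 59, 61, 117, 146})


@dataclass
class SomaticSet:
    """Variant calls of one specimen, keyed by variant identity."""

    specimen_id: str
    calls: dict[tuple, VariantCall] = field(default_factory=dict)

    @classmethod
    def from_calls(cls, specimen_id: str, calls: Iterable[VariantCall]) -> "SomaticSet":
        out: dict[tuple, VariantCall] = {}
        for c in calls:
            if c.key in out:
                raise ValidationError(
                    f"specimen {specimen_id!r}: duplicate variant key {c.key}"
                )
            out[c.key] = c
        return cls(specimen_id=specimen_id, calls=out)

    @property
    def keys(self) -> set[tuple]:
        return set(self.calls)

    def __len__(self) -> int:
        return len(self.calls)

    def __contains__(self, key: tuple) -> bool:
        return key in self.calls


@dataclass
class VennPartition:
    """Compartments of a case's somatic variants across its tumour specimens.

    ``truncal`` keys occur in every tumour specimen, ``private`` keys in
    exactly one, ``other_shared`` keys in at least two but not all.  The
    three compartments are disjoint and their union covers every somatic
    key of the case.
    """

    case_id: str
    truncal: set[tuple] = field(default_factory=set)
    private: dict[str, set[tuple]] = field(default_factory=dict)
    other_shared: dict[tuple, frozenset[str]] = field(default_factory=dict)

    @property
    def all_keys(self) -> set[tuple]:
        keys = set(self.truncal)
        for s in self.private.values():
            keys |= s
        keys |= set(self.other_shared)
        return keys


@dataclass
class RasVariantTrack:
    """One RAS hotspot variant followed across all tumour specimens."""

    variant: Variant
    af_by_specimen: dict[str, Optional[float]]
    status_by_specimen: dict[str, DetectionStatus]
    in_primary: bool
    maintained: bool


@dataclass
class RasTrajectory:
    case_id: str
    ras_variants: list[RasVariantTrack]
    primary_status: str  # "wildtype" | "mutated"
    maintained: bool
    sub_threshold_specimens: list[str] = field(default_factory=list)

    @property
    def primary_variants(self) -> list[Variant]:
        return [t.variant for t in self.ras_variants if t.in_primary]


@dataclass
class ConcordanceRecord:
    """Shared vs exclusive variants of two co-resected lesions."""

    case_id: str
    specimen_a: str
    specimen_b: str
    shared: set[tuple]
    exclusive_a: set[tuple]
    exclusive_b: set[tuple]

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.shared), len(self.exclusive_a), len(self.exclusive_b))


# --------------------------------------------------------------------------- #


def _check_same_case(a: Optional[Specimen], b: Optional[Specimen]) -> None:
    if a is not None and b is not None and a.case_id != b.case_id:
        raise CaseMismatchError(
            f"specimens {a.specimen_id!r} (case {a.case_id!r}) and "
            f"{b.specimen_id!r} (case {b.case_id!r}) belong to different cases"
        )


def subtract_germline(
    tumour_calls: Iterable[VariantCall],
    normal_calls: Iterable[VariantCall],
    config: FilterConfig = FilterConfig(),
    tumour_specimen: Optional[Specimen] = None,
    normal_specimen: Optional[Specimen] = None,
) -> SomaticSet:
    """Remove matched-normal variants from a tumour call set.

    Matching is by variant identity and ignores allele fraction, except for
    a low evidence floor: a normal-side call only counts as germline
    evidence at AF >= ``config.rescue_af``, so that noise-level normal
    calls cannot delete genuine somatic variants.
    """
    _check_same_case(tumour_specimen, normal_specimen)
    tumour_calls = list(tumour_calls)
    sid = (
        tumour_specimen.specimen_id
        if tumour_specimen is not None
        else (tumour_calls[0].specimen_id if tumour_calls else "")
    )
    germline_keys = {
        c.key for c in normal_calls if c.allele_fraction >= config.rescue_af
    }
    kept = [c for c in tumour_calls if c.key not in germline_keys]
    return SomaticSet.from_calls(sid, kept)


def classify_metastasis(
    specimen: Specimen, primary_date: YearMonth
) -> MetastasisTiming:
    """Timing rule: metachronous iff resected more than 6 months after the
    primary tumour (whole calendar-month arithmetic, strictly greater)."""
    if not specimen.is_metastasis:
        raise DomainError(
            f"timing classification applies to metastases only, "
            f"got {specimen.tissue.value!r} specimen {specimen.specimen_id!r}"
        )
    delta = specimen.resection_date.months_since(primary_date)
    if delta > METACHRONOUS_AFTER_MONTHS:
        return MetastasisTiming.METACHRONOUS
    return MetastasisTiming.SYNCHRONOUS


def partition_shared(
    case: Case, somatic: Mapping[str, SomaticSet]
) -> VennPartition:
    """Partition the case's somatic keys into truncal / private / other-shared."""
    tumour_ids = [s.specimen_id for s in case.tumour_specimens]
    for sid in tumour_ids:
        if sid not in somatic:
            raise IncompleteCaseError(
                f"case {case.case_id!r}: no somatic set for specimen {sid!r}"
            )
    support: dict[tuple, set[str]] = {}
    for sid in tumour_ids:
        for key in somatic[sid].keys:
            support.setdefault(key, set()).add(sid)
    n = len(tumour_ids)
    part = VennPartition(case_id=case.case_id, private={sid: set() for sid in tumour_ids})
    for key, sids in support.items():
        if len(sids) == n and n > 0:
            part.truncal.add(key)
        elif len(sids) == 1:
            part.private[next(iter(sids))].add(key)
        else:
            part.other_shared[key] = frozenset(sids)
    return part


def derive_de_novo(
    met: SomaticSet,
    primary: SomaticSet,
    met_specimen: Optional[Specimen] = None,
    primary_specimen: Optional[Specimen] = None,
    primary_rescue: Optional[SomaticSet] = None,
) -> set[tuple]:
    """Variant keys present in the metastasis but absent from the primary.

    Default mode subtracts the primary's standard-cutoff somatic set.  When
    ``primary_rescue`` is supplied (strict mode), keys present in the
    primary even at the rescue threshold are also removed.
    """
    _check_same_case(met_specimen, primary_specimen)
    excluded = primary.keys
    if primary_rescue is not None:
        excluded = excluded | primary_rescue.keys
    return met.keys - excluded


# --------------------------------------------------------------------------- #
# RAS trajectory


def is_ras_hotspot(variant: Variant) -> bool:
    """KRAS/NRAS codons 12, 13, 59, 61, 117, 146 (exons 2-4)."""
    if variant.gene not in RAS_GENES:
        return False
    codon = variant.protein_codon
    return codon is not None and codon in RAS_HOTSPOT_CODONS


def _detection(af: Optional[float], config: FilterConfig) -> DetectionStatus:
    if af is None or af < config.rescue_af:
        return DetectionStatus.NOT_DETECTED
    if af < config.af_cutoff:
        return DetectionStatus.DETECTED_BELOW_THRESHOLD
    return DetectionStatus.DETECTED


def track_ras(
    case: Case,
    raw_calls: Mapping[str, Sequence[VariantCall]],
    config: FilterConfig = FilterConfig(),
) -> RasTrajectory:
    """Follow every RAS hotspot variant of a case across all tumour lesions.

    Works on *unfiltered* calls so the rescue scan can see sub-threshold
    alleles.  ``primary_status`` is decided on the primary specimen at the
    standard cutoff.  The case-level ``maintained`` flag is true for a
    mutated case when every tumour specimen carries at least one of the
    case's tracked RAS hotspot variants at or above the rescue threshold;
    distinct alleles at one codon are tracked independently and a lesion
    carrying a different hotspot allele than the primary still counts as
    RAS-status-maintained.
    """
    try:
        primary = case.primary
    except StopIteration:
        raise ValidationError(f"case {case.case_id!r} has no primary specimen")
    tumour_ids = [s.specimen_id for s in case.tumour_specimens]

    # Collect hotspot AFs per variant per specimen (best AF wins on dupes).
    af_map: dict[Variant, dict[str, float]] = {}
    for sid in tumour_ids:
        for call in raw_calls.get(sid, ()):  # raw, pre-AF-filter
            if not is_ras_hotspot(call.variant):
                continue
            if call.allele_fraction < config.rescue_af:
                continue
            per = af_map.setdefault(call.variant, {})
            if sid not in per or call.allele_fraction > per[sid]:
                per[sid] = call.allele_fraction

    tracks: list[RasVariantTrack] = []
    for variant in sorted(af_map, key=lambda v: (v.gene or "", v.hgvs_p or "", str(v.key))):
        per = af_map[variant]
        afs = {sid: per.get(sid) for sid in tumour_ids}
        statuses = {sid: _detection(afs[sid], config) for sid in tumour_ids}
        in_primary = (
            statuses[primary.specimen_id] is DetectionStatus.DETECTED
        )
        maintained = all(
            st is not DetectionStatus.NOT_DETECTED for st in statuses.values()
        )
        tracks.append(
            RasVariantTrack(
                variant=variant,
                af_by_specimen=afs,
                status_by_specimen=statuses,
                in_primary=in_primary,
                maintained=maintained,
            )
        )

    mutated = any(t.in_primary for t in tracks)
    if mutated:
        covered = {
            sid: any(
                t.status_by_specimen[sid] is not DetectionStatus.NOT_DETECTED
                for t in tracks
            )
            for sid in tumour_ids
        }
        case_maintained = all(covered.values())
    else:
        case_maintained = False

    sub_threshold = sorted(
        {
            sid
            for t in tracks
            for sid, st in t.status_by_specimen.items()
            if st is DetectionStatus.DETECTED_BELOW_THRESHOLD
        }
    )
    return RasTrajectory(
        case_id=case.case_id,
        ras_variants=tracks if mutated or tracks else [],
        primary_status="mutated" if mutated else "wildtype",
        maintained=case_maintained,
        sub_threshold_specimens=sub_threshold,
    )


# --------------------------------------------------------------------------- #


def compare_colocated_lesions(
    case: Case, lesion_a: SomaticSet, lesion_b: SomaticSet
) -> ConcordanceRecord:
    """Concordance of two topographically separate lesions from one resection."""
    sp_a = case.specimen(lesion_a.specimen_id)
    sp_b = case.specimen(lesion_b.specimen_id)
    if sp_a.tissue != sp_b.tissue:
        raise CaseMismatchError(
            f"lesions {sp_a.specimen_id!r}/{sp_b.specimen_id!r} differ in "
            f"tissue ({sp_a.tissue.value} vs {sp_b.tissue.value})"
        )
    if sp_a.resection_date != sp_b.resection_date:
        raise CaseMismatchError(
            f"lesions {sp_a.specimen_id!r}/{sp_b.specimen_id!r} were not "
            f"resected at the same date "
            f"({sp_a.resection_date} vs {sp_b.resection_date})"
        )
    a, b = lesion_a.keys, lesion_b.keys
    return ConcordanceRecord(
        case_id=case.case_id,
        specimen_a=lesion_a.specimen_id,
        specimen_b=lesion_b.specimen_id,
        shared=a & b,
        exclusive_a=a - b,
        exclusive_b=b - a,
    )


# --------------------------------------------------------------------------- #
# Convenience: full per-case somatic-set computation used by the pipeline.


def somatic_sets_for_case(
    case: Case,
    filtered_calls: Mapping[str, Sequence[VariantCall]],
    config: FilterConfig = FilterConfig(),
) -> dict[str, SomaticSet]:
    """Germline-subtract every tumour specimen of a case.

    ``filtered_calls`` maps specimen_id to calls that already passed
    :func:`somatrack.filtering.filter_calls`; the matched normal is looked
    up from the case itself.  Specimens with no calls yield empty sets.
    """
    normal_calls = list(filtered_calls.get(case.normal.specimen_id, ()))
    out: dict[str, SomaticSet] = {}
    for sp in case.tumour_specimens:
        out[sp.specimen_id] = subtract_germline(
            filtered_calls.get(sp.specimen_id, ()),
            normal_calls,
            config=config,
            tumour_specimen=sp,
            normal_specimen=case.normal,
        )
        # from_calls may infer "" for empty input; pin the id
        out[sp.specimen_id].specimen_id = sp.specimen_id
    return out
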