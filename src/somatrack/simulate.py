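"""Synthetic clonal-evolution cohorts with planted ground truth.

The generative model per case: truncal variants (shared by every tumour
specimen), germline polymorphisms (present in every specimen including the
matched normal at ~50 % / ~100 % allele fraction), and lesion-private
de-novo variants whose per-gene rates depend on the metastasis class.
Somatic expected allele fraction is ``purity * clonal_fraction / 2``
(heterozygous diploid, no copy-number modelling); observed fractions are
drawn from a mean-preserving Beta law whose concentration is the
``af_noise`` parameter, so low-purity lesions produce sub-threshold alleles
by construction.

The default per-gene de-novo rates are illustrative only (no biological
calibration is implied).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .errors import ValidationError
from .io import CohortManifest, write_manifest
from .model import (
    Case,
    Consequence,
    Specimen,
    Tissue,
    Treatment,
    Variant,
    VariantCall,
    YearMonth,
)
from .panel import panel_genes

__all__ = [
    "SimParams",
    "CaseTruth",
    "Truth",
    "SimResult",
    "simulate_cohort",
    "emit_files",
    "expected_filtered_fraction",
]

MET_CLASSES = ("synM[HEP]", "synM[PUL]", "metM[HEP]", "metM[PUL]")

_DEFAULT_CLASS_MIX = {
    "synM[HEP]": 0.35,
    "synM[PUL]": 0.20,
    "metM[HEP]": 0.15,
    "metM[PUL]": 0.30,
}

# Illustrative, deliberately non-biological defaults.
_DEFAULT_DE_NOVO_RATE = {
    "FBXW7": {"metM[PUL]": 0.8, "synM[PUL]": 0.3},
    "SMO": {"metM[PUL]": 0.6},
    "STK11": {"metM[PUL]": 0.6},
    "ATM": {"synM[PUL]": 0.7},
    "KIT": {"synM[PUL]": 0.5},
    "PIK3CA": {"synM[PUL]": 0.5},
    "SMAD4": {"synM[PUL]": 0.5},
    "PTEN": {"synM[HEP]": 0.5},
    "FGFR3": {"synM[HEP]": 0.4},
    "GNAQ": {"synM[HEP]": 0.4},
}

_AA = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"


@dataclass(frozen=True)
class SimParams:
    """Parameters of the cohort generator; a fixed seed gives byte-identical
    output files."""

    n_cases: int = 14
    specimens_per_case: tuple[int, int] = (4, 6)  # total, incl. normal+primary
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_MIX)
    )
    truncal_count: tuple[int, int] = (1, 3)
    germline_count: tuple[int, int] = (3, 8)
    de_novo_rate: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(r) for g, r in _DEFAULT_DE_NOVO_RATE.items()}
    )
    purity: tuple[float, float] = (0.25, 0.90)
    depth_mean: float = 5000.0
    af_noise: float = 5000.0  # Beta concentration; higher = tighter
    germline_hom_rate: float = 0.1
    ras_mut_rate: float = 9.0 / 14.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ValidationError("n_cases must be >= 0")
        for name, rng in (
            ("specimens_per_case", self.specimens_per_case),
            ("truncal_count", self.truncal_count),
            ("germline_count", self.germline_count),
        ):
            if rng[0] > rng[1]:
                raise ValidationError(f"{name} range empty: {rng}")
        if self.specimens_per_case[0] < 4:
            raise ValidationError(
                "specimens_per_case must allow >= 4 (normal + primary + 2 mets)"
            )
        total = sum(self.class_mix.get(c, 0.0) for c in MET_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class_mix probabilities sum to {total}, not 1")
        if not (
            0.05 <= self.purity[0] <= self.purity[1] <= 0.95
        ):
            raise ValidationError(f"purity range must lie within [0.05,0.95]: {self.purity}")
        if self.depth_mean <= 0 or self.af_noise <= 0:
            raise ValidationError("depth_mean and af_noise must be positive")
        if not 0.0 <= self.germline_hom_rate <= 1.0:
            raise ValidationError("germline_hom_rate outside [0,1]")
        if not 0.0 <= self.ras_mut_rate <= 1.0:
            raise ValidationError("ras_mut_rate outside [0,1]")

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "specimens_per_case": list(self.specimens_per_case),
            "class_mix": dict(self.class_mix),
            "truncal_count": list(self.truncal_count),
            "germline_count": list(self.germline_count),
            "de_novo_rate": {g: dict(r) for g, r in self.de_novo_rate.items()},
            "purity": list(self.purity),
            "depth_mean": self.depth_mean,
            "af_noise": self.af_noise,
            "germline_hom_rate": self.germline_hom_rate,
            "ras_mut_rate": self.ras_mut_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimParams":
        kwargs = dict(d)
        for key in ("specimens_per_case", "truncal_count", "germline_count", "purity"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class CaseTruth:
    case_id: str
    germline_keys: set[tuple] = field(default_factory=set)
    truncal_keys: set[tuple] = field(default_factory=set)
    private: dict[str, dict[tuple, float]] = field(default_factory=dict)
    purity: dict[str, float] = field(default_factory=dict)
    met_class: dict[str, str] = field(default_factory=dict)
    ras_status: str = "wildtype"
    ras_key: Optional[tuple] = None


@dataclass
class Truth:
    cases: dict[str, CaseTruth] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            cid: {
                "germline_keys": sorted(map(list, ct.germline_keys)),
                "truncal_keys": sorted(map(list, ct.truncal_keys)),
                "private": {
                    sid: {"|".join(map(str, k)): af for k, af in sorted(d.items())}
                    for sid, d in sorted(ct.private.items())
                },
                "purity": dict(sorted(ct.purity.items())),
                "met_class": dict(sorted(ct.met_class.items())),
                "ras_status": ct.ras_status,
                "ras_key": list(ct.ras_key) if ct.ras_key else None,
            }
            for cid, ct in sorted(self.cases.items())
        }


@dataclass
class SimResult:
    manifest: CohortManifest
    calls: dict[str, list[VariantCall]]
    truth: Truth


# --------------------------------------------------------------------------- #
# Variant fabrication

_GENES = None


def _gene_layout():
    """Deterministic fake genomic layout: one window per panel gene."""
    global _GENES
    if _GENES is None:
        layout = {}
        for i, gene in enumerate(panel_genes()):
            layout[gene] = (f"chr{(i % 22) + 1}", 1_000_000 * (i + 1))
        _GENES = layout
    return _GENES


def _draw_variant(
    rng: np.random.Generator,
    gene: str,
    used_pos: set[tuple[str, int]],
    consequence: Consequence,
    population_af: Optional[float] = None,
) -> Variant:
    chrom, base = _gene_layout()[gene]
    while True:
        offset = int(rng.integers(0, 100_000))
        pos = base + offset
        if (chrom, pos) not in used_pos:
            used_pos.add((chrom, pos))
            break
    ref = _BASES[int(rng.integers(0, 4))]
    alt = _BASES[(int(rng.integers(1, 4)) + _BASES.index(ref)) % 4]
    codon = offset // 3 + 1
    aa1 = _AA[int(rng.integers(0, 20))]
    if consequence is Consequence.NONSENSE:
        hgvs = f"p.{aa1}{codon}*"
    elif consequence is Consequence.FRAMESHIFT:
        aa2 = _AA[int(rng.integers(0, 20))]
        hgvs = f"p.{aa1}{codon}{aa2}fs*"
    elif consequence is Consequence.SYNONYMOUS:
        hgvs = f"p.{aa1}{codon}{aa1}"  # notation only; identity is genomic
    else:
        aa2 = _AA[int(rng.integers(0, 20))]
        hgvs = f"p.{aa1}{codon}{aa2}"
    return Variant(
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        hgvs_p=hgvs,
        consequence=consequence,
        population_af=population_af,
    )


def _draw_ras_variant(
    rng: np.random.Generator, used_pos: set[tuple[str, int]]
) -> Variant:
    gene = "KRAS" if rng.random() < 8.0 / 9.0 else "NRAS"
    codon = int(rng.choice([12, 13, 61]))
    chrom, base = _gene_layout()[gene]
    while True:
        pos = base + 500_000 + codon * 3 + int(rng.integers(0, 3))
        if (chrom, pos) not in used_pos:
            used_pos.add((chrom, pos))
            break
    alt_aa = _AA[int(rng.integers(0, 20))]
    ref = _BASES[int(rng.integers(0, 4))]
    alt = _BASES[(int(rng.integers(1, 4)) + _BASES.index(ref)) % 4]
    return Variant(
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        hgvs_p=f"p.{'G' if codon in (12, 13) else 'Q'}{codon}{alt_aa}",
        consequence=Consequence.MISSENSE,
    )


def _somatic_consequence(rng: np.random.Generator) -> Consequence:
    r = rng.random()
    if r < 0.80:
        return Consequence.MISSENSE
    if r < 0.90:
        return Consequence.NONSENSE
    return Consequence.FRAMESHIFT


def _observe_af(rng: np.random.Generator, mean_pct: float, k: float) -> float:
    """Mean-preserving Beta draw around ``mean_pct``, in percent."""
    m = mean_pct / 100.0
    if m >= 1.0:
        return 100.0
    if m <= 0.0:
        return 0.0
    af = float(rng.beta(m * k, (1.0 - m) * k)) * 100.0
    return round(min(max(af, 0.0), 100.0), 4)


def expected_filtered_fraction(
    mean_af_pct: float, af_noise: float, cutoff_pct: float = 10.0
) -> float:
    """Probability that an observed AF falls below the cutoff under the
    Beta noise law (the tail probability of the filter)."""
    from scipy.stats import beta as beta_dist

    m = mean_af_pct / 100.0
    if m >= 1.0:
        return 0.0
    return float(beta_dist.cdf(cutoff_pct / 100.0, m * af_noise, (1 - m) * af_noise))


def _add_months(ym: YearMonth, months: int) -> YearMonth:
    total = ym.year * 12 + (ym.month - 1) + months
    return YearMonth(total // 12, total % 12 + 1)


# --------------------------------------------------------------------------- #


def simulate_cohort(params: SimParams) -> SimResult:
    """Generate a cohort, its raw per-specimen calls, and the ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    used_pos: set[tuple[str, int]] = set()
    genes = panel_genes()
    classes = list(MET_CLASSES)
    probs = np.array([params.class_mix.get(c, 0.0) for c in classes])

    cases: list[Case] = []
    calls: dict[str, list[VariantCall]] = {}
    truth = Truth()

    for ci in range(params.n_cases):
        case_id = f"sim{ci + 1:02d}"
        ct = CaseTruth(case_id=case_id)
        n_total = int(
            rng.integers(params.specimens_per_case[0], params.specimens_per_case[1] + 1)
        )
        n_mets = n_total - 2

        # planted variants ---------------------------------------------------
        n_trunc = int(rng.integers(params.truncal_count[0], params.truncal_count[1] + 1))
        truncal = [
            _draw_variant(
                rng,
                genes[int(rng.integers(0, len(genes)))],
                used_pos,
                _somatic_consequence(rng),
            )
            for _ in range(n_trunc)
        ]
        if rng.random() < params.ras_mut_rate:
            ras = _draw_ras_variant(rng, used_pos)
            truncal.append(ras)
            ct.ras_status = "mutated"
            ct.ras_key = ras.key
        n_germ = int(
            rng.integers(params.germline_count[0], params.germline_count[1] + 1)
        )
        germline: list[tuple[Variant, float]] = []
        for _ in range(n_germ):
            v = _draw_variant(
                rng,
                genes[int(rng.integers(0, len(genes)))],
                used_pos,
                Consequence.MISSENSE
                if rng.random() > 0.15
                else Consequence.SYNONYMOUS,
            )
            hom = rng.random() < params.germline_hom_rate
            germline.append((v, 100.0 if hom else 50.0))
        ct.truncal_keys = {v.key for v in truncal}
        ct.germline_keys = {v.key for v, _ in germline}

        # specimens ----------------------------------------------------------
        pdate = YearMonth(2004 + int(rng.integers(0, 10)), int(rng.integers(1, 13)))
        specimens = [
            Specimen(f"{case_id}_N", case_id, Tissue.NORMAL),
            Specimen(
                f"{case_id}_PT",
                case_id,
                Tissue.PRIMARY,
                resection_date=pdate,
            ),
        ]
        met_specs: list[tuple[Specimen, str]] = []
        class_counts: dict[str, int] = {}
        for mi in range(n_mets):
            mclass = classes[int(rng.choice(len(classes), p=probs))]
            class_counts[mclass] = class_counts.get(mclass, 0) + 1
            tissue = Tissue.LIVER_MET if "[HEP]" in mclass else Tissue.LUNG_MET
            if mclass.startswith("syn"):
                offset = int(rng.integers(0, 7))
            else:
                offset = int(rng.integers(7, 49))
            sid = f"{case_id}_{mclass[:4]}{'HEP' if tissue is Tissue.LIVER_MET else 'PUL'}{class_counts[mclass]}"
            sp = Specimen(
                sid,
                case_id,
                tissue,
                lesion_label=f"lesion {mi + 1}",
                resection_date=_add_months(pdate, offset),
            )
            met_specs.append((sp, mclass))
            ct.met_class[sid] = mclass
        specimens.extend(sp for sp, _ in met_specs)

        # per-specimen purity + calls ---------------------------------------
        depth_of = lambda: max(int(rng.poisson(params.depth_mean)), 1)

        def emit(sid: str, variant: Variant, mean_pct: float) -> VariantCall:
            af = _observe_af(rng, mean_pct, params.af_noise)
            dp = depth_of()
            alt_reads = int(rng.binomial(dp, af / 100.0))
            return VariantCall(
                variant=variant,
                specimen_id=sid,
                allele_fraction=af,
                depth=dp,
                alt_reads=alt_reads,
            )

        # normal: germline only
        nsid = specimens[0].specimen_id
        calls[nsid] = [emit(nsid, v, af) for v, af in germline]

        tumour_entries = [(specimens[1], None)] + met_specs
        final_specimens = [specimens[0]]
        for sp, mclass in tumour_entries:
            purity = float(rng.uniform(params.purity[0], params.purity[1]))
            ct.purity[sp.specimen_id] = round(purity, 4)
            sp = Specimen(
                sp.specimen_id,
                sp.case_id,
                sp.tissue,
                lesion_label=sp.lesion_label,
                resection_date=sp.resection_date,
                tumour_cell_content=round(purity * 100.0, 1),
            )
            final_specimens.append(sp)
            sid = sp.specimen_id
            specimen_calls = [emit(sid, v, af) for v, af in germline]
            somatic_mean = purity * 1.0 / 2.0 * 100.0  # clonal, heterozygous
            specimen_calls.extend(emit(sid, v, somatic_mean) for v in truncal)
            if mclass is not None:
                priv: dict[tuple, float] = {}
                for gene in sorted(params.de_novo_rate):
                    lam = params.de_novo_rate[gene].get(mclass, 0.0)
                    if lam <= 0:
                        continue
                    for _ in range(int(rng.poisson(lam))):
                        v = _draw_variant(
                            rng, gene, used_pos, _somatic_consequence(rng)
                        )
                        priv[v.key] = somatic_mean
                        specimen_calls.append(emit(sid, v, somatic_mean))
                ct.private[sid] = priv
            calls[sid] = specimen_calls

        case = Case(
            case_id=case_id,
            specimens=final_specimens,
            treatments=[Treatment(regimen="regimen-A")]
            if rng.random() < 0.7
            else [],
            attributes={
                "location": str(
                    rng.choice(["colon left", "colon right", "rectum"])
                ),
            },
        )
        cases.append(case)
        truth.cases[case_id] = ct

    manifest = CohortManifest(
        cases=cases,
        provenance=f"synthetic cohort (seed={params.seed}, n_cases={params.n_cases})",
    )
    manifest.validate()
    return SimResult(manifest=manifest, calls=calls, truth=truth)


# --------------------------------------------------------------------------- #
# File emission


_VCF_HEADER = """##fileformat=VCFv4.2
##source=somatrack-simulate
{contigs}##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=HGVSP,Number=1,Type=String,Description="Protein-level change">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
##INFO=<ID=POPAF,Number=1,Type=Float,Description="Population allele frequency (fraction)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction (0-1)">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def _contig_order(chrom: str) -> int:
    return int(chrom.replace("chr", ""))


def write_vcf(calls: list[VariantCall], specimen_id: str, path: str | Path) -> None:
    """Write one specimen's calls as an uncompressed single-sample VCF."""
    contigs = "".join(
        f"##contig=<ID=chr{i},length=250000000>\n" for i in range(1, 23)
    )
    lines = [_VCF_HEADER.format(contigs=contigs, sample=specimen_id)]
    for c in sorted(calls, key=lambda c: (_contig_order(c.variant.chrom), c.variant.pos)):
        v = c.variant
        info = [f"GENE={v.gene}", f"HGVSP={v.hgvs_p}", f"CSQ={v.consequence.value}"]
        if v.population_af is not None:
            info.append(f"POPAF={v.population_af:.6f}")
        dp = c.depth if c.depth is not None else 0
        alt_reads = c.alt_reads if c.alt_reads is not None else 0
        ref_reads = max(dp - alt_reads, 0)
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
            f"{';'.join(info)}\tGT:AF:AD:DP\t"
            f"0/1:{c.allele_fraction / 100.0:.6f}:{ref_reads},{alt_reads}:{dp}\n"
        )
    with open(path, "w") as fh:
        fh.writelines(lines)


def emit_files(result: SimResult, directory: str | Path) -> dict[str, Path]:
    """Write manifest + one VCF per specimen + truth JSON; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    mpath = directory / "manifest.yaml"
    write_manifest(result.manifest, mpath)
    paths["manifest"] = mpath
    for case in result.manifest.cases:
        for sp in case.specimens:
            vpath = directory / f"{sp.specimen_id}.vcf"
            write_vcf(result.calls.get(sp.specimen_id, []), sp.specimen_id, vpath)
            paths[sp.specimen_id] = vpath
    tpath = directory / "truth.json"
    with open(tpath, "w") as fh:
        json.dump(result.truth.to_json(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["truth"] = tpath
    return paths
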