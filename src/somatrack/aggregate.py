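"""Cohort-level summary tables.

All tables are plain :class:`pandas.DataFrame` objects with deterministic
row ordering; percentages are always recomputed from their numerator and
denominator and rounded to the nearest integer for reporting.
"""

from __future__ import annotations

import warnings as _warnings
from typing import Mapping, Optional, Sequence

import pandas as pd

from .casematch import (
    RAS_GENES,
    RasTrajectory,
    SomaticSet,
    classify_metastasis,
    is_ras_hotspot,
)
from .io import CohortManifest
from .model import (
    Case,
    FilterConfig,
    MetastasisTiming,
    Specimen,
    Tissue,
    VariantCall,
)
from .panel import panel_genes

__all__ = [
    "SITE_CLASSES",
    "MET_CLASSES",
    "assign_timing",
    "site_class",
    "gene_case_summary",
    "site_mixed_tally",
    "de_novo_frequency",
    "treatment_report",
    "cohort_summary",
    "pct",
]

MET_CLASSES = ["synM[HEP]", "synM[PUL]", "metM[HEP]", "metM[PUL]"]
SITE_CLASSES = ["PT-Colon", "PT-Rectum"] + MET_CLASSES


def pct(numerator: int, denominator: int) -> int:
    """Integer-rounded percentage, 0 when the denominator is zero."""
    if denominator == 0:
        return 0
    return int(round(100.0 * numerator / denominator))


def assign_timing(cohort: CohortManifest) -> dict[str, MetastasisTiming]:
    """Classify every metastatic specimen against its case's primary date."""
    timing: dict[str, MetastasisTiming] = {}
    for case in cohort.cases:
        pdate = case.primary.resection_date
        for sp in case.metastases:
            timing[sp.specimen_id] = classify_metastasis(sp, pdate)
    return timing


def met_class(specimen: Specimen, timing: MetastasisTiming) -> str:
    organ = "HEP" if specimen.tissue is Tissue.LIVER_MET else "PUL"
    prefix = "syn" if timing is MetastasisTiming.SYNCHRONOUS else "met"
    return f"{prefix}M[{organ}]"


def site_class(
    specimen: Specimen,
    case: Case,
    timing: Mapping[str, MetastasisTiming],
) -> Optional[str]:
    """Case-mixed site class of a tumour specimen.

    Primaries split by organ (colon pooled over left/right, vs rectum);
    metastases by organ and timing.  Returns None for normals or when the
    primary location attribute is missing/unknown.
    """
    if specimen.tissue is Tissue.NORMAL:
        return None
    if specimen.tissue is Tissue.PRIMARY:
        location = str(case.attributes.get("location", "")).lower()
        if location.startswith("colon"):
            return "PT-Colon"
        if location.startswith("rectum"):
            return "PT-Rectum"
        return None
    return met_class(specimen, timing[specimen.specimen_id])


def _variant_label(call: VariantCall) -> tuple[str, str]:
    v = call.variant
    gene = v.gene or (v.chrom or "?")
    label = v.hgvs_p or f"{v.chrom}:{v.pos}{v.ref}>{v.alt}"
    return gene, label


# --------------------------------------------------------------------------- #


def gene_case_summary(
    cohort: CohortManifest,
    somatic: Mapping[str, SomaticSet],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Variants recurring in >= 2 tumour specimens of a case.

    Returns the per-(case, variant) table plus per-gene cohort counts: for
    gene *g*, the number of cases with at least one qualifying variant row.
    """
    rows = []
    for case in cohort.cases:
        tumour_ids = [s.specimen_id for s in case.tumour_specimens]
        support: dict[tuple, list[str]] = {}
        rep: dict[tuple, VariantCall] = {}
        for sid in tumour_ids:
            sset = somatic.get(sid)
            if sset is None:
                continue
            for key, call in sset.calls.items():
                support.setdefault(key, []).append(sid)
                rep.setdefault(key, call)
        for key, sids in support.items():
            if len(sids) < 2:
                continue
            gene, label = _variant_label(rep[key])
            rows.append(
                {
                    "case_id": case.case_id,
                    "gene": gene,
                    "hgvs_p": label,
                    "n_specimens_present": len(sids),
                    "n_tumour_specimens": len(tumour_ids),
                    "specimens": ";".join(sorted(sids)),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "case_id",
            "gene",
            "hgvs_p",
            "n_specimens_present",
            "n_tumour_specimens",
            "specimens",
        ],
    )
    if len(df):
        df = df.sort_values(["case_id", "gene", "hgvs_p"]).reset_index(drop=True)
    counts = (
        df.groupby("gene")["case_id"].nunique().to_dict() if len(df) else {}
    )
    return df, counts


def site_mixed_tally(
    cohort: CohortManifest,
    somatic: Mapping[str, SomaticSet],
    timing: Mapping[str, MetastasisTiming],
    config: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    """Case-mixed per-site specimen counts for variants recurrent at a site.

    A (gene, variant) row is kept when some site class counts >= 2
    specimens.  KRAS/NRAS (reported via the RAS trajectory) and blacklisted
    variants are excluded.  Cases with an unknown primary location are
    excluded from the PT columns with a warning.
    """
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for case in cohort.cases:
        for sp in case.tumour_specimens:
            sclass = site_class(sp, case, timing)
            if sclass is None:
                _warnings.warn(
                    f"case {case.case_id!r}: unknown primary location; "
                    f"specimen {sp.specimen_id!r} excluded from PT columns",
                    stacklevel=2,
                )
                continue
            sset = somatic.get(sp.specimen_id)
            if sset is None:
                continue
            for call in sset.calls.values():
                gene, label = _variant_label(call)
                if gene in RAS_GENES:
                    continue
                if (gene, label) in config.blacklist:
                    continue
                per = counts.setdefault((gene, label), {c: 0 for c in SITE_CLASSES})
                per[sclass] += 1
    rows = []
    for (gene, label), per in sorted(counts.items()):
        if max(per.values(), default=0) >= 2:
            rows.append({"gene": gene, "variant": label, **per})
    return pd.DataFrame(rows, columns=["gene", "variant"] + SITE_CLASSES)


def de_novo_frequency(
    cohort: CohortManifest,
    de_novo_calls: Mapping[str, Sequence[VariantCall]],
    timing: Mapping[str, MetastasisTiming],
) -> pd.DataFrame:
    """Cases with >= 1 de-novo variant, per panel gene and metastasis class.

    Counts are case counts: a case with two lesions of one class counts
    once for that class.  The table covers all 48 panel genes, zero-filled.
    """
    cases_by_cell: dict[tuple[str, str], set[str]] = {}
    for case in cohort.cases:
        for sp in case.metastases:
            mclass = met_class(sp, timing[sp.specimen_id])
            for call in de_novo_calls.get(sp.specimen_id, ()):
                gene, _ = _variant_label(call)
                cases_by_cell.setdefault((gene, mclass), set()).add(case.case_id)
    genes = sorted(set(panel_genes()) | {g for g, _ in cases_by_cell})
    data = {
        mclass: [len(cases_by_cell.get((g, mclass), ())) for g in genes]
        for mclass in MET_CLASSES
    }
    df = pd.DataFrame({"gene": genes, **data})
    return df


def treatment_report(
    cohort: CohortManifest,
    de_novo_calls: Mapping[str, Sequence[VariantCall]],
    timing: Mapping[str, MetastasisTiming],
) -> pd.DataFrame:
    """De-novo genes in lung metastases per case, next to treatment history.

    One row per case with at least one lung metastasis.  Years post
    primary are whole years (floored) per lung-metastasis episode.
    """
    rows = []
    for case in cohort.cases:
        lung = [s for s in case.metastases if s.tissue is Tissue.LUNG_MET]
        if not lung:
            continue
        pdate = case.primary.resection_date
        classes = []
        years = []
        genes: set[str] = set()
        for sp in sorted(lung, key=lambda s: (s.resection_date, s.specimen_id)):
            t = timing[sp.specimen_id]
            label = "syn" if t is MetastasisTiming.SYNCHRONOUS else "met"
            if label not in classes:
                classes.append(label)
            yr = max(sp.resection_date.months_since(pdate), 0) // 12
            if yr not in years:
                years.append(yr)
            for call in de_novo_calls.get(sp.specimen_id, ()):
                genes.add(_variant_label(call)[0])
        rows.append(
            {
                "case_id": case.case_id,
                "timing": ",".join(classes),
                "years_post_primary": ",".join(str(y) for y in years),
                "regimens": "; ".join(t.regimen for t in case.treatments),
                "de_novo_genes": (
                    ", ".join(sorted(genes)) if genes else "no de novo mutations"
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "case_id",
            "timing",
            "years_post_primary",
            "regimens",
            "de_novo_genes",
        ],
    )


def cohort_summary(
    cohort: CohortManifest,
    trajectories: Mapping[str, RasTrajectory],
) -> dict:
    """Headline cohort counts and integer percentages."""
    n_cases = cohort.n_cases
    n_specimens = cohort.n_specimens
    mutated = [t for t in trajectories.values() if t.primary_status == "mutated"]
    wildtype_n = sum(
        1 for t in trajectories.values() if t.primary_status == "wildtype"
    )
    kras = [
        t
        for t in mutated
        if any(v.gene == "KRAS" for v in t.primary_variants)
    ]
    nras = [
        t
        for t in mutated
        if any(v.gene == "NRAS" for v in t.primary_variants)
    ]
    maintained_n = sum(1 for t in mutated if t.maintained)
    sub_thresh_cases = sum(
        1 for t in trajectories.values() if t.sub_threshold_specimens
    )
    return {
        "n_cases": n_cases,
        "n_specimens": n_specimens,
        "ras_mutated_primaries": len(mutated),
        "ras_wildtype_primaries": wildtype_n,
        "kras_mutant_primaries": len(kras),
        "nras_mutant_primaries": len(nras),
        "kras_mutant_pct": pct(len(kras), n_cases),
        "nras_mutant_pct": pct(len(nras), n_cases),
        "maintained_cases": maintained_n,
        "maintained_pct": pct(maintained_n, len(mutated)),
        "sub_threshold_cases": sub_thresh_cases,
    }
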