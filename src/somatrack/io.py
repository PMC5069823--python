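"""File formats: cohort manifest (YAML), variant tables (TSV), VCF, reports.

Conventions
-----------
* Coordinates are 1-based everywhere (VCF standard; the TSV dialect states
  this in its header comment).
* ``af_percent`` columns are 0-100; ``population_af`` is a 0-1 fraction.
* Reports are TSV with ``#``-prefixed header comments naming the pipeline
  version and the filter configuration they were produced under.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .errors import FormatError, MalformedVariantError, ValidationError
from .model import (
    Case,
    Consequence,
    FilterConfig,
    Specimen,
    Tissue,
    Treatment,
    Variant,
    VariantCall,
    YearMonth,
)

VARIANT_TABLE_COLUMNS = [
    "specimen_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "hgvs_p",
    "consequence",
    "af_percent",
    "population_af",
    "depth",
    "alt_reads",
]
_MANDATORY_COLUMNS = {"specimen_id", "af_percent"}


@dataclass
class CohortManifest:
    """The cohort: validated cases plus free-text provenance."""

    cases: list[Case] = field(default_factory=list)
    provenance: str = ""

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_specimens(self) -> int:
        return sum(len(c.specimens) for c in self.cases)

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for case in self.cases:
            case.validate()
            for sp in case.specimens:
                if sp.specimen_id in seen:
                    raise ValidationError(
                        f"duplicate specimen_id {sp.specimen_id!r} "
                        f"(cases {seen[sp.specimen_id]!r} and {case.case_id!r})"
                    )
                seen[sp.specimen_id] = case.case_id

    def case(self, case_id: str) -> Case:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)

    def specimen(self, specimen_id: str) -> Specimen:
        for c in self.cases:
            for s in c.specimens:
                if s.specimen_id == specimen_id:
                    return s
        raise KeyError(specimen_id)

    @property
    def specimens(self) -> list[Specimen]:
        return [s for c in self.cases for s in c.specimens]


# --------------------------------------------------------------------------- #
# Manifest


def _parse_specimen(entry: dict, case_id: str) -> Specimen:
    sid = entry.get("specimen_id")
    if not sid:
        raise ValidationError(f"specimen of case {case_id!r} lacks specimen_id")
    declared = entry.get("case_id", case_id)
    if declared != case_id:
        raise ValidationError(
            f"specimen {sid!r} references unknown case {declared!r} "
            f"(listed under case {case_id!r})"
        )
    date = entry.get("resection_date")
    return Specimen(
        specimen_id=str(sid),
        case_id=case_id,
        tissue=Tissue(entry["tissue"]),
        lesion_label=str(entry.get("lesion_label", "") or ""),
        resection_date=YearMonth.parse(date) if date is not None else None,
        tumour_cell_content=entry.get("tumour_cell_content"),
    )


def _parse_treatment(entry) -> Treatment:
    if isinstance(entry, str):
        return Treatment(regimen=entry)
    return Treatment(
        regimen=str(entry.get("regimen", "")), period=str(entry.get("period", ""))
    )


def load_manifest(path: str | Path) -> CohortManifest:
    """Load and validate a cohort manifest.

    Metastasis timing (synchronous vs metachronous) is *not* assigned here;
    that is case-matching logic computed from resection dates downstream.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise FormatError(f"manifest {path}: top level must be a mapping")
    cases = []
    for centry in doc.get("cases") or []:
        case_id = str(centry.get("case_id", ""))
        if not case_id:
            raise ValidationError(f"manifest {path}: case without case_id")
        case = Case(
            case_id=case_id,
            specimens=[
                _parse_specimen(s, case_id) for s in centry.get("specimens") or []
            ],
            treatments=[
                _parse_treatment(t) for t in centry.get("treatments") or []
            ],
            attributes=dict(centry.get("attributes") or {}),
        )
        cases.append(case)
    manifest = CohortManifest(cases=cases, provenance=str(doc.get("provenance", "")))
    manifest.validate()
    return manifest


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    doc = {
        "provenance": manifest.provenance,
        "cases": [
            {
                "case_id": c.case_id,
                "attributes": dict(c.attributes),
                "treatments": [
                    {"regimen": t.regimen, "period": t.period} for t in c.treatments
                ],
                "specimens": [
                    {
                        "specimen_id": s.specimen_id,
                        "tissue": s.tissue.value,
                        "lesion_label": s.lesion_label,
                        "resection_date": (
                            str(s.resection_date) if s.resection_date else None
                        ),
                        "tumour_cell_content": s.tumour_cell_content,
                    }
                    for s in c.specimens
                ],
            }
            for c in manifest.cases
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# --------------------------------------------------------------------------- #
# Variant tables


def _cell(row, name):
    if name not in row:
        return None
    val = row[name]
    if val is None:
        return None
    if isinstance(val, float) and math.isnan(val):
        return None
    if isinstance(val, str) and val.strip() in ("", ".", "NA"):
        return None
    return val


def read_variant_table(path: str | Path) -> list[VariantCall]:
    """Read the TSV variant-call dialect (1-based coordinates, AF in percent)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = _MANDATORY_COLUMNS - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) {sorted(missing)}"
        )
    calls: list[VariantCall] = []
    bad: list[str] = []
    for idx, row in enumerate(df.to_dict("records"), start=2):  # 1 = header line
        try:
            pos = _cell(row, "pos")
            popaf = _cell(row, "population_af")
            depth = _cell(row, "depth")
            alt_reads = _cell(row, "alt_reads")
            consequence = _cell(row, "consequence")
            variant = Variant(
                gene=_cell(row, "gene"),
                chrom=_cell(row, "chrom"),
                pos=int(pos) if pos is not None else None,
                ref=_cell(row, "ref"),
                alt=_cell(row, "alt"),
                hgvs_p=_cell(row, "hgvs_p"),
                consequence=(
                    Consequence(consequence) if consequence else Consequence.OTHER
                ),
                population_af=float(popaf) if popaf is not None else None,
            )
            af = _cell(row, "af_percent")
            if af is None:
                raise ValidationError("missing af_percent")
            calls.append(
                VariantCall(
                    variant=variant,
                    specimen_id=str(row["specimen_id"]),
                    allele_fraction=float(af),
                    depth=int(float(depth)) if depth is not None else None,
                    alt_reads=int(float(alt_reads)) if alt_reads is not None else None,
                )
            )
        except (ValidationError, MalformedVariantError, ValueError) as exc:
            bad.append(f"row {idx}: {exc}")
    if bad:
        raise FormatError(f"{path}: {len(bad)} invalid row(s): " + "; ".join(bad))
    return calls


def write_variant_table(calls: Iterable[VariantCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        v = c.variant
        rows.append(
            {
                "specimen_id": c.specimen_id,
                "gene": v.gene,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "hgvs_p": v.hgvs_p,
                "consequence": v.consequence.value,
                "af_percent": c.allele_fraction,
                "population_af": v.population_af,
                "depth": c.depth,
                "alt_reads": c.alt_reads,
            }
        )
    df = pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# somatrack variant table; coordinates 1-based; af_percent 0-100\n")
        df.to_csv(fh, sep="\t", index=False)


# --------------------------------------------------------------------------- #
# VCF


class VcfReadResult(list):
    """List of :class:`VariantCall` plus per-file read metadata."""

    def __init__(self, calls=(), n_records=0, n_skipped=0, warnings=()):
        super().__init__(calls)
        self.n_records = n_records
        self.n_skipped = n_skipped
        self.warnings = list(warnings)


def _info_get(record, key):
    try:
        val = record.INFO.get(key)
    except Exception:
        return None
    if isinstance(val, bytes):
        val = val.decode()
    return val


def read_vcf(path: str | Path, specimen_id: str) -> VcfReadResult:
    """Read a single-sample VCF into variant calls with AF in percent.

    The allele fraction comes from the per-sample ``AF`` FORMAT field when
    present, otherwise from ``AD``/``DP``.  Multi-allelic records are split
    into one call per alternate allele.  Records with no usable allele
    fraction are skipped and counted in the returned metadata.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    calls: list[VariantCall] = []
    n_records = 0
    n_skipped = 0
    warnings: list[str] = []
    for rec in vcf:
        n_records += 1
        gene = _info_get(rec, "GENE")
        hgvsp = _info_get(rec, "HGVSP")
        csq = _info_get(rec, "CSQ")
        popaf = _info_get(rec, "POPAF")
        try:
            af_arr = rec.format("AF")
        except Exception:
            af_arr = None
        try:
            ad_arr = rec.format("AD")
        except Exception:
            ad_arr = None
        try:
            dp_arr = rec.format("DP")
        except Exception:
            dp_arr = None
        for ai, alt in enumerate(rec.ALT):
            af_pct = None
            depth = None
            alt_reads = None
            if dp_arr is not None:
                depth = int(dp_arr[0][0]) if dp_arr[0][0] >= 0 else None
            if ad_arr is not None and len(ad_arr[0]) > ai + 1:
                ar = int(ad_arr[0][ai + 1])
                alt_reads = ar if ar >= 0 else None
            if af_arr is not None and len(af_arr[0]) > ai and af_arr[0][ai] >= 0:
                af_pct = round(float(af_arr[0][ai]) * 100.0, 4)
            elif alt_reads is not None and depth:
                af_pct = round(100.0 * alt_reads / depth, 4)
            if af_pct is None:
                n_skipped += 1
                warnings.append(
                    f"{path}:{rec.CHROM}:{rec.POS} alt {alt}: no usable AF/AD+DP"
                )
                continue
            variant = Variant(
                gene=str(gene) if gene else None,
                chrom=rec.CHROM,
                pos=int(rec.POS),
                ref=rec.REF,
                alt=str(alt),
                hgvs_p=str(hgvsp) if hgvsp else None,
                consequence=Consequence(str(csq)) if csq else Consequence.OTHER,
                population_af=float(popaf) if popaf is not None else None,
            )
            calls.append(
                VariantCall(
                    variant=variant,
                    specimen_id=specimen_id,
                    allele_fraction=af_pct,
                    depth=depth,
                    alt_reads=alt_reads,
                )
            )
    return VcfReadResult(calls, n_records, n_skipped, warnings)


# --------------------------------------------------------------------------- #
# Reports


def write_report(
    table: pd.DataFrame,
    path: str | Path,
    config: Optional[FilterConfig] = None,
) -> None:
    """Write a report table as TSV with a provenance header comment."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# somatrack {__version__}\n")
        if config is not None:
            fh.write(f"# filter: {config.describe()}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    return pd.read_csv(path, sep="\t", comment="#")
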