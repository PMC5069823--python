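"""Loaders for the hand-curated reference cohort bundled with the package.

The reference cohort is a 14-case / 70-specimen colorectal cohort with two
call tables: the recurrent-variant presence table (variants seen in >= 2
tumour specimens of a case, nominal 50 % allele fraction where none is
recorded) and the raw RAS hotspot call table with per-lesion allele
fractions, including two sub-threshold detections.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import CohortManifest, load_manifest, read_variant_table
from .model import VariantCall


def _data_path(name: str) -> Path:
    return Path(str(resources.files("somatrack").joinpath(f"data/{name}")))


def reference_manifest() -> CohortManifest:
    """The bundled 14-case / 70-specimen cohort manifest."""
    return load_manifest(_data_path("table1_manifest.yaml"))


def reference_recurrent_calls() -> dict[str, list[VariantCall]]:
    """Per-specimen presence calls for variants recurrent within a case."""
    return group_by_specimen(read_variant_table(_data_path("table2_calls.tsv")))


def reference_ras_calls() -> dict[str, list[VariantCall]]:
    """Per-specimen raw RAS hotspot calls (pre-filter allele fractions)."""
    return group_by_specimen(read_variant_table(_data_path("table3_ras_calls.tsv")))


def group_by_specimen(calls) -> dict[str, list[VariantCall]]:
    out: dict[str, list[VariantCall]] = {}
    for c in calls:
        out.setdefault(c.specimen_id, []).append(c)
    return out
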