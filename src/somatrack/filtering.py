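"""The variant-filter stack and the FFPE DNA quality metric.

A call survives filtering when all of the following hold:

* allele fraction >= the AF cutoff (inclusive; default 10 %),
* its consequence is not synonymous (when synonymous exclusion is on),
* its population frequency is absent or <= the population cutoff
  (strictly greater than 5 % is removed by default), and
* its (gene, protein change) is not on the common-variant blacklist.

Calls with absent population frequency are retained: annotation absence must
not silently delete somatic candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError
from .model import Consequence, FilterConfig, VariantCall

__all__ = ["QCRecord", "compute_qc_value", "filter_calls", "call_passes"]

QC_VALID_BELOW = 2.0


@dataclass(frozen=True)
class QCRecord:
    """Relative qPCR quality value for one DNA sample (mean delta-Ct)."""

    specimen_id: str
    qc_value: float
    valid: bool

    def __post_init__(self) -> None:
        if self.valid != (self.qc_value < QC_VALID_BELOW):
            raise ValidationError(
                f"QCRecord inconsistent: qc_value={self.qc_value}, valid={self.valid}"
            )


def compute_qc_value(
    sample_cts: Sequence[float],
    control_cts: Sequence[float],
    specimen_id: str = "",
) -> QCRecord:
    """Mean Ct difference between a sample triplicate and a control triplicate.

    A value below 2 cycles marks the DNA as suitable for library preparation.
    """
    for name, cts in (("sample", sample_cts), ("control", control_cts)):
        if len(cts) != 3:
            raise ValidationError(
                f"{name} Ct values must be a triplicate, got {len(cts)}"
            )
        for ct in cts:
            if not (float(ct) > 0.0 and float(ct) == float(ct)):
                raise ValidationError(f"{name} Ct must be finite and > 0, got {ct}")
    qc = sum(float(x) for x in sample_cts) / 3.0 - sum(
        float(x) for x in control_cts
    ) / 3.0
    return QCRecord(specimen_id=specimen_id, qc_value=qc, valid=qc < QC_VALID_BELOW)


def call_passes(call: VariantCall, config: FilterConfig) -> bool:
    """The filter predicate for a single call."""
    v = call.variant
    if call.allele_fraction < config.af_cutoff:
        return False
    if config.exclude_synonymous and v.consequence is Consequence.SYNONYMOUS:
        return False
    if v.population_af is not None and v.population_af > config.pop_af_cutoff:
        return False
    if v.gene and v.hgvs_p and (v.gene, v.hgvs_p) in config.blacklist:
        return False
    return True


def filter_calls(
    calls: Iterable[VariantCall], config: FilterConfig
) -> list[VariantCall]:
    """Apply the filter stack; preserves input order, never mutates input."""
    return [c for c in calls if call_passes(c, config)]
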