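"""The 48-gene amplicon cancer panel used throughout."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources


@lru_cache(maxsize=1)
def panel_genes() -> tuple[str, ...]:
    """The 48 HGNC symbols of the targeted amplicon panel, sorted."""
    text = (
        resources.files("somatrack").joinpath("data/panel_genes.txt").read_text()
    )
    genes = tuple(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )
    return genes
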