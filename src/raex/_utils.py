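"""Small shared helpers: reporting-precision percentages and gene-list IO."""

from __future__ import annotations

from decimal import Decimal, ROUND_FLOOR, ROUND_HALF_UP
from pathlib import Path


def percentage(count: int, total: int, decimals: int = 2, mode: str = "floor") -> float:
    """Percentage at reporting precision.

    ``mode="floor"`` truncates toward zero at the requested number of
    decimals; ``mode="half_up"`` rounds half away from zero.  Published
    AEI frequency tables truncate their two-decimal percentages (e.g.
    126/7334 is quoted as 1.71%, not 1.72%) while whole-number
    percentages are conventionally rounded (42/48 -> 88%), so both modes
    are needed.

    Returns 0.0 when ``total`` is 0 (callers warn separately).
    """
    if total == 0:
        return 0.0
    value = Decimal(count) * 100 / Decimal(total)
    quantum = Decimal(1).scaleb(-decimals)
    rounding = ROUND_FLOOR if mode == "floor" else ROUND_HALF_UP
    if mode not in ("floor", "half_up"):
        raise ValueError(f"unknown rounding mode: {mode!r}")
    return float(value.quantize(quantum, rounding=rounding))


def read_gene_list(path: str | Path) -> set[str]:
    """Read a gene-list file: one symbol per line, ``#`` starts a comment."""
    genes: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.add(line)
    return genes
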