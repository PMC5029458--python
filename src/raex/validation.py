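"""Orthogonal validation of array allelic calls by primer extension.

A single-nucleotide primer-extension (SNaPshot-style) assay yields two
allele-specific peak heights per reaction; their ratio gives a
beta-value on the same X/(X+Y) scale as the array, so the two
platforms can be compared directly per (gene, sample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def allele_fraction(height_a: float, height_b: float) -> float:
    """Shared functional form of both beta estimates: a / (a + b)."""
    if height_a < 0 or height_b < 0:
        raise ValueError("peak heights must be nonnegative")
    total = height_a + height_b
    if total == 0:
        raise ValueError("both peak heights are zero")
    return height_a / total


def snapshot_beta(height_a: float, height_b: float) -> float:
    """Beta-value from the two allele-specific extension peak heights."""
    return allele_fraction(height_a, height_b)


@dataclass(frozen=True)
class ConcordanceSummary:
    results: pd.DataFrame
    n_pairs: int
    n_concordant: int
    frac_concordant: float
    n_class_agree: int
    frac_class_agree: float


def _side_class(beta: float, t_sk: float, t_ma: float) -> str:
    dev = abs(beta - 0.5)
    if dev >= t_ma:
        return "MA"
    if dev >= t_sk:
        return "SK"
    return "BA"


def concordance(
    peaks: pd.DataFrame,
    array_calls: pd.DataFrame,
    tolerance: float = 0.1,
    t_sk: float = 0.1,
    t_ma: float = 0.2,
) -> ConcordanceSummary:
    """Compare SNaPshot betas against array-derived allelic calls.

    ``peaks``: columns assay_id, gene_id, sample_id (clone), peak_height_a,
    peak_height_b.  ``array_calls``: per (gene_id, clone_id) score and
    direction from the array pipeline.  The array beta is reconstructed
    around the heterozygous midpoint as 0.5 + signed score (positive for
    ALLELE_A).  A pair is concordant when |beta_snapshot - beta_array|
    <= tolerance; class agreement additionally compares the BA/SK/MA
    side implied by each platform's deviation from 0.5.
    """
    calls = array_calls.copy()
    sign = calls["direction"].map({"ALLELE_A": 1.0, "ALLELE_B": -1.0}).fillna(0.0)
    calls["beta_array"] = 0.5 + sign * calls["score"].astype(float)
    merged = peaks.merge(
        calls[["gene_id", "clone_id", "beta_array"]],
        left_on=["gene_id", "sample_id"],
        right_on=["gene_id", "clone_id"],
        how="inner",
    )
    if merged.empty:
        raise ValueError("no matched (gene, sample) pairs between peaks and array calls")
    merged["beta_snapshot"] = [
        snapshot_beta(a, b) for a, b in zip(merged["peak_height_a"], merged["peak_height_b"])
    ]
    merged["abs_difference"] = (merged["beta_snapshot"] - merged["beta_array"]).abs()
    merged["concordant"] = merged["abs_difference"] <= tolerance
    merged["class_snapshot"] = [_side_class(b, t_sk, t_ma) for b in merged["beta_snapshot"]]
    merged["class_array"] = [_side_class(b, t_sk, t_ma) for b in merged["beta_array"]]
    merged["class_agree"] = merged["class_snapshot"] == merged["class_array"]
    cols = [
        "assay_id",
        "gene_id",
        "sample_id",
        "beta_snapshot",
        "beta_array",
        "abs_difference",
        "concordant",
        "class_snapshot",
        "class_array",
        "class_agree",
    ]
    results = merged[[c for c in cols if c in merged.columns]]
    n = len(results)
    n_conc = int(results["concordant"].sum())
    n_agree = int(results["class_agree"].sum())
    return ConcordanceSummary(
        results=results,
        n_pairs=n,
        n_concordant=n_conc,
        frac_concordant=n_conc / n,
        n_class_agree=n_agree,
        frac_class_agree=n_agree / n,
    )
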