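"""Clonal comparison of allelic expression calls.

Random allelic expression imbalance (random AEI) is the signature of a
stochastic, mitotically stable allele choice: a gene monoallelic in one
single-cell-derived clone but biallelic in a sister clone of the same
genetic background and developmental state.  When opposite alleles are
observed monoallelically in different sister clones the evidence is
direct and the gene is labelled random MA.  Genes monoallelic for the
same allele wherever detected are candidates for cis-genetic (eQTL-like)
control; genes detected in only one clone cannot be resolved.

Two genome-wide frequency estimators are provided: the clonal estimator
(random-AEI genes over expressed genes, from sister-clone discordance)
and the polyclonal estimator (clone-MA genes that average back to a
biallelic signal in a many-founder polyclonal population).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import percentage
from .stats import OverlapTestResult, hypergeom_overlap_test

log = logging.getLogger(__name__)

AEI_CATEGORIES = ("RANDOM_AEI", "RANDOM_MA", "CONSTANT_MA", "INDETERMINATE_MA", "NOT_MA")

TRANSITION_CATEGORIES = (
    "RESET",        # MA -> BA
    "RETAINED",     # MA -> MA
    "TO_SKEWED",    # MA -> SK
    "LOST",         # MA -> ND
    "DE_NOVO",      # BA/SK/ND -> MA
    "STABLE_BA",    # BA -> BA
    "OTHER",
)


@dataclass
class ClonePanel:
    """Per-clone gene calls plus sample metadata.

    ``calls``: long frame with columns gene_id, sample_id, clone_id,
    developmental_state, n_informative, score, direction,
    allelic_class, excluded_reason.  ``clones``: one row per cDNA
    sample (clone x state) with lineage information.
    """

    calls: pd.DataFrame
    clones: pd.DataFrame

    def __post_init__(self):
        required = {"gene_id", "clone_id", "developmental_state", "allelic_class", "direction"}
        missing = required - set(self.calls.columns)
        if missing:
            raise ValueError(f"panel calls missing columns: {sorted(missing)}")

    def analysis_calls(self) -> pd.DataFrame:
        """Calls with excluded genes (imprinted/protocadherin/chrX) removed."""
        if "excluded_reason" not in self.calls.columns:
            return self.calls
        return self.calls[self.calls["excluded_reason"].isna()]

    def state_calls(self, state: str) -> pd.DataFrame:
        calls = self.analysis_calls()
        return calls[calls["developmental_state"] == state]

    def clone_ids(self, state: str) -> list[str]:
        calls = self.calls[self.calls["developmental_state"] == state]
        return sorted(calls["clone_id"].unique())


def _classify_gene_group(classes: pd.Series, directions: pd.Series) -> str:
    ma = classes == "MA"
    if not ma.any():
        return "NOT_MA"
    ma_dirs = set(directions[ma]) - {"DISCORDANT", "NA"}
    if "ALLELE_A" in ma_dirs and "ALLELE_B" in ma_dirs:
        return "RANDOM_MA"
    if (classes == "BA").any():
        return "RANDOM_AEI"
    detected = classes != "ND"
    if detected.sum() >= 2:
        return "CONSTANT_MA"
    return "INDETERMINATE_MA"


def detect_random_aei(panel: ClonePanel, state: str, clone_ids: list[str] | None = None) -> pd.Series:
    """Categorize every expressed gene in a sister-clone group.

    RANDOM_MA: monoallelic for opposite alleles in different clones.
    RANDOM_AEI: MA in >= 1 clone with BA in >= 1 sister clone.
    CONSTANT_MA: MA with one consistent direction, no BA sister,
    detected in >= 2 clones.  INDETERMINATE_MA: MA in a single clone
    with no expression detected elsewhere.  NOT_MA: everything else
    expressed.  Genes ND in every clone of the group are omitted.
    """
    calls = panel.state_calls(state)
    if clone_ids is not None:
        calls = calls[calls["clone_id"].isin(clone_ids)]
    n_clones = calls["clone_id"].nunique()
    if n_clones < 2:
        raise ValueError(
            f"random AEI is undecidable with {n_clones} clone(s) in group {state!r}"
        )
    categories = {}
    for gene, grp in calls.groupby("gene_id", sort=True):
        if (grp["allelic_class"] == "ND").all():
            continue
        categories[gene] = _classify_gene_group(grp["allelic_class"], grp["direction"])
    return pd.Series(categories, name="aei_category", dtype=object)


@dataclass(frozen=True)
class FrequencySummary:
    """Genome-wide random-AEI frequency over one comparison group."""

    estimator: str  # "clonal" or "polyclonal"
    n_expressed: int
    n_ma_any_clone: int
    n_random_aei: int
    pct_ma: float
    pct_random_aei: float
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "estimator": self.estimator,
            "n_expressed": self.n_expressed,
            "n_ma_any_clone": self.n_ma_any_clone,
            "n_random_aei": self.n_random_aei,
            "pct_ma": self.pct_ma,
            "pct_random_aei": self.pct_random_aei,
        }
        d.update(self.extra)
        return d


def summarize_frequencies(
    panel: ClonePanel, state: str, clone_ids: list[str] | None = None
) -> FrequencySummary:
    """Clonal estimator of the random-AEI frequency for one group.

    Denominator: non-excluded autosomal genes expressed (non-ND) in at
    least one clone of the group.  Numerators: genes MA in >= 1 clone,
    and genes categorized RANDOM_AEI or RANDOM_MA.  Percentages are
    reported at two decimals (truncated, matching published tables).
    """
    calls = panel.state_calls(state)
    if clone_ids is not None:
        calls = calls[calls["clone_id"].isin(clone_ids)]
    expressed = calls.loc[calls["allelic_class"] != "ND", "gene_id"].unique()
    n_expressed = len(expressed)
    if n_expressed == 0:
        log.warning("empty panel group %r: frequencies undefined, reported as 0", state)
        return FrequencySummary("clonal", 0, 0, 0, 0.0, 0.0)
    categories = detect_random_aei(panel, state, clone_ids=clone_ids)
    ma_any = calls.loc[calls["allelic_class"] == "MA", "gene_id"].unique()
    random_aei = categories[categories.isin(["RANDOM_AEI", "RANDOM_MA"])].index
    return FrequencySummary(
        estimator="clonal",
        n_expressed=n_expressed,
        n_ma_any_clone=len(ma_any),
        n_random_aei=len(random_aei),
        pct_ma=percentage(len(ma_any), n_expressed, 2, "floor"),
        pct_random_aei=percentage(len(random_aei), n_expressed, 2, "floor"),
    )


def polyclonal_estimate(
    panel: ClonePanel,
    state: str,
    polyclonal_calls: pd.DataFrame,
    clone_ids: list[str] | None = None,
) -> FrequencySummary:
    """Polyclonal estimator of the random-AEI frequency.

    A gene whose clone-level MA expression reflects a stochastic allele
    choice averages toward equal allele quantities in a many-founder
    polyclonal population; genes that stay MA (or skewed) there are
    cis-genetic candidates instead.  Numerator: clone-MA genes called
    BA in the polyclonal sample; denominator: total expressed genes of
    the clonal group.  ``extra`` carries the measurable/MA/SK splits in
    the polyclonal sample and the biallelic-in-polyclonal rate of the
    clonally identified random-AEI genes.
    """
    if polyclonal_calls is None or len(polyclonal_calls) == 0:
        raise ValueError("polyclonal sample missing")
    clonal = summarize_frequencies(panel, state, clone_ids=clone_ids)
    calls = panel.state_calls(state)
    if clone_ids is not None:
        calls = calls[calls["clone_id"].isin(clone_ids)]
    ma_genes = set(calls.loc[calls["allelic_class"] == "MA", "gene_id"])
    categories = detect_random_aei(panel, state, clone_ids=clone_ids)
    random_genes = set(categories[categories.isin(["RANDOM_AEI", "RANDOM_MA"])].index)

    poly = polyclonal_calls.set_index("gene_id")["allelic_class"]
    measurable = {g for g in ma_genes if poly.get(g, "ND") != "ND"}
    ba_in_poly = {g for g in measurable if poly[g] == "BA"}
    ma_in_poly = {g for g in measurable if poly[g] == "MA"}
    sk_in_poly = {g for g in measurable if poly[g] == "SK"}
    random_measurable = {g for g in random_genes if poly.get(g, "ND") != "ND"}
    random_ba = {g for g in random_genes if poly.get(g, "ND") == "BA"}
    return FrequencySummary(
        estimator="polyclonal",
        n_expressed=clonal.n_expressed,
        n_ma_any_clone=len(ma_genes),
        n_random_aei=len(ba_in_poly),
        pct_ma=clonal.pct_ma,
        pct_random_aei=percentage(len(ba_in_poly), clonal.n_expressed, 2, "floor"),
        extra={
            "n_measurable_in_polyclonal": len(measurable),
            "n_ba_in_polyclonal": len(ba_in_poly),
            "n_ma_in_polyclonal": len(ma_in_poly),
            "n_sk_in_polyclonal": len(sk_in_poly),
            "pct_ba_of_measurable": percentage(len(ba_in_poly), len(measurable), 1, "half_up"),
            "n_random_aei_clonal": len(random_genes),
            "n_random_aei_ba_in_polyclonal": len(random_ba),
            "pct_random_aei_ba_in_polyclonal": percentage(
                len(random_ba), len(random_genes), 0, "half_up"
            ),
        },
    )


def _state_consensus(classes: pd.Series) -> str:
    # Collapse multiple clones of one state to a gene-level class:
    # MA anywhere dominates, then SK, then BA; all-ND stays ND.
    for label in ("MA", "SK", "BA"):
        if (classes == label).any():
            return label
    return "ND"


def _transition_category(before: str, after: str) -> str:
    if before == "MA":
        return {"BA": "RESET", "MA": "RETAINED", "SK": "TO_SKEWED", "ND": "LOST"}[after]
    if after == "MA":
        return "DE_NOVO"
    if before == "BA" and after == "BA":
        return "STABLE_BA"
    return "OTHER"


@dataclass(frozen=True)
class TransitionSummary:
    """Per-gene class transitions between two developmental states."""

    records: pd.DataFrame
    counts: dict
    n_ma_before: int
    n_ma_before_detected_after: int
    pct_reset_of_ma_before: float
    pct_reset_of_detected: float


def transition_analysis(
    panel: ClonePanel,
    before: str,
    after: str,
    universe: str = "before_detected",
) -> TransitionSummary:
    """Track per-gene allelic class across a developmental transition.

    Gene-level classes within each state are the clone consensus (MA if
    MA in any clone, else SK, else BA, else ND).  The gene universe is
    genes detected in the before state (``universe="before_detected"``)
    or detected in either state (``"either"``).  Reset percentages are
    reported against two denominators used in practice: all MA-before
    genes, and MA-before genes still detected after.
    """
    calls = panel.analysis_calls()
    for st in (before, after):
        if not (calls["developmental_state"] == st).any():
            raise ValueError(f"state {st!r} not present in panel")
    b = calls[calls["developmental_state"] == before].groupby("gene_id")["allelic_class"].apply(_state_consensus)
    a = calls[calls["developmental_state"] == after].groupby("gene_id")["allelic_class"].apply(_state_consensus)
    if universe == "before_detected":
        genes = b[b != "ND"].index
    elif universe == "either":
        genes = b.index.union(a.index)
    else:
        raise ValueError(f"unknown universe {universe!r}")
    records = pd.DataFrame(
        {
            "gene_id": genes,
            "state_before": before,
            "state_after": after,
            "class_before": [b.get(g, "ND") for g in genes],
            "class_after": [a.get(g, "ND") for g in genes],
        }
    )
    records["category"] = [
        _transition_category(cb, ca)
        for cb, ca in zip(records["class_before"], records["class_after"])
    ]
    counts = {cat: int((records["category"] == cat).sum()) for cat in TRANSITION_CATEGORIES}
    ma_before = records[records["class_before"] == "MA"]
    detected_after = ma_before[ma_before["class_after"] != "ND"]
    n_reset = counts["RESET"]
    return TransitionSummary(
        records=records,
        counts=counts,
        n_ma_before=len(ma_before),
        n_ma_before_detected_after=len(detected_after),
        pct_reset_of_ma_before=percentage(n_reset, len(ma_before), 0, "half_up"),
        pct_reset_of_detected=percentage(n_reset, len(detected_after), 0, "half_up"),
    )


@dataclass(frozen=True)
class MaOverlapResult:
    """Concordance of MA gene sets between two clone sets."""

    n_ma_union: int
    n_expressed_both: int
    n_ma_both: int
    pct_ma_both: float


def ma_overlap_between_sets(
    panel: ClonePanel, state: str, clones_a: list[str], clones_b: list[str]
) -> MaOverlapResult:
    """How often an MA gene from either clone set is MA in both.

    Universe: genes MA in >= 1 clone of either set AND expressed
    (non-ND somewhere) in both sets.  Reported percentage at one
    decimal, half-up.
    """
    calls = panel.state_calls(state)

    def _sets(clone_ids):
        sub = calls[calls["clone_id"].isin(clone_ids)]
        ma = set(sub.loc[sub["allelic_class"] == "MA", "gene_id"])
        expressed = set(sub.loc[sub["allelic_class"] != "ND", "gene_id"])
        return ma, expressed

    ma_a, expr_a = _sets(clones_a)
    ma_b, expr_b = _sets(clones_b)
    union_ma = ma_a | ma_b
    universe = union_ma & expr_a & expr_b
    both = ma_a & ma_b & universe
    return MaOverlapResult(
        n_ma_union=len(union_ma),
        n_expressed_both=len(universe),
        n_ma_both=len(both),
        pct_ma_both=percentage(len(both), len(universe), 1, "half_up"),
    )


def hotspot_overlap(
    ma_genes: set[str], hotspot_genes: set[str], background: set[str]
) -> OverlapTestResult:
    """Exact enrichment of MA genes in reprogramming-hotspot genes.

    Both sets are intersected with the background universe before the
    two-tailed Fisher test; fold enrichment is observed over the
    hypergeometric expectation |MA| * |hotspot| / |background|.
    """
    if not background:
        raise ValueError("background gene set is empty")
    a = ma_genes & background
    b = hotspot_genes & background
    return hypergeom_overlap_test(len(a), len(b), len(a & b), len(background))
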