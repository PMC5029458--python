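"""Worked-example clone panels built from published summary counts.

Genome-wide allelic expression surveys of clonal neural stem cell
panels report their results as summary counts: how many genes were
expressed, how many were monoallelic in at least one clone, how many
showed random allelic expression imbalance, how the monoallelic genes
behaved after reprogramming, and how they read out in a polyclonal
population.  The builders here construct explicit per-clone call
matrices realizing such counts, so the package's summarizers can be
exercised (and their printed percentages checked) without the
underlying raw arrays, which are not public.

Default counts follow a published five-clone iPSC-derived neural stem
cell panel: 7334 expressed genes, 126 monoallelic in at least one
clone, 48 with random allelic expression imbalance, 62 of the
clone-monoallelic genes biallelic in the polyclonal sample, and the
reprogramming behaviour of the 23 random-AEI and 56 unresolved
monoallelic genes of the parental clone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clonal import ClonePanel

_CALL_COLUMNS = [
    "gene_id",
    "sample_id",
    "clone_id",
    "developmental_state",
    "n_informative",
    "score",
    "direction",
    "allelic_class",
    "excluded_reason",
]

# representative per-class scores/directions consistent with the
# classification thresholds (t_sk = 0.1, t_ma = 0.2)
_CLASS_ROW = {
    "BA": (3, 0.04, "NA"),
    "SK": (3, 0.15, "ALLELE_A"),
    "MA": (3, 0.30, "ALLELE_A"),
    "MA_B": (3, 0.30, "ALLELE_B"),
    "ND": (0, np.nan, "NA"),
}


def _row(gene: str, clone: str, state: str, cls: str) -> dict:
    n, score, direction = _CLASS_ROW[cls]
    return {
        "gene_id": gene,
        "sample_id": f"{clone}_{state}",
        "clone_id": clone,
        "developmental_state": state,
        "n_informative": n,
        "score": score,
        "direction": direction,
        "allelic_class": "MA" if cls == "MA_B" else cls,
        "excluded_reason": None,
    }


def _panel(rows: list[dict]) -> ClonePanel:
    calls = pd.DataFrame(rows, columns=_CALL_COLUMNS)
    clones = calls[["sample_id", "clone_id", "developmental_state"]].drop_duplicates()
    return ClonePanel(calls=calls, clones=clones)


def five_clone_panel(
    n_expressed: int = 7334,
    n_ma_any: int = 126,
    n_random_aei: int = 48,
    state: str = "iPSC_NSC",
) -> ClonePanel:
    """Five sister clones with the published MA / random-AEI counts.

    Random-AEI genes are monoallelic in the first clone and biallelic
    in the four sisters; the remaining clone-MA genes are monoallelic
    for one consistent allele in every clone; all other expressed
    genes are biallelic throughout.
    """
    clones = [f"cl{i:02d}" for i in range(1, 6)]
    rows = []
    for i in range(n_expressed):
        gene = f"G{i + 1:05d}"
        if i < n_random_aei:
            pattern = ["MA"] + ["BA"] * 4
        elif i < n_ma_any:
            pattern = ["MA"] * 5
        else:
            pattern = ["BA"] * 5
        rows.extend(_row(gene, c, state, p) for c, p in zip(clones, pattern))
    return _panel(rows)


def polyclonal_calls_for(
    panel: ClonePanel,
    state: str = "iPSC_NSC",
    n_measurable: int = 88,
    n_ba: int = 62,
    n_ma: int = 17,
    n_sk: int = 9,
    n_random_ba: int = 42,
) -> pd.DataFrame:
    """Polyclonal-sample calls for the panel's clone-MA genes.

    Of the clone-MA genes, ``n_measurable`` are expressed in the
    polyclonal population and split into ``n_ba``/``n_ma``/``n_sk``
    biallelic/monoallelic/skewed, with ``n_random_ba`` of the
    random-AEI genes among the biallelic ones; the rest are below
    detection (and appear as ND by omission).
    """
    if n_ba + n_ma + n_sk != n_measurable:
        raise ValueError("class counts must sum to n_measurable")
    calls = panel.state_calls(state)
    ma_genes = sorted(calls.loc[calls["allelic_class"] == "MA", "gene_id"].unique())
    # panel construction puts the random-AEI genes first
    by_clone = calls[calls["gene_id"].isin(ma_genes)]
    ba_sister = set(by_clone.loc[by_clone["allelic_class"] == "BA", "gene_id"])
    random_genes = [g for g in ma_genes if g in ba_sister]
    constant_genes = [g for g in ma_genes if g not in ba_sister]
    n_random = len(random_genes)
    rows = []
    # random-AEI genes: n_random_ba biallelic, the rest split MA/SK
    classes = (
        ["BA"] * n_random_ba
        + ["MA"] * ((n_random - n_random_ba + 1) // 2)
        + ["SK"] * ((n_random - n_random_ba) // 2)
    )
    for gene, cls in zip(random_genes, classes):
        rows.append((gene, cls))
    used_ba = n_random_ba
    used_ma = (n_random - n_random_ba + 1) // 2
    used_sk = (n_random - n_random_ba) // 2
    # constant-MA genes fill the remaining measurable slots
    remaining = (
        ["BA"] * (n_ba - used_ba) + ["MA"] * (n_ma - used_ma) + ["SK"] * (n_sk - used_sk)
    )
    for gene, cls in zip(constant_genes, remaining):
        rows.append((gene, cls))
    out = []
    for gene, cls in rows:
        r = _row(gene, "polyclonal", "polyclonal", cls)
        out.append(r)
    return pd.DataFrame(out, columns=_CALL_COLUMNS)


def reprogramming_panel(
    n_ma_before: int = 56,
    n_reset: int = 26,
    n_retained: int = 20,
    n_skewed: int = 5,
    n_lost: int = 5,
    before: str = "NSC_parental",
    after: str = "iPSC_early",
) -> ClonePanel:
    """One clone before and after reprogramming with the published fate counts.

    Monoallelic genes of the parental clone revert to biallelic
    (``n_reset``), stay monoallelic, become skewed, or drop below
    detection in the pluripotent state.
    """
    if n_reset + n_retained + n_skewed + n_lost != n_ma_before:
        raise ValueError("fate counts must sum to n_ma_before")
    fates = ["BA"] * n_reset + ["MA"] * n_retained + ["SK"] * n_skewed + ["ND"] * n_lost
    rows = []
    for i, fate in enumerate(fates):
        gene = f"M{i + 1:04d}"
        rows.append(_row(gene, "SPC01", before, "MA"))
        rows.append(_row(gene, "iPS1", after, fate))
    return _panel(rows)


def ma_overlap_panel(
    n_universe: int = 63,
    n_ma_both: int = 37,
    state: str = "iPSC_NSC",
) -> ClonePanel:
    """Two clone sets sharing MA genes at the published overlap.

    ``n_universe`` monoallelic genes are expressed in both clone sets;
    ``n_ma_both`` of them are monoallelic in at least one clone of
    each set, the rest only in the first set.
    """
    rows = []
    for i in range(n_universe):
        gene = f"V{i + 1:04d}"
        in_both = i < n_ma_both
        rows.append(_row(gene, "nsc1a", state, "MA"))
        rows.append(_row(gene, "nsc1b", state, "BA"))
        rows.append(_row(gene, "nsc2a", state, "MA" if in_both else "BA"))
        rows.append(_row(gene, "nsc2b", state, "BA"))
    return _panel(rows)
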