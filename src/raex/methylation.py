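"""Region-level DNA methylation versus allelic expression state.

Consumes a 450K-style CpG beta matrix (values in [0, 1], preprocessed
upstream) and probe annotations (gene-region class relative to the
transcription start site, CpG-island relation, CpG vs non-CpG site).
The central comparison pairs each probe's mean methylation across
monoallelically expressing clones with its mean across biallelic
sister clones and applies a Wilcoxon signed-rank test per genic region
(TSS200, 1st exon, gene body, island features, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .stats import TestResult, rank_sum_test, signed_rank_test

log = logging.getLogger(__name__)

GENE_REGIONS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
SITE_CLASSES = ("CpG", "non-CpG")

AUTOSOMES = tuple(str(i) for i in range(1, 23))


@dataclass(frozen=True)
class MethAnnotation:
    """CpG probe annotation.

    ``probes``: indexed by cpg_id with columns chromosome, position
    (1-based), island_relation, site_class.  ``memberships``: long
    table (cpg_id, gene_id, gene_region); a probe may annotate several
    genes and regions, mirroring semicolon-delimited 450K manifests.
    """

    probes: pd.DataFrame
    memberships: pd.DataFrame

    @classmethod
    def from_csv(cls, path) -> "MethAnnotation":
        """Parse a 450K-style annotation CSV.

        Columns: ``IlmnID``, ``CHR``, ``MAPINFO``,
        ``UCSC_RefGene_Name`` / ``UCSC_RefGene_Group``
        (semicolon-delimited, parallel), ``Relation_to_UCSC_CpG_Island``
        and optionally ``Site_Class`` (defaults to CpG).
        """
        df = pd.read_csv(path, dtype={"IlmnID": str, "CHR": str})
        probes = pd.DataFrame(
            {
                "chromosome": df["CHR"].to_numpy(),
                "position": df["MAPINFO"].astype(int).to_numpy(),
                "island_relation": df["Relation_to_UCSC_CpG_Island"].fillna("OpenSea").to_numpy(),
                "site_class": df.get("Site_Class", pd.Series("CpG", index=df.index))
                .fillna("CpG")
                .to_numpy(),
            },
            index=pd.Index(df["IlmnID"], name="cpg_id"),
        )
        rows = []
        for cpg, genes, regions in zip(
            df["IlmnID"], df["UCSC_RefGene_Name"].fillna(""), df["UCSC_RefGene_Group"].fillna("")
        ):
            for gene, region in zip(genes.split(";"), regions.split(";")):
                if gene:
                    rows.append({"cpg_id": cpg, "gene_id": gene, "gene_region": region})
        return cls(probes=probes, memberships=pd.DataFrame(rows, columns=["cpg_id", "gene_id", "gene_region"]))

    def autosomal_ids(self) -> pd.Index:
        return self.probes.index[self.probes["chromosome"].isin(AUTOSOMES)]


def filter_probes(m: pd.DataFrame, blocklist: set[str]) -> pd.DataFrame:
    """Drop blocklisted (e.g. cross-hybridizing) probes from a beta matrix.

    Unknown blocklist ids are ignored; removal and unknown counts are
    logged.  Returns a new matrix (never mutates the input).
    """
    present = m.index.intersection(list(blocklist))
    unknown = len(blocklist) - len(present)
    out = m.drop(index=present)
    log.info("filter_probes: removed %d probes (%d blocklist ids unknown)", len(present), unknown)
    if out.shape[0] == 0:
        log.warning("filter_probes: blocklist removed every probe")
    return out


@dataclass(frozen=True)
class RegionTestResult:
    """Paired MA-vs-BA methylation comparison for one genic region."""

    region_label: str
    n_pairs: int
    statistic: float
    p_value: float
    method: str
    direction: str  # "MA_higher", "BA_higher", "none"
    mean_difference: float


def paired_region_test(
    m: pd.DataFrame,
    ann: MethAnnotation,
    genes: set[str],
    ma_samples: list[str],
    ba_samples: list[str],
    region: str,
    autosomal_only: bool = True,
    exact_limit: int = 12,
) -> RegionTestResult:
    """Signed-rank test of MA-clone vs BA-clone methylation in a region.

    Each probe annotated to ``region`` for any gene in ``genes``
    contributes one pair: (mean beta over MA samples, mean beta over BA
    samples).  Differences of zero are dropped per the Wilcoxon
    convention; the direction is the sign of the median difference.
    The p-value is exact (full sign enumeration) for n <= exact_limit
    and a continuity-corrected normal approximation above it.
    """
    region_is_island = region in ISLAND_RELATIONS
    if region_is_island:
        cpgs = ann.probes.index[ann.probes["island_relation"] == region]
        sel = ann.memberships["gene_id"].isin(genes) & ann.memberships["cpg_id"].isin(cpgs)
    else:
        sel = ann.memberships["gene_id"].isin(genes) & (ann.memberships["gene_region"] == region)
    probe_ids = pd.Index(ann.memberships.loc[sel, "cpg_id"].unique())
    if autosomal_only:
        probe_ids = probe_ids.intersection(ann.autosomal_ids())
    probe_ids = probe_ids.intersection(m.index)
    ma = m.loc[probe_ids, ma_samples].mean(axis=1)
    ba = m.loc[probe_ids, ba_samples].mean(axis=1)
    diffs = (ma - ba).dropna()
    if len(diffs) < 1:
        raise ValueError(f"no usable probe pairs for region {region!r}")
    res = signed_rank_test(diffs.to_numpy(), exact_limit=exact_limit)
    median = float(np.median(diffs))
    if res.n == 0 or median == 0:
        direction = "none"
    else:
        direction = "MA_higher" if median > 0 else "BA_higher"
    return RegionTestResult(
        region_label=region,
        n_pairs=len(diffs),
        statistic=res.statistic,
        p_value=res.p_value,
        method=res.method,
        direction=direction,
        mean_difference=float(diffs.mean()),
    )


def paired_region_test_by_gene(
    m: pd.DataFrame,
    ann: MethAnnotation,
    gene_groups: dict[str, tuple[list[str], list[str]]],
    region: str,
    autosomal_only: bool = True,
    exact_limit: int = 12,
) -> RegionTestResult:
    """Region test where the MA/BA clone split differs per gene.

    ``gene_groups`` maps gene_id -> (MA-clone sample ids, BA-clone
    sample ids) for that gene; each of the gene's probes in ``region``
    contributes the pair (mean beta over its gene's MA samples, mean
    over its BA samples).  Pairs are pooled across genes and tested
    with the signed-rank test exactly as in
    :func:`paired_region_test`.  This is the natural comparison for
    random-AEI genes, where which sister clone is monoallelic varies
    gene by gene.
    """
    region_is_island = region in ISLAND_RELATIONS
    autosomal = set(ann.autosomal_ids())
    diffs = []
    for gene, (ma_s, ba_s) in sorted(gene_groups.items()):
        if not ma_s or not ba_s:
            continue
        sel = ann.memberships["gene_id"] == gene
        if region_is_island:
            cpgs = ann.probes.index[ann.probes["island_relation"] == region]
            sel &= ann.memberships["cpg_id"].isin(cpgs)
        else:
            sel &= ann.memberships["gene_region"] == region
        probe_ids = pd.Index(ann.memberships.loc[sel, "cpg_id"].unique()).intersection(m.index)
        if autosomal_only:
            probe_ids = pd.Index([p for p in probe_ids if p in autosomal])
        if len(probe_ids) == 0:
            continue
        d = m.loc[probe_ids, ma_s].mean(axis=1) - m.loc[probe_ids, ba_s].mean(axis=1)
        diffs.append(d.dropna())
    if not diffs:
        raise ValueError(f"no usable probe pairs for region {region!r}")
    all_diffs = pd.concat(diffs)
    res = signed_rank_test(all_diffs.to_numpy(), exact_limit=exact_limit)
    median = float(np.median(all_diffs))
    if res.n == 0 or median == 0:
        direction = "none"
    else:
        direction = "MA_higher" if median > 0 else "BA_higher"
    return RegionTestResult(
        region_label=region,
        n_pairs=len(all_diffs),
        statistic=res.statistic,
        p_value=res.p_value,
        method=res.method,
        direction=direction,
        mean_difference=float(all_diffs.mean()),
    )


def count_dmps(m1, m2, threshold: float = 0.3) -> tuple[int, int]:
    """Count probes whose methylation differs by more than ``threshold``.

    ``m1``/``m2`` are per-probe beta Series (DataFrames are reduced to
    row means first).  Compared on the probe intersection; the
    comparison is strict (|difference| exactly at the threshold does
    not count).  Returns (count, total probes compared).  Symmetric in
    its arguments.
    """
    if isinstance(m1, pd.DataFrame):
        m1 = m1.mean(axis=1)
    if isinstance(m2, pd.DataFrame):
        m2 = m2.mean(axis=1)
    common = m1.index.intersection(m2.index)
    if len(common) == 0:
        raise ValueError("probe sets are disjoint")
    diff = (m1.loc[common] - m2.loc[common]).abs().dropna()
    # strict inequality with a round-off guard so a difference that is
    # exactly the threshold up to float error does not count
    return int((diff > threshold + 1e-12).sum()), int(len(diff))


def noncpg_summary(m: pd.DataFrame, ann: MethAnnotation) -> pd.DataFrame:
    """Per-sample mean and median methylation at autosomal non-CpG sites.

    Elevated non-CpG methylation is a hallmark of the pluripotent
    state, so this summary separates pluripotent from neural samples.
    """
    ids = ann.probes.index[
        (ann.probes["site_class"] == "non-CpG")
        & ann.probes["chromosome"].isin(AUTOSOMES)
    ].intersection(m.index)
    if len(ids) == 0:
        raise ValueError("no autosomal non-CpG probes present")
    sub = m.loc[ids]
    return pd.DataFrame(
        {"n_probes": sub.notna().sum(), "mean": sub.mean(), "median": sub.median()}
    )


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage sample clustering on correlation distance."""

    labels: list[str]
    linkage_matrix: np.ndarray

    def merge_heights(self) -> list[float]:
        return [float(h) for h in self.linkage_matrix[:, 2]]


def cluster_samples(m: pd.DataFrame) -> Dendrogram:
    """Hierarchically cluster samples on their methylation profiles.

    Distance is 1 - Pearson correlation between sample beta vectors
    (rows with any missing value are dropped first), linkage is
    average; samples are ordered by id so tie-breaks are deterministic.
    A constant sample vector has no defined correlation and is a fatal,
    named error.
    """
    labels = sorted(m.columns)
    if len(labels) < 2:
        raise ValueError("clustering requires at least two samples")
    data = m[labels].dropna(axis=0).to_numpy(dtype=float)
    sd = data.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"constant methylation vector for sample {labels[j]!r}")
    corr = np.corrcoef(data, rowvar=False)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(labels=labels, linkage_matrix=z)


def promoter_window(
    tss: int, strand: str, upstream: int = 1000, downstream: int = 500
) -> tuple[int, int]:
    """Promoter interval around a TSS, strand-aware, 1-based inclusive.

    Default window: 1000 bp upstream to 500 bp downstream of the TSS
    on the coding strand; for minus-strand genes upstream lies on the
    larger-coordinate side.
    """
    if strand == "+":
        return tss - upstream, tss + downstream
    if strand == "-":
        return tss - downstream, tss + upstream
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def promoter_signal_compare(signal_a, signal_b) -> TestResult:
    """Compare promoter chromatin signal (-log10 p) between gene classes.

    Unpaired Wilcoxon rank-sum on per-gene promoter signal values for
    e.g. MA-like vs BA-like genes; exact for small samples, normal
    approximation otherwise.
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both gene groups must be non-empty")
    return rank_sum_test(a, b)
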