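"""Allelic expression calling from beta-values.

Informative SNPs are those heterozygous in genomic DNA; for each such
SNP the signed difference delta-beta = beta_cDNA - beta_gDNA measures
allelic imbalance in the transcript pool (positive = A allele
over-expressed).  Gene (or isoform) scores are the weighted mean of
|delta-beta| over informative SNPs, and genes are classified as

    BA (biallelic)    score <  t_sk        (default 0.1)
    SK (skewed)       t_sk <= score < t_ma (default 0.2)
    MA (monoallelic)  score >= t_ma
    ND (not detected) no informative SNP with passing cDNA intensity

The interval boundaries are lower-closed; under the symmetric mapping
r = (0.5 + d)/(0.5 - d) the BA/SK boundary d = 0.1 corresponds to a
1.5-fold major:minor allele ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_io import BetaMatrix, ProbeManifest, SampleManifest

GENOTYPES = ("HOM_A", "HET", "HOM_B", "NO_CALL")
CLASSES = ("BA", "SK", "MA", "ND")
DIRECTIONS = ("ALLELE_A", "ALLELE_B", "DISCORDANT", "NA")


@dataclass(frozen=True)
class CallParams:
    """Thresholds for genotyping and allelic classification.

    het band and homozygote bands act on gDNA beta; t_sk/t_ma act on
    the gene-level mean |delta-beta| score.
    """

    het_low: float = 0.3
    het_high: float = 0.7
    hom_a_min: float = 0.8
    hom_b_max: float = 0.2
    t_sk: float = 0.1
    t_ma: float = 0.2
    min_informative: int = 1

    def __post_init__(self):
        if self.het_low >= self.het_high:
            raise ValueError("het_low must be < het_high")
        if not (0 < self.t_sk < self.t_ma):
            raise ValueError("thresholds must satisfy 0 < t_sk < t_ma")


@dataclass(frozen=True)
class PenaltyConfig:
    """Hook for down-weighting large transcripts.

    With ``enabled`` False every SNP has unit weight.  The one built-in
    scheme is per-transcript shrinkage of the score toward zero,
    score' = score * n / (n + shrinkage_k); shrinkage_k = 0 is a no-op.
    """

    enabled: bool = False
    shrinkage_k: float = 0.0


def call_genotypes(b: BetaMatrix, params: CallParams = CallParams()) -> pd.DataFrame:
    """Genotype gDNA probes from beta: probe x sample frame of labels.

    HET iff beta in [het_low, het_high] with the intensity filter
    passed; HOM_A iff beta > hom_a_min; HOM_B iff beta < hom_b_max;
    NO_CALL otherwise (including filtered and missing cells).
    """
    if b.material != "gDNA":
        raise ValueError("genotypes are called on the gDNA beta matrix")
    beta = b.beta
    ok = b.pass_filter & beta.notna()
    out = pd.DataFrame("NO_CALL", index=beta.index, columns=beta.columns)
    out = out.mask(ok & (beta >= params.het_low) & (beta <= params.het_high), "HET")
    out = out.mask(ok & (beta > params.hom_a_min), "HOM_A")
    out = out.mask(ok & (beta < params.hom_b_max), "HOM_B")
    return out


def compute_snp_delta(
    beta_cdna: BetaMatrix,
    beta_gdna: BetaMatrix,
    genotypes: pd.DataFrame,
    samples: SampleManifest,
) -> pd.DataFrame:
    """Signed delta-beta per informative SNP per cDNA sample.

    One record per probe that is HET in the paired gDNA sample and
    whose cDNA intensity passes the background filter.  Columns:
    probe_id, sample_id (cDNA), gdna_sample, clone_id,
    developmental_state, delta_beta, abs_delta.
    """
    meta = samples.samples.set_index("sample_id")
    records = []
    for cdna_sample in beta_cdna.sample_ids:
        gdna_sample = samples.paired_gdna(cdna_sample)
        if gdna_sample not in genotypes.columns:
            raise ValueError(f"no genotype column for paired gDNA sample {gdna_sample!r}")
        common = beta_cdna.beta.index.intersection(genotypes.index)
        het = genotypes.loc[common, gdna_sample] == "HET"
        usable = het & beta_cdna.pass_filter.loc[common, cdna_sample]
        usable &= beta_cdna.beta.loc[common, cdna_sample].notna()
        usable &= beta_gdna.beta.loc[common, gdna_sample].notna()
        probes = common[usable]
        if len(probes) == 0:
            continue
        delta = (
            beta_cdna.beta.loc[probes, cdna_sample] - beta_gdna.beta.loc[probes, gdna_sample]
        )
        records.append(
            pd.DataFrame(
                {
                    "probe_id": probes,
                    "sample_id": cdna_sample,
                    "gdna_sample": gdna_sample,
                    "clone_id": meta.loc[cdna_sample, "clone_id"],
                    "developmental_state": meta.loc[cdna_sample, "developmental_state"],
                    "delta_beta": delta.to_numpy(),
                }
            )
        )
    if not records:
        return pd.DataFrame(
            columns=[
                "probe_id",
                "sample_id",
                "gdna_sample",
                "clone_id",
                "developmental_state",
                "delta_beta",
                "abs_delta",
            ]
        )
    out = pd.concat(records, ignore_index=True)
    out["abs_delta"] = out["delta_beta"].abs()
    return out


def _direction(deltas: np.ndarray, t_sk: float) -> str:
    strong = deltas[np.abs(deltas) >= t_sk]
    if strong.size == 0:
        return "NA"
    pos, neg = (strong > 0).any(), (strong < 0).any()
    if pos and neg:
        return "DISCORDANT"
    return "ALLELE_A" if pos else "ALLELE_B"


def aggregate_gene(
    deltas: pd.DataFrame,
    manifest: ProbeManifest,
    penalty: PenaltyConfig = PenaltyConfig(),
    level: str = "gene",
    t_sk: float = 0.1,
) -> pd.DataFrame:
    """Aggregate SNP delta-betas to gene or isoform scores per sample.

    score = sum(w_i * |d_i|) / sum(w_i) with unit weights unless the
    penalty hook is enabled (then per-feature shrinkage n/(n+k) is
    applied to the score).  Direction comes from the common sign among
    SNPs with |d| >= t_sk; mixed signs give DISCORDANT, none reaching
    t_sk gives NA.  Features with no mapped informative SNP are absent
    from the output (ND is assigned later, at classification).
    """
    if level not in ("gene", "transcript"):
        raise ValueError("level must be 'gene' or 'transcript'")
    key = "gene_id" if level == "gene" else "transcript_id"
    merged = deltas.merge(manifest.memberships[["probe_id", key]].drop_duplicates(), on="probe_id")
    rows = []
    for (feature, sample), grp in merged.groupby([key, "sample_id"], sort=True):
        d = grp["delta_beta"].to_numpy()
        n = d.size
        score = float(np.abs(d).mean())
        if penalty.enabled:
            score *= n / (n + penalty.shrinkage_k)
        rows.append(
            {
                key: feature,
                "sample_id": sample,
                "clone_id": grp["clone_id"].iloc[0],
                "developmental_state": grp["developmental_state"].iloc[0],
                "n_informative": n,
                "score": score,
                "direction": _direction(d, t_sk),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[key, "sample_id", "clone_id", "developmental_state", "n_informative", "score", "direction"],
    )


@dataclass(frozen=True)
class ExclusionLists:
    """Gene lists removed from the autosomal random-AEI analysis.

    Imprinted genes (parent-of-origin monoallelic) and the
    alpha/gamma protocadherin clusters (overlapping annotations) are
    excluded outright; chromosome X genes are flagged and routed to a
    separate X report where the near-bimodal |delta-beta| distribution
    serves as a threshold calibration.
    """

    imprinted: frozenset[str] = frozenset()
    protocadherin: frozenset[str] = frozenset()
    chrx: frozenset[str] = frozenset()

    def reason_for(self, gene: str) -> str | None:
        if gene in self.imprinted:
            return "imprinted"
        if gene in self.protocadherin:
            return "protocadherin"
        if gene in self.chrx:
            return "chrX"
        return None


def classify(
    scores: pd.DataFrame,
    exclusions: ExclusionLists = ExclusionLists(),
    params: CallParams = CallParams(),
    informative_universe: pd.DataFrame | None = None,
    level: str = "gene",
) -> pd.DataFrame:
    """Assign BA/SK/MA classes to aggregated scores; fill in ND rows.

    ``informative_universe``, if given, is a frame with columns
    (feature key, sample_id, clone_id, developmental_state) listing
    every feature x sample where the gene is genotypically informative
    (has >= 1 HET probe); informative features missing from ``scores``
    in a sample become ND there.  Classification partitions all
    detected features: BA iff score < t_sk, SK iff t_sk <= score <
    t_ma, MA iff score >= t_ma.  Features with fewer than
    ``min_informative`` SNPs are demoted to ND.
    """
    key = "gene_id" if level == "gene" else "transcript_id"
    calls = scores.copy()
    score = calls["score"].to_numpy(dtype=float)
    cls = np.where(score >= params.t_ma, "MA", np.where(score >= params.t_sk, "SK", "BA"))
    cls = np.where(calls["n_informative"].to_numpy() < params.min_informative, "ND", cls)
    calls["allelic_class"] = cls
    calls.loc[calls["allelic_class"] == "ND", ["score", "direction"]] = [np.nan, "NA"]
    if informative_universe is not None:
        have = set(zip(calls[key], calls["sample_id"]))
        nd_rows = informative_universe[
            ~informative_universe.apply(lambda r: (r[key], r["sample_id"]) in have, axis=1)
        ].copy()
        if len(nd_rows):
            nd_rows["n_informative"] = 0
            nd_rows["score"] = np.nan
            nd_rows["direction"] = "NA"
            nd_rows["allelic_class"] = "ND"
            calls = pd.concat([calls, nd_rows[calls.columns]], ignore_index=True)
    calls["excluded_reason"] = [exclusions.reason_for(g) for g in calls[key]]
    return calls.sort_values([key, "sample_id"], ignore_index=True)


def delta_to_ratio(delta: float) -> float:
    """Fold ratio of major to minor allele implied by a |delta-beta|.

    Assumes the heterozygous gDNA beta sits at 0.5, so the expressed
    A-fraction is 0.5 + delta: r = (0.5 + delta)/(0.5 - delta).
    Strictly increasing on [0, 0.5) with r(0) = 1; delta >= 0.5 means
    complete monoallelic expression (infinite ratio).
    """
    if delta < 0:
        raise ValueError("delta_to_ratio expects a nonnegative |delta-beta|")
    if delta >= 0.5:
        return math.inf
    return (0.5 + delta) / (0.5 - delta)


def ratio_to_delta(ratio: float) -> float:
    """Inverse of :func:`delta_to_ratio`: d = (r - 1) / (2 (r + 1))."""
    if ratio < 1:
        raise ValueError("fold ratio must be >= 1")
    return (ratio - 1.0) / (2.0 * (ratio + 1.0))
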