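"""Two-channel SNP-array input handling.

Parses GenomeStudio-final-report-like intensity tables, probe and
sample manifests, quantile-normalizes intensity columns within a
material type (gDNA or cDNA), and computes per-probe allelic
beta-values X/(X+Y) with a background-intensity filter.

Channel convention: channel X carries the A allele, channel Y the B
allele, so beta = X/(X+Y) is the A-allele fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CHANNELS = ("X", "Y")
MATERIALS = ("gDNA", "cDNA")
DEVELOPMENTAL_STATES = (
    "NSC_parental",
    "NSC_differentiated",
    "iPSC_early",
    "iPSC_late",
    "iPSC_NSC",
    "polyclonal",
)

#: Default background-intensity cutoff: probes whose X+Y exceeds this are kept.
DEFAULT_INTENSITY_THRESHOLD = 750.0

# Column names of the supported intensity-report dialect.
REPORT_COLUMNS = {"probe": "SNP Name", "sample": "Sample ID", "x": "X Raw", "y": "Y Raw"}


@dataclass(frozen=True)
class ProbeManifest:
    """SNP probe annotation.

    ``probes``: one row per probe, indexed by ``probe_id``, with columns
    ``chromosome``, ``position`` (1-based), ``allele_a``, ``allele_b``.
    ``memberships``: long table (``probe_id``, ``gene_id``,
    ``transcript_id``); a probe may belong to zero or more transcripts
    (intronic probes are first-class).
    """

    probes: pd.DataFrame
    memberships: pd.DataFrame

    def __post_init__(self):
        if not self.probes.index.is_unique:
            dup = self.probes.index[self.probes.index.duplicated()][0]
            raise ValueError(f"duplicate probe_id in manifest: {dup!r}")
        if (self.probes["position"] < 1).any():
            raise ValueError("probe positions must be 1-based (>= 1)")

    @classmethod
    def from_csv(cls, probes_path: str | Path, memberships_path: str | Path) -> "ProbeManifest":
        probes = pd.read_csv(probes_path, dtype={"probe_id": str, "chromosome": str})
        probes = probes.set_index("probe_id")
        memberships = pd.read_csv(
            memberships_path, dtype={"probe_id": str, "gene_id": str, "transcript_id": str}
        )
        return cls(probes=probes, memberships=memberships)

    def genes_on_chromosome(self, chromosome: str) -> set[str]:
        on_chrom = self.probes.index[self.probes["chromosome"] == chromosome]
        sel = self.memberships["probe_id"].isin(on_chrom)
        return set(self.memberships.loc[sel, "gene_id"])


@dataclass(frozen=True)
class SampleManifest:
    """Sample sheet for gDNA/cDNA arrays.

    One row per sample: ``sample_id``, ``material`` (gDNA/cDNA),
    ``clone_id``, ``developmental_state``, optional ``lineage_parent``
    and ``passage``, and for cDNA rows ``paired_gdna`` naming the gDNA
    sample of the same genetic background.
    """

    samples: pd.DataFrame

    def __post_init__(self):
        df = self.samples
        if not df["sample_id"].is_unique:
            raise ValueError("sample_id values must be unique")
        bad_mat = set(df["material"]) - set(MATERIALS)
        if bad_mat:
            raise ValueError(f"unknown material labels: {sorted(bad_mat)}")
        bad_state = set(df["developmental_state"]) - set(DEVELOPMENTAL_STATES)
        if bad_state:
            raise ValueError(f"unknown developmental states: {sorted(bad_state)}")
        cdna = df[df["material"] == "cDNA"]
        gdna_ids = set(df.loc[df["material"] == "gDNA", "sample_id"])
        if "paired_gdna" not in df.columns:
            raise ValueError("manifest must carry a paired_gdna column for cDNA samples")
        unpaired = cdna[~cdna["paired_gdna"].isin(gdna_ids)]
        if len(unpaired):
            raise ValueError(
                f"cDNA samples without a gDNA pair: {sorted(unpaired['sample_id'])}"
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleManifest":
        return cls(pd.read_csv(path, dtype=str))

    def of_material(self, material: str) -> pd.DataFrame:
        return self.samples[self.samples["material"] == material].copy()

    def paired_gdna(self, cdna_sample: str) -> str:
        row = self.samples[self.samples["sample_id"] == cdna_sample]
        if row.empty or row["material"].iloc[0] != "cDNA":
            raise KeyError(f"not a cDNA sample: {cdna_sample!r}")
        return row["paired_gdna"].iloc[0]


@dataclass
class IntensityMatrix:
    """Raw or normalized two-channel intensities.

    ``values`` is probe x (sample, channel): rows indexed by probe_id,
    columns a MultiIndex of (sample_id, channel in {X, Y}).  Missing
    cells are NaN (absent, never zero-filled).
    """

    values: pd.DataFrame
    material: str
    normalized: bool = False

    def __post_init__(self):
        if self.material not in MATERIALS:
            raise ValueError(f"unknown material: {self.material!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensities must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns.get_level_values(0).unique())


def read_intensity_report(path: str | Path, manifest: SampleManifest) -> IntensityMatrix:
    """Parse a final-report-style TSV into an IntensityMatrix.

    Expected columns: ``SNP Name``, ``Sample ID``, ``X Raw``, ``Y Raw``.
    All referenced samples must exist in the manifest and share one
    material type.  Duplicated (probe, sample) rows, unknown samples and
    negative intensities are fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype={REPORT_COLUMNS["probe"]: str, REPORT_COLUMNS["sample"]: str})
    missing = [c for c in REPORT_COLUMNS.values() if c not in df.columns]
    if missing:
        raise ValueError(f"intensity report missing columns: {missing}")
    known = set(manifest.samples["sample_id"])
    unknown = sorted(set(df[REPORT_COLUMNS["sample"]]) - known)
    if unknown:
        raise ValueError(f"intensity report references samples absent from manifest: {unknown}")
    dup = df.duplicated([REPORT_COLUMNS["probe"], REPORT_COLUMNS["sample"]])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            "duplicated (probe, sample) row: "
            f"({row[REPORT_COLUMNS['probe']]!r}, {row[REPORT_COLUMNS['sample']]!r})"
        )
    if (df[[REPORT_COLUMNS["x"], REPORT_COLUMNS["y"]]].to_numpy() < 0).any():
        raise ValueError("negative intensity encountered")
    materials = set(
        manifest.samples.set_index("sample_id").loc[
            df[REPORT_COLUMNS["sample"]].unique(), "material"
        ]
    )
    if len(materials) != 1:
        raise ValueError(f"report mixes material types: {sorted(materials)}")
    long = df.rename(
        columns={
            REPORT_COLUMNS["probe"]: "probe_id",
            REPORT_COLUMNS["sample"]: "sample_id",
            REPORT_COLUMNS["x"]: "X",
            REPORT_COLUMNS["y"]: "Y",
        }
    )
    wide = long.pivot(index="probe_id", columns="sample_id", values=["X", "Y"])
    wide.columns = pd.MultiIndex.from_tuples([(s, ch) for ch, s in wide.columns])
    wide = wide.sort_index(axis=1)
    return IntensityMatrix(values=wide, material=materials.pop(), normalized=False)


def merge_intensity(a: IntensityMatrix, b: IntensityMatrix) -> IntensityMatrix:
    """Column-concatenate two unnormalized matrices of the same material."""
    if a.material != b.material:
        raise ValueError("cannot merge matrices of different materials")
    if a.normalized or b.normalized:
        raise ValueError("merge before normalization, not after")
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise ValueError(f"samples present in both matrices: {sorted(overlap)}")
    values = pd.concat([a.values, b.values], axis=1).sort_index(axis=1)
    return IntensityMatrix(values=values, material=a.material, normalized=False)


def quantile_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Quantile-normalize all (sample, channel) columns of one material.

    Every column is mapped onto the mean order-statistic distribution
    pooled over all columns of the matrix (channels X and Y together,
    so the two allele channels become directly comparable for beta).
    Rank order within each column is preserved; ties receive the mean
    of their reference values via average ranks.  Missing cells stay
    missing; columns with unequal missingness are placed on the pooled
    reference by quantile interpolation.
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    vals = m.values.to_numpy(dtype=float)
    n_probes, n_cols = vals.shape
    counts = np.sum(~np.isnan(vals), axis=0)
    if (counts == 0).any():
        col = m.values.columns[int(np.argmin(counts))]
        raise ValueError(f"column entirely missing: {col}")
    n_ref = int(counts.max())
    ref_grid = np.linspace(0.0, 1.0, n_ref)
    # Pooled reference: mean over columns of their sorted values,
    # interpolated onto a common quantile grid.
    ref = np.zeros(n_ref)
    for j in range(n_cols):
        col = np.sort(vals[~np.isnan(vals[:, j]), j])
        if col.size == 1:
            ref += col[0]
        else:
            ref += np.interp(ref_grid, np.linspace(0.0, 1.0, col.size), col)
    ref /= n_cols
    out = np.full_like(vals, np.nan)
    for j in range(n_cols):
        mask = ~np.isnan(vals[:, j])
        col = vals[mask, j]
        # average ranks -> positions on [0, 1] -> reference values
        order = col.argsort(kind="mergesort")
        ranks = np.empty(col.size)
        ranks[order] = np.arange(col.size, dtype=float)
        # average tied ranks
        sorted_col = col[order]
        uniq, inv = np.unique(sorted_col, return_inverse=True)
        rank_sums = np.bincount(inv, weights=np.arange(col.size, dtype=float))
        rank_counts = np.bincount(inv)
        mean_rank_of_sorted = (rank_sums / rank_counts)[inv]
        ranks[order] = mean_rank_of_sorted
        pos = ranks / (col.size - 1) if col.size > 1 else np.zeros(col.size)
        out[mask, j] = np.interp(pos, ref_grid, ref)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return IntensityMatrix(values=values, material=m.material, normalized=True)


@dataclass
class BetaMatrix:
    """Per-probe allelic beta with the background-intensity filter.

    ``beta`` = X/(X+Y) wherever the total is positive (NaN otherwise —
    no 0/0 arithmetic); ``pass_filter`` is strict: total > threshold.
    """

    beta: pd.DataFrame
    total: pd.DataFrame
    pass_filter: pd.DataFrame
    intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD
    material: str = "cDNA"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)


def compute_beta(
    m: IntensityMatrix, intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD
) -> BetaMatrix:
    """Compute beta = X/(X+Y) and the strict total-intensity filter.

    Requires a normalized matrix.  A cell passes the filter iff
    X + Y strictly exceeds ``intensity_threshold`` (a total exactly at
    the threshold is background).
    """
    if not m.normalized:
        raise ValueError("compute_beta requires a quantile-normalized matrix")
    x = m.values.xs("X", axis=1, level=1)
    y = m.values.xs("Y", axis=1, level=1)
    total = x + y
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = x / total
    beta = beta.where(total > 0)
    pass_filter = (total > intensity_threshold).fillna(False)
    return BetaMatrix(
        beta=beta,
        total=total,
        pass_filter=pass_filter,
        intensity_threshold=intensity_threshold,
        material=m.material,
    )
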