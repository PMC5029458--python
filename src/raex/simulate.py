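"""Synthetic clone panels with known allelic ground truth.

The generator emulates the statistical structure the analysis assumes:
a single genetic background profiled as multiple single-cell-derived
clones (and optionally a many-founder polyclonal population) on a
two-channel SNP array, with genes drawn from five truth classes:

  BA             both alleles expressed equally (allele fraction 0.5)
  EQTL_SK        cis-genetic skew, same allele and magnitude in every
                 clone, |delta-beta| within the skewed band
  IMPRINTED      parent-of-origin monoallelic, same allele everywhere,
                 persists through reprogramming
  RANDOM_MA      stochastic monoallelic choice, an independent fair
                 coin per clone (and per lineage commitment), reset to
                 biallelic in pluripotent states
  X_INACTIVATED  chromosome X genes silenced on one randomly chosen X
                 per clone, near-complete skew

Measured allele fractions get Gaussian noise; per-cell totals are
log-normal with an engineered low-intensity fraction so the background
filter is exercised.  A companion methylation simulator couples
promoter/island hypermethylation (and mild gene-body hypomethylation)
to clone-level monoallelic expression, and elevates non-CpG
methylation in pluripotent-state samples.  Everything is a
deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .array_io import IntensityMatrix, ProbeManifest, SampleManifest

TRUTH_CLASSES = ("BA", "EQTL_SK", "IMPRINTED", "RANDOM_MA", "X_INACTIVATED")

#: Developmental states in which stochastic allelic choices are erased
#: (pluripotency resets random monoallelic expression; imprints persist).
DEFAULT_RESET_STATES = ("iPSC_early", "iPSC_late")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic clone panel.

    Defaults describe a lineage-committed neural-stem-cell-like panel:
    five sister clones of one background, ~3% of genes under random
    monoallelic control at a 5:1 allelic ratio (the conventional
    "clear monoallelic" cutoff), cis-skewed genes inside the skewed
    delta-beta band, imprinted genes at 10:1, X-linked genes
    near-completely inactivated (19:1).  Array noise: allele-fraction
    s.d. 0.03, heterozygous gDNA beta centred on 0.5 with s.d. 0.02,
    log-normal totals with 5% of cells below the 750 background cutoff.
    """

    n_genes: int = 1000
    snps_per_gene_mean: float = 5.0  # 1 + Poisson(mean - 1)
    class_proportions: dict = field(
        default_factory=lambda: {
            "BA": 0.925,
            "EQTL_SK": 0.02,
            "IMPRINTED": 0.01,
            "RANDOM_MA": 0.03,
            "X_INACTIVATED": 0.015,
        }
    )
    ratio_random_ma: float = 5.0
    #: probability that a RANDOM_MA gene actually commits to imbalanced
    #: expression in a given clone (1.0 = the pure fair-coin model where
    #: every clone is monoallelic and only the allele varies; lower
    #: values emulate panels where the same locus is monoallelic in one
    #: sister clone but biallelic in another)
    random_ma_commitment: float = 1.0
    ratio_imprinted: float = 10.0
    ratio_x_inactivated: float = 19.0
    skew_delta_range: tuple[float, float] = (0.11, 0.19)
    n_clones: dict = field(default_factory=lambda: {"NSC_parental": 5})
    reset_states: tuple[str, ...] = DEFAULT_RESET_STATES
    founders_per_polyclonal: int = 100
    expressed_fraction: float = 0.9
    het_fraction: float = 0.75
    intensity_log_mean: float = float(np.log(4000.0))
    intensity_log_sd: float = 0.5
    low_intensity_fraction: float = 0.05
    low_intensity_log_mean: float = float(np.log(300.0))
    unexpressed_log_mean: float = float(np.log(150.0))
    beta_noise_sd: float = 0.03
    gdna_het_bias_sd: float = 0.02
    hom_beta_margin: float = 0.03  # homozygote beta centred at margin / 1 - margin
    # methylation model
    promoter_effect: float = 0.2
    body_effect: float = 0.1
    meth_noise_sd: float = 0.05
    probes_per_region: dict = field(
        default_factory=lambda: {
            "TSS1500": 3,
            "TSS200": 3,
            "5UTR": 1,
            "1stExon": 2,
            "Body": 6,
            "3UTR": 1,
        }
    )
    region_baseline: dict = field(
        default_factory=lambda: {
            "TSS1500": 0.15,
            "TSS200": 0.10,
            "5UTR": 0.15,
            "1stExon": 0.10,
            "Body": 0.60,
            "3UTR": 0.55,
        }
    )
    n_noncpg: int = 100
    noncpg_baseline: float = 0.02
    noncpg_pluripotent: float = 0.15
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        unknown = set(self.class_proportions) - set(TRUTH_CLASSES)
        if unknown:
            raise ValueError(f"unknown truth classes: {sorted(unknown)}")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("class proportions must be nonnegative")
        for name in ("beta_noise_sd", "gdna_het_bias_sd", "meth_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.founders_per_polyclonal < 1:
            raise ValueError("founders_per_polyclonal must be >= 1")


@dataclass
class TruthTable:
    """Ground truth of the simulated panel.

    ``genes``: per gene truth_class, true ratio, expressed flag, the
    fixed skewed allele for cis-controlled classes, and chromosome.
    ``choices``: per (gene, clone, state) expressed-allele choice
    ('A'/'B') for stochastic classes, plus the effective A-allele
    fraction used for that clone.  Fair-coin choices are independent
    across genes, clones and (non-reset) states.
    """

    genes: pd.DataFrame
    choices: pd.DataFrame

    def clone_fraction(self, gene_id: str, clone_id: str, state: str) -> float:
        sel = (
            (self.choices["gene_id"] == gene_id)
            & (self.choices["clone_id"] == clone_id)
            & (self.choices["developmental_state"] == state)
        )
        return float(self.choices.loc[sel, "a_fraction"].iloc[0])


@dataclass
class SimulatedPanel:
    gdna: IntensityMatrix
    cdna: IntensityMatrix
    probes: ProbeManifest
    samples: SampleManifest
    truth: TruthTable
    config: SimConfig
    #: per-probe affinity bias shared between the gDNA and cDNA
    #: hybridizations of the same probe (what the delta-beta design
    #: cancels); indexed by probe_id
    probe_bias: pd.Series | None = None
    #: true per-gene A-allele fraction of the polyclonal mixture
    #: (set by simulate_polyclonal); indexed by gene_id
    polyclonal_fractions: pd.Series | None = None


def _ratio_to_fraction(ratio: float) -> float:
    return ratio / (1.0 + ratio)


def _class_fraction(cfg: SimConfig, truth_class: str) -> float:
    return {
        "BA": 0.5,
        "EQTL_SK": np.nan,  # drawn per gene from skew_delta_range
        "IMPRINTED": _ratio_to_fraction(cfg.ratio_imprinted),
        "RANDOM_MA": _ratio_to_fraction(cfg.ratio_random_ma),
        "X_INACTIVATED": _ratio_to_fraction(cfg.ratio_x_inactivated),
    }[truth_class]


def _draw_genes(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    classes = rng.choice(
        list(cfg.class_proportions),
        size=cfg.n_genes,
        p=list(cfg.class_proportions.values()),
    )
    gene_ids = [f"G{i:05d}" for i in range(1, cfg.n_genes + 1)]
    chrom = np.where(
        classes == "X_INACTIVATED", "X", rng.choice(np.array(AUTOSOME_NAMES), size=cfg.n_genes)
    )
    fractions = np.empty(cfg.n_genes)
    ratios = np.empty(cfg.n_genes)
    for i, c in enumerate(classes):
        if c == "EQTL_SK":
            d = rng.uniform(*cfg.skew_delta_range)
            fractions[i] = 0.5 + d
            ratios[i] = (0.5 + d) / (0.5 - d)
        else:
            fractions[i] = _class_fraction(cfg, c)
            ratios[i] = {
                "BA": 1.0,
                "IMPRINTED": cfg.ratio_imprinted,
                "RANDOM_MA": cfg.ratio_random_ma,
                "X_INACTIVATED": cfg.ratio_x_inactivated,
            }[c]
    skew_allele = np.where(rng.random(cfg.n_genes) < 0.5, "A", "B")
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "truth_class": classes,
            "chromosome": chrom,
            "true_ratio": ratios,
            "a_fraction_major": fractions,
            "skew_allele": skew_allele,  # fixed allele for EQTL_SK / IMPRINTED
            "expressed": rng.random(cfg.n_genes) < cfg.expressed_fraction,
        }
    )


AUTOSOME_NAMES = [str(i) for i in range(1, 23)]


def _sample_frame(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for state, n in cfg.n_clones.items():
        for i in range(1, n + 1):
            clone = f"cl{i:02d}"
            gdna_id = f"{clone}_{state}_gDNA"
            rows.append(
                {
                    "sample_id": gdna_id,
                    "material": "gDNA",
                    "clone_id": clone,
                    "developmental_state": state,
                    "lineage_parent": "",
                    "passage": "",
                    "paired_gdna": "",
                }
            )
            rows.append(
                {
                    "sample_id": f"{clone}_{state}_cDNA",
                    "material": "cDNA",
                    "clone_id": clone,
                    "developmental_state": state,
                    "lineage_parent": "",
                    "passage": "",
                    "paired_gdna": gdna_id,
                }
            )
    return pd.DataFrame(rows)


def _draw_choices(cfg: SimConfig, genes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    cls = genes["truth_class"].to_numpy()
    major = genes["a_fraction_major"].to_numpy(dtype=float)
    skew_allele = genes["skew_allele"].to_numpy()
    stochastic = np.isin(cls, ("RANDOM_MA", "X_INACTIVATED"))
    fixed_frac = np.where(
        cls == "BA", 0.5, np.where(skew_allele == "A", major, 1.0 - major)
    )
    frames = []
    for state, n in cfg.n_clones.items():
        reset = state in cfg.reset_states
        for i in range(1, n + 1):
            clone = f"cl{i:02d}"
            coins = np.where(rng.random(len(genes)) < 0.5, "A", "B")
            committed = rng.random(len(genes)) < cfg.random_ma_commitment
            frac = np.where(
                stochastic,
                np.where(coins == "A", major, 1.0 - major),
                fixed_frac,
            )
            frac = np.where((cls == "RANDOM_MA") & ~committed, 0.5, frac)
            if reset:
                frac = np.where(cls == "RANDOM_MA", 0.5, frac)
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": genes["gene_id"].to_numpy(),
                        "clone_id": clone,
                        "developmental_state": state,
                        "chosen_allele": np.where(stochastic, coins, ""),
                        "a_fraction": frac,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _probe_manifest(cfg: SimConfig, genes: pd.DataFrame, rng: np.random.Generator):
    n_snps = 1 + rng.poisson(max(cfg.snps_per_gene_mean - 1.0, 0.0), size=len(genes))
    n_total = int(n_snps.sum())
    probe_ids = np.array([f"rs{k:07d}" for k in range(1, n_total + 1)])
    gene_idx = np.repeat(np.arange(len(genes)), n_snps)
    probes = pd.DataFrame(
        {
            "chromosome": genes["chromosome"].to_numpy()[gene_idx],
            "position": rng.integers(1, 250_000_000, size=n_total),
            "allele_a": "A",
            "allele_b": "G",
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    gene_of_probe = genes["gene_id"].to_numpy()[gene_idx]
    memberships = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_id": gene_of_probe,
            "transcript_id": np.char.add(gene_of_probe.astype(str), ".1"),
        }
    )
    manifest = ProbeManifest(probes=probes, memberships=memberships)
    het = rng.random(n_total) < cfg.het_fraction
    is_a_hom = ~het & (rng.random(n_total) < 0.5)  # which homozygote when not het
    return manifest, pd.Series(het, index=probe_ids), pd.Series(is_a_hom, index=probe_ids)


def _draw_totals(cfg: SimConfig, size: int, rng: np.random.Generator, expressed: np.ndarray):
    log_mean = np.where(expressed, cfg.intensity_log_mean, cfg.unexpressed_log_mean)
    totals = np.exp(rng.normal(log_mean, cfg.intensity_log_sd, size=size))
    low = rng.random(size) < cfg.low_intensity_fraction
    totals[low] = np.exp(rng.normal(cfg.low_intensity_log_mean, cfg.intensity_log_sd, low.sum()))
    return totals


def _intensity_columns(
    cfg: SimConfig,
    fractions: np.ndarray,
    expressed: np.ndarray,
    rng: np.random.Generator,
):
    """Turn measured A-fractions into (X, Y) channel intensities.

    Measurement noise is already folded into ``fractions`` (the model
    is defined on the beta scale: gDNA heterozygote beta = 0.5 +
    N(0, gdna_het_bias_sd), cDNA beta = class fraction +
    N(0, beta_noise_sd)); here the fraction is just split across the
    two channels under a log-normal total.
    """
    size = fractions.size
    totals = _draw_totals(cfg, size, rng, expressed)
    x = totals * np.clip(fractions, 0.0, 1.0)
    return x, totals - x


def simulate_panel(cfg: SimConfig) -> SimulatedPanel:
    """Generate gDNA and cDNA intensity matrices with ground truth.

    Heterozygous gDNA beta is 0.5 plus truncated Gaussian bias;
    homozygous probes sit near 0 or 1.  cDNA beta follows the truth
    class of the gene (per-clone fair-coin allele for stochastic
    classes).  Totals are log-normal with an engineered low-intensity
    fraction below the background cutoff; unexpressed genes get low
    cDNA totals in every clone.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    genes = _draw_genes(cfg, rng)
    choices = _draw_choices(cfg, genes, rng)
    manifest, het, is_a_hom = _probe_manifest(cfg, genes, rng)
    samples = SampleManifest(_sample_frame(cfg))
    truth = TruthTable(genes=genes, choices=choices)

    probe_index = manifest.probes.index
    n_probes = len(probe_index)
    probe_gene = manifest.memberships.set_index("probe_id")["gene_id"].loc[probe_index]
    expressed_probe = (
        genes.set_index("gene_id")["expressed"].loc[probe_gene].to_numpy()
    )
    het_arr = het.to_numpy()
    a_hom_arr = is_a_hom.to_numpy()

    # Probe-specific affinity bias, shared between gDNA and cDNA
    # hybridizations of a probe: this is the deviation the delta-beta
    # reference design removes.  Marginally the gDNA heterozygote beta
    # is 0.5 + N(0, gdna_het_bias_sd).
    bias = rng.normal(0.0, cfg.gdna_het_bias_sd, n_probes)
    hom_frac = np.where(a_hom_arr, 1.0 - cfg.hom_beta_margin, cfg.hom_beta_margin)
    g_frac = np.clip(np.where(het_arr, 0.5 + bias, hom_frac), 0.0, 1.0)

    frac_table = choices.pivot_table(
        index="gene_id", columns=["clone_id", "developmental_state"], values="a_fraction"
    )

    gdna_cols, cdna_cols = {}, {}
    for _, s in samples.of_material("cDNA").iterrows():
        clone, state = s["clone_id"], s["developmental_state"]
        gx, gy = _intensity_columns(cfg, g_frac, np.ones(n_probes, bool), rng)
        gdna_cols[(s["paired_gdna"], "X")] = gx
        gdna_cols[(s["paired_gdna"], "Y")] = gy
        # cDNA fractions follow the clone's true allele fraction at het
        # probes; homozygous probes transcribe the single allele present
        gene_frac = frac_table[(clone, state)].loc[probe_gene].to_numpy()
        c_frac = np.where(het_arr, gene_frac + bias, hom_frac)
        c_frac = np.clip(c_frac + rng.normal(0.0, cfg.beta_noise_sd, n_probes), 0.0, 1.0)
        cx, cy = _intensity_columns(cfg, c_frac, expressed_probe, rng)
        cdna_cols[(s["sample_id"], "X")] = cx
        cdna_cols[(s["sample_id"], "Y")] = cy

    def _matrix(cols, material):
        df = pd.DataFrame(cols, index=probe_index)
        df.columns = pd.MultiIndex.from_tuples(df.columns)
        return IntensityMatrix(values=df.sort_index(axis=1), material=material, normalized=False)

    return SimulatedPanel(
        gdna=_matrix(gdna_cols, "gDNA"),
        cdna=_matrix(cdna_cols, "cDNA"),
        probes=manifest,
        samples=samples,
        truth=truth,
        config=cfg,
        probe_bias=pd.Series(bias, index=probe_index),
    )


def simulate_polyclonal(
    panel: SimulatedPanel, state: str = "polyclonal", founders: int | None = None
) -> SimulatedPanel:
    """Add a polyclonal cDNA/gDNA sample pair drawn from the truth table.

    The polyclonal allele fraction of a stochastic gene is the mean
    over ``founders`` independent fair-coin re-draws of the clone-level
    choice; deterministic (cis-genetic) skews are unchanged and
    biallelic genes stay at 0.5.  Returns a new panel with the
    polyclonal columns appended (inputs are not mutated).
    """
    cfg = panel.config
    founders = cfg.founders_per_polyclonal if founders is None else founders
    if founders < 1:
        raise ValueError("founders must be >= 1")
    rng = np.random.default_rng([cfg.seed, 1])
    genes = panel.truth.genes
    stochastic = genes["truth_class"].isin(["RANDOM_MA", "X_INACTIVATED"]).to_numpy()
    major = genes["a_fraction_major"].to_numpy()
    skew_a = (genes["skew_allele"] == "A").to_numpy()
    p_hat = rng.binomial(founders, 0.5, size=len(genes)) / founders
    frac = np.where(
        stochastic,
        0.5 + (2 * p_hat - 1) * (major - 0.5),
        np.where(
            genes["truth_class"] == "BA", 0.5, np.where(skew_a, major, 1.0 - major)
        ),
    )
    gene_frac = pd.Series(frac, index=genes["gene_id"])

    index = panel.probes.probes.index
    n_probes = len(index)
    probe_gene = panel.probes.memberships.set_index("probe_id")["gene_id"].loc[index]
    expressed_probe = genes.set_index("gene_id")["expressed"].loc[probe_gene].to_numpy()
    # reuse the panel's genotype structure: a probe is heterozygous iff
    # its gDNA beta sits in the het band for the first clone sample
    gdna_x = panel.gdna.values.xs("X", axis=1, level=1).iloc[:, 0]
    gdna_tot = gdna_x + panel.gdna.values.xs("Y", axis=1, level=1).iloc[:, 0]
    g_first_frac = (gdna_x / gdna_tot).to_numpy()
    het = np.abs(g_first_frac - 0.5) < 0.2
    bias = (
        panel.probe_bias.loc[index].to_numpy()
        if panel.probe_bias is not None
        else g_first_frac - 0.5
    )

    sample_cdna = f"polyclonal_{state}_cDNA"
    sample_gdna = f"polyclonal_{state}_gDNA"
    g_frac = np.clip(np.where(het, 0.5 + bias, g_first_frac), 0.0, 1.0)
    gx, gy = _intensity_columns(cfg, g_frac, np.ones(n_probes, bool), rng)
    c_frac = np.where(het, gene_frac.loc[probe_gene].to_numpy() + bias, g_first_frac)
    c_frac = np.clip(c_frac + rng.normal(0.0, cfg.beta_noise_sd, n_probes), 0.0, 1.0)
    cx, cy = _intensity_columns(cfg, c_frac, expressed_probe, rng)
    gdna_new = pd.DataFrame({(sample_gdna, "X"): gx, (sample_gdna, "Y"): gy}, index=index)
    cdna_new = pd.DataFrame({(sample_cdna, "X"): cx, (sample_cdna, "Y"): cy}, index=index)
    gdna_new.columns = pd.MultiIndex.from_tuples(gdna_new.columns)
    cdna_new.columns = pd.MultiIndex.from_tuples(cdna_new.columns)

    samples = pd.concat(
        [
            panel.samples.samples,
            pd.DataFrame(
                [
                    {
                        "sample_id": sample_gdna,
                        "material": "gDNA",
                        "clone_id": "polyclonal",
                        "developmental_state": state,
                        "lineage_parent": "",
                        "passage": "",
                        "paired_gdna": "",
                    },
                    {
                        "sample_id": sample_cdna,
                        "material": "cDNA",
                        "clone_id": "polyclonal",
                        "developmental_state": state,
                        "lineage_parent": "",
                        "passage": "",
                        "paired_gdna": sample_gdna,
                    },
                ]
            ),
        ],
        ignore_index=True,
    )
    return SimulatedPanel(
        gdna=IntensityMatrix(
            pd.concat([panel.gdna.values, gdna_new], axis=1).sort_index(axis=1), "gDNA", False
        ),
        cdna=IntensityMatrix(
            pd.concat([panel.cdna.values, cdna_new], axis=1).sort_index(axis=1), "cDNA", False
        ),
        probes=panel.probes,
        samples=SampleManifest(samples),
        truth=panel.truth,
        config=cfg,
        probe_bias=panel.probe_bias,
        polyclonal_fractions=gene_frac,
    )


def simulate_methylation(panel: SimulatedPanel, gene_subset: list[str] | None = None):
    """Methylation beta matrix coupled to the panel's allelic truth.

    One methylation sample per (clone, state).  For a gene monoallelic
    in a clone (imprinted, or a stochastic class not reset in that
    state) its TSS200, 1st-exon and island-annotated probes are raised
    by ``promoter_effect`` and gene-body probes lowered by
    ``body_effect`` in that clone only; biallelic sister clones stay at
    the regional baseline.  Noise is beta-distributed around the target
    mean with s.d. ``meth_noise_sd``.  Non-CpG probes are elevated in
    pluripotent-state samples.  Returns (beta matrix, MethAnnotation,
    sample table).
    """
    from .methylation import MethAnnotation

    cfg = panel.config
    rng = np.random.default_rng([cfg.seed, 2])
    genes = panel.truth.genes
    if gene_subset is not None:
        genes = genes[genes["gene_id"].isin(gene_subset)]
    frac_table = panel.truth.choices.pivot_table(
        index="gene_id", columns=["clone_id", "developmental_state"], values="a_fraction"
    )

    probe_rows, member_rows = [], []
    k = 0
    for _, g in genes.iterrows():
        for region, n in cfg.probes_per_region.items():
            for _ in range(n):
                k += 1
                cpg = f"cg{k:07d}"
                island = {
                    "TSS200": "Island",
                    "1stExon": "Island",
                    "TSS1500": "N_Shore",
                    "5UTR": "S_Shore",
                    "Body": "OpenSea",
                    "3UTR": "OpenSea",
                }[region]
                probe_rows.append(
                    {
                        "cpg_id": cpg,
                        "chromosome": g["chromosome"],
                        "position": int(rng.integers(1, 250_000_000)),
                        "island_relation": island,
                        "site_class": "CpG",
                        "gene_id": g["gene_id"],
                        "gene_region": region,
                    }
                )
    for i in range(cfg.n_noncpg):
        probe_rows.append(
            {
                "cpg_id": f"ch{i + 1:07d}",
                "chromosome": str((i % 22) + 1),
                "position": int(rng.integers(1, 250_000_000)),
                "island_relation": "OpenSea",
                "site_class": "non-CpG",
                "gene_id": "",
                "gene_region": "",
            }
        )
    ann_df = pd.DataFrame(probe_rows).set_index("cpg_id")
    member_rows = ann_df[ann_df["gene_id"] != ""][["gene_id", "gene_region"]].reset_index()
    annotation = MethAnnotation(
        probes=ann_df[["chromosome", "position", "island_relation", "site_class"]],
        memberships=member_rows,
    )

    meth_samples = panel.samples.of_material("cDNA")[
        ["clone_id", "developmental_state"]
    ].drop_duplicates()
    meth_samples["sample_id"] = (
        meth_samples["clone_id"] + "_" + meth_samples["developmental_state"]
    )

    def _beta_noise(mean: np.ndarray) -> np.ndarray:
        mean = np.clip(mean, 0.01, 0.99)
        var = cfg.meth_noise_sd**2
        kappa = np.maximum(mean * (1 - mean) / var - 1.0, 2.0)
        return rng.beta(mean * kappa, (1 - mean) * kappa)

    gene_of_probe = ann_df["gene_id"]
    region_of_probe = ann_df["gene_region"]
    site_of_probe = ann_df["site_class"]
    baseline = np.array(
        [
            cfg.region_baseline.get(r, cfg.noncpg_baseline)
            if s == "CpG"
            else cfg.noncpg_baseline
            for r, s in zip(region_of_probe, site_of_probe)
        ]
    )
    promoter_like = region_of_probe.isin(["TSS200", "1stExon"]).to_numpy()
    body_like = (region_of_probe == "Body").to_numpy()
    noncpg = (site_of_probe == "non-CpG").to_numpy()

    cols = {}
    for _, s in meth_samples.iterrows():
        clone, state = s["clone_id"], s["developmental_state"]
        mean = baseline.copy()
        if noncpg.any() and state in ("iPSC_early", "iPSC_late"):
            mean[noncpg] = cfg.noncpg_pluripotent
        # clone-level monoallelic genes drive promoter hyper / body hypo
        if (clone, state) in frac_table.columns:
            frac = frac_table[(clone, state)]
            ma_genes = set(frac.index[(frac - 0.5).abs() >= 0.2])
        else:
            ma_genes = set()
        in_ma_gene = gene_of_probe.isin(ma_genes).to_numpy()
        mean = np.where(in_ma_gene & promoter_like, mean + cfg.promoter_effect, mean)
        mean = np.where(in_ma_gene & body_like, mean - cfg.body_effect, mean)
        cols[s["sample_id"]] = _beta_noise(mean)
    beta = pd.DataFrame(cols, index=ann_df.index)
    return beta, annotation, meth_samples.reset_index(drop=True)
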