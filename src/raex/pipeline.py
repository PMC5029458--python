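"""End-to-end orchestration: normalize -> call -> compare -> methylation -> report.

The pipeline can run on simulated data (a :class:`~raex.simulate.SimConfig`
in the ``simulate`` config section) or on user-supplied files (an
``inputs`` section with intensity reports and manifests).  All stages
share one seed; rerunning with an identical config yields a
byte-identical report bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._utils import read_gene_list
from .array_io import (
    DEFAULT_INTENSITY_THRESHOLD,
    IntensityMatrix,
    ProbeManifest,
    SampleManifest,
    compute_beta,
    quantile_normalize,
    read_intensity_report,
)
from .calling import (
    CallParams,
    ExclusionLists,
    PenaltyConfig,
    aggregate_gene,
    call_genotypes,
    classify,
    compute_snp_delta,
)
from .clonal import (
    ClonePanel,
    detect_random_aei,
    polyclonal_estimate,
    summarize_frequencies,
    transition_analysis,
)
from .methylation import noncpg_summary, paired_region_test_by_gene
from .simulate import SimConfig, simulate_methylation, simulate_panel, simulate_polyclonal

log = logging.getLogger(__name__)

DEFAULT_METH_REGIONS = ("TSS1500", "TSS200", "1stExon", "Body", "Island")


def informative_universe(
    genotypes: pd.DataFrame, probes: ProbeManifest, samples: SampleManifest
) -> pd.DataFrame:
    """Gene x cDNA-sample pairs where the gene has >= 1 HET probe.

    These are the genes assessable in a sample; assessable genes with
    no informative expressed SNP will be classified ND there.
    """
    memberships = probes.memberships
    rows = []
    for _, s in samples.of_material("cDNA").iterrows():
        gdna = s["paired_gdna"]
        if gdna not in genotypes.columns:
            continue
        het_probes = genotypes.index[genotypes[gdna] == "HET"]
        genes = memberships.loc[memberships["probe_id"].isin(het_probes), "gene_id"].unique()
        for g in sorted(genes):
            rows.append(
                {
                    "gene_id": g,
                    "sample_id": s["sample_id"],
                    "clone_id": s["clone_id"],
                    "developmental_state": s["developmental_state"],
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "clone_id", "developmental_state"])


def call_clone_panel(
    gdna: IntensityMatrix,
    cdna: IntensityMatrix,
    probes: ProbeManifest,
    samples: SampleManifest,
    params: CallParams = CallParams(),
    exclusions: ExclusionLists = ExclusionLists(),
    penalty: PenaltyConfig = PenaltyConfig(),
    intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD,
) -> ClonePanel:
    """Run the per-clone calling stack and assemble a ClonePanel.

    gDNA and cDNA are quantile-normalized separately (each material
    pooled across its samples and both channels), beta-filtered at the
    background cutoff, genotyped on gDNA, differenced at heterozygous
    SNPs, aggregated to gene scores and classified.  Chromosome X
    genes are auto-flagged from the probe manifest on top of any
    user-supplied exclusion lists.
    """
    beta_gdna = compute_beta(quantile_normalize(gdna), intensity_threshold)
    beta_cdna = compute_beta(quantile_normalize(cdna), intensity_threshold)
    genotypes = call_genotypes(beta_gdna, params)
    deltas = compute_snp_delta(beta_cdna, beta_gdna, genotypes, samples)
    scores = aggregate_gene(deltas, probes, penalty=penalty, t_sk=params.t_sk)
    chrx = probes.genes_on_chromosome("X")
    exclusions = ExclusionLists(
        imprinted=frozenset(exclusions.imprinted),
        protocadherin=frozenset(exclusions.protocadherin),
        chrx=frozenset(set(exclusions.chrx) | chrx),
    )
    universe = informative_universe(genotypes, probes, samples)
    calls = classify(scores, exclusions, params, informative_universe=universe)
    return ClonePanel(calls=calls, clones=samples.of_material("cDNA"))


@dataclass
class ReportBundle:
    """All pipeline outputs plus the metadata needed to re-derive them.

    Every reported percentage is recomputable from counts in the same
    section.  ``to_json`` is deterministic (sorted keys, fixed float
    repr) so identical runs produce byte-identical bundles.
    """

    metadata: dict
    frequency_summaries: dict = field(default_factory=dict)
    transitions: dict = field(default_factory=dict)
    aei_gene_lists: dict = field(default_factory=dict)
    methylation: dict = field(default_factory=dict)
    calls: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "frequency_summaries": self.frequency_summaries,
            "transitions": self.transitions,
            "aei_gene_lists": self.aei_gene_lists,
            "methylation": self.methylation,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json() + "\n")
        if self.calls is not None:
            self.calls.to_csv(out / "calls.tsv", sep="\t", index=False)
        for name, section in self.transitions.items():
            records = section.get("records")
            if records:
                pd.DataFrame(records).to_csv(out / f"transitions_{name}.tsv", sep="\t", index=False)


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        return yaml.safe_load(Path(config).read_text())
    return config


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _load_exclusions(section: dict | None) -> ExclusionLists:
    if not section:
        return ExclusionLists()

    def _as_set(v):
        if v is None:
            return frozenset()
        if isinstance(v, (list, tuple, set)):
            return frozenset(v)
        return frozenset(read_gene_list(v))

    return ExclusionLists(
        imprinted=_as_set(section.get("imprinted")),
        protocadherin=_as_set(section.get("protocadherin")),
        chrx=_as_set(section.get("chrx")),
    )


def _load_inputs(section: dict):
    probes = ProbeManifest.from_csv(section["probes"], section["memberships"])
    samples = SampleManifest.from_csv(section["samples"])
    gdna = read_intensity_report(section["gdna_report"], samples)
    cdna = read_intensity_report(section["cdna_report"], samples)
    return gdna, cdna, probes, samples


def run_pipeline(config: dict | str | Path) -> ReportBundle:
    """Execute all stages described by a config mapping (or YAML path).

    Stages run in order normalize -> call -> compare -> methylation ->
    report; a failing stage aborts with an error naming it.  Sections
    absent from the config are marked skipped in the bundle rather
    than failing the run.
    """
    config = _load_config(config)
    seed = int(config.get("seed", 0))
    metadata = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "raex_version": __version__,
    }
    bundle = ReportBundle(metadata=metadata)

    stage = "simulate/load"
    t0 = time.perf_counter()
    try:
        sim_panel = None
        if "inputs" in config:
            gdna, cdna, probes, samples = _load_inputs(config["inputs"])
        elif "simulate" in config:
            sim_cfg = SimConfig(**{**config.get("simulate", {}), "seed": seed})
            sim_panel = simulate_panel(sim_cfg)
            if config.get("analysis", {}).get("polyclonal", False):
                sim_panel = simulate_polyclonal(sim_panel)
            gdna, cdna = sim_panel.gdna, sim_panel.cdna
            probes, samples = sim_panel.probes, sim_panel.samples
        else:
            raise ValueError("config needs either an 'inputs' or a 'simulate' section")
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "call"
        t0 = time.perf_counter()
        params = CallParams(**config.get("call", {}))
        penalty = PenaltyConfig(**config.get("penalty", {}))
        exclusions = _load_exclusions(config.get("exclusions"))
        threshold = float(config.get("intensity_threshold", DEFAULT_INTENSITY_THRESHOLD))
        panel = call_clone_panel(
            gdna, cdna, probes, samples, params, exclusions, penalty, threshold
        )
        bundle.calls = panel.calls
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "compare"
        t0 = time.perf_counter()
        analysis = config.get("analysis", {})
        states = analysis.get(
            "group_states",
            sorted(
                s
                for s in panel.clones["developmental_state"].unique()
                if s != "polyclonal" and len(panel.clone_ids(s)) >= 2
            ),
        )
        for state in states:
            summary = summarize_frequencies(panel, state)
            bundle.frequency_summaries[state] = summary.as_dict()
            cats = detect_random_aei(panel, state)
            bundle.aei_gene_lists[state] = {
                cat: sorted(cats[cats == cat].index) for cat in cats.unique()
            }
        poly_calls = panel.calls[panel.calls["clone_id"] == "polyclonal"]
        if analysis.get("polyclonal", False) and len(poly_calls) and states:
            summary = polyclonal_estimate(panel, states[0], poly_calls)
            bundle.frequency_summaries["polyclonal"] = summary.as_dict()
        for pair in analysis.get("transitions", []):
            t = transition_analysis(panel, pair["before"], pair["after"])
            bundle.transitions[f"{pair['before']}__{pair['after']}"] = {
                "counts": t.counts,
                "n_ma_before": t.n_ma_before,
                "n_ma_before_detected_after": t.n_ma_before_detected_after,
                "pct_reset_of_ma_before": t.pct_reset_of_ma_before,
                "pct_reset_of_detected": t.pct_reset_of_detected,
                "records": t.records.to_dict("records"),
            }
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "methylation"
        t0 = time.perf_counter()
        meth_cfg = config.get("methylation")
        if not meth_cfg or not meth_cfg.get("enabled", True):
            bundle.methylation = {"skipped": True}
        elif sim_panel is None and "beta" not in meth_cfg:
            bundle.methylation = {"skipped": True, "reason": "no methylation inputs"}
        else:
            regions = meth_cfg.get("regions", list(DEFAULT_METH_REGIONS))
            if sim_panel is not None:
                beta, ann, meth_samples = simulate_methylation(sim_panel)
            else:
                from .methylation import MethAnnotation

                beta = pd.read_csv(meth_cfg["beta"], sep="\t", index_col=0)
                ann = MethAnnotation.from_csv(meth_cfg["annotation"])
                meth_samples = None
            state = states[0] if states else None
            gene_groups = _ma_ba_gene_groups(panel, state) if state else {}
            section = {"region_tests": {}}
            for region in regions:
                try:
                    res = paired_region_test_by_gene(beta, ann, gene_groups, region)
                except ValueError:
                    continue
                section["region_tests"][region] = {
                    "n_pairs": res.n_pairs,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "method": res.method,
                    "direction": res.direction,
                    "mean_difference": res.mean_difference,
                }
            try:
                section["noncpg"] = noncpg_summary(beta, ann).to_dict("index")
            except ValueError:
                pass
            bundle.methylation = section
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle


def _ma_ba_gene_groups(panel: ClonePanel, state: str) -> dict:
    """Per-gene (MA-clone, BA-clone) methylation sample groups.

    Methylation sample ids follow the simulator's convention
    ``<clone>_<state>``.
    """
    calls = panel.state_calls(state)
    groups: dict[str, tuple[list[str], list[str]]] = {}
    for gene, grp in calls.groupby("gene_id"):
        ma = sorted(grp.loc[grp["allelic_class"] == "MA", "clone_id"])
        ba = sorted(grp.loc[grp["allelic_class"] == "BA", "clone_id"])
        if ma and ba:
            groups[gene] = (
                [f"{c}_{state}" for c in ma],
                [f"{c}_{state}" for c in ba],
            )
    return groups
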