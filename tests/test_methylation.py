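"""Region-level methylation comparisons, DMP counting and clustering."""

import numpy as np
import pandas as pd
import pytest

import raex
from raex.methylation import MethAnnotation

from oracles import signed_rank_enum


def _annotation(n_tss=10, n_body=0, n_noncpg=0, gene="GENE1"):
    rows, members = [], []
    k = 0
    for region, count, island in (("TSS200", n_tss, "Island"), ("Body", n_body, "OpenSea")):
        for _ in range(count):
            k += 1
            rows.append({"cpg_id": f"cg{k}", "chromosome": "1", "position": k,
                         "island_relation": island, "site_class": "CpG"})
            members.append({"cpg_id": f"cg{k}", "gene_id": gene, "gene_region": region})
    for _ in range(n_noncpg):
        k += 1
        rows.append({"cpg_id": f"ch{k}", "chromosome": "2", "position": k,
                     "island_relation": "OpenSea", "site_class": "non-CpG"})
    probes = pd.DataFrame(rows).set_index("cpg_id")
    return MethAnnotation(probes=probes, memberships=pd.DataFrame(members, columns=["cpg_id", "gene_id", "gene_region"]))


class TestFilterProbes:
    def test_empty_blocklist_is_identity(self):
        m = pd.DataFrame({"s": [0.1, 0.2]}, index=["cg1", "cg2"])
        out = raex.filter_probes(m, set())
        assert out.equals(m)

    def test_blocklist_removes_and_ignores_unknown(self):
        m = pd.DataFrame({"s": [0.1, 0.2]}, index=["cg1", "cg2"])
        out = raex.filter_probes(m, {"cg2", "not_a_probe"})
        assert out.index.tolist() == ["cg1"]

    def test_blocklist_covering_everything_leaves_empty_matrix(self):
        m = pd.DataFrame({"s": [0.1]}, index=["cg1"])
        assert raex.filter_probes(m, {"cg1"}).shape[0] == 0


class TestPairedRegionTest:
    def test_identical_groups_are_null(self):
        ann = _annotation(n_tss=6)
        vals = np.linspace(0.1, 0.6, 6)
        m = pd.DataFrame({"ma1": vals, "ba1": vals}, index=ann.probes.index)
        res = raex.paired_region_test(m, ann, {"GENE1"}, ["ma1"], ["ba1"], "TSS200")
        assert res.p_value == 1.0 and res.direction == "none"

    def test_six_uniform_shifts_exact_p(self):
        ann = _annotation(n_tss=6)
        base = np.linspace(0.1, 0.6, 6)
        m = pd.DataFrame({"ma1": base + 0.1, "ba1": base}, index=ann.probes.index)
        res = raex.paired_region_test(m, ann, {"GENE1"}, ["ma1"], ["ba1"], "TSS200")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 64)
        assert res.direction == "MA_higher"
        assert res.mean_difference == pytest.approx(0.1)

    def test_hypermethylated_ma_clone_direction(self):
        ann = _annotation(n_tss=10)
        base = np.full(10, 0.2)
        m = pd.DataFrame({"ma1": base + 0.2, "ba1": base}, index=ann.probes.index)
        res = raex.paired_region_test(m, ann, {"GENE1"}, ["ma1"], ["ba1"], "TSS200")
        assert res.direction == "MA_higher"

    def test_island_region_selection(self):
        ann = _annotation(n_tss=6, n_body=4)
        rng = np.random.default_rng(1)
        base = rng.uniform(0.1, 0.7, 10)
        m = pd.DataFrame({"ma1": base + 0.15, "ba1": base}, index=ann.probes.index)
        res = raex.paired_region_test(m, ann, {"GENE1"}, ["ma1"], ["ba1"], "Island")
        # only the six TSS200 probes are island-annotated
        assert res.n_pairs == 6

    def test_no_usable_pairs_rejected(self):
        ann = _annotation(n_tss=2)
        m = pd.DataFrame({"ma1": [0.1, 0.2], "ba1": [0.2, 0.3]}, index=ann.probes.index)
        with pytest.raises(ValueError, match="3UTR"):
            raex.paired_region_test(m, ann, {"GENE1"}, ["ma1"], ["ba1"], "3UTR")

    def test_agrees_with_sign_enumeration(self):
        ann = _annotation(n_tss=8)
        rng = np.random.default_rng(5)
        ba = rng.uniform(0.2, 0.6, 8)
        ma = ba + rng.normal(0.05, 0.08, 8)
        m = pd.DataFrame({"ma1": ma, "ba1": ba}, index=ann.probes.index)
        res = raex.paired_region_test(m, ann, {"GENE1"}, ["ma1"], ["ba1"], "TSS200")
        _, p = signed_rank_enum(ma - ba)
        assert res.p_value == pytest.approx(p)


class TestCountDmps:
    def test_strict_threshold_counting(self):
        a = pd.Series([0.1, 0.5, 0.9], index=["cg1", "cg2", "cg3"])
        b = pd.Series([0.5, 0.5, 0.5], index=["cg1", "cg2", "cg3"])
        count, total = raex.count_dmps(a, b, threshold=0.3)
        assert (count, total) == (2, 3)

    def test_difference_exactly_at_threshold_not_counted(self):
        a = pd.Series([0.8], index=["cg1"])
        b = pd.Series([0.5], index=["cg1"])
        assert raex.count_dmps(a, b, threshold=0.3)[0] == 0

    def test_identical_and_symmetry_and_monotonicity(self):
        rng = np.random.default_rng(2)
        idx = [f"cg{i}" for i in range(100)]
        a = pd.Series(rng.uniform(0, 1, 100), index=idx)
        b = pd.Series(rng.uniform(0, 1, 100), index=idx)
        assert raex.count_dmps(a, a)[0] == 0
        assert raex.count_dmps(a, b) == raex.count_dmps(b, a)
        counts = [raex.count_dmps(a, b, threshold=t)[0] for t in (0.1, 0.3, 0.5, 0.7)]
        assert counts == sorted(counts, reverse=True)

    def test_disjoint_probe_sets_rejected(self):
        a = pd.Series([0.1], index=["cg1"])
        b = pd.Series([0.1], index=["cg2"])
        with pytest.raises(ValueError):
            raex.count_dmps(a, b)


class TestNonCpg:
    def test_summary_over_noncpg_autosomal_probes(self):
        ann = _annotation(n_tss=2, n_noncpg=3)
        ids = ann.probes.index
        m = pd.DataFrame({"s1": [0.5, 0.5, 0.0, 0.1, 0.2]}, index=ids)
        out = raex.noncpg_summary(m, ann)
        assert out.loc["s1", "n_probes"] == 3
        assert out.loc["s1", "mean"] == pytest.approx(0.1)

    def test_single_probe_mean_is_value(self):
        ann = _annotation(n_tss=0, n_noncpg=1)
        m = pd.DataFrame({"s1": [0.37]}, index=ann.probes.index)
        assert raex.noncpg_summary(m, ann).loc["s1", "mean"] == pytest.approx(0.37)

    def test_no_noncpg_probes_rejected(self):
        ann = _annotation(n_tss=2)
        m = pd.DataFrame({"s1": [0.1, 0.2]}, index=ann.probes.index)
        with pytest.raises(ValueError):
            raex.noncpg_summary(m, ann)


class TestClustering:
    def test_identical_samples_merge_at_zero(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0, 1, 50)
        m = pd.DataFrame({"a": v, "b": v})
        dend = raex.cluster_samples(m)
        assert dend.merge_heights()[0] == pytest.approx(0.0, abs=1e-12)

    def test_identical_pair_merges_before_outlier(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0, 1, 50)
        m = pd.DataFrame({"a": v, "b": v, "c": 1 - v})
        dend = raex.cluster_samples(m)
        first = set(dend.linkage_matrix[0, :2].astype(int))
        assert first == {dend.labels.index("a"), dend.labels.index("b")}

    def test_state_specific_shifts_group_samples(self, small_sim_panel):
        beta, ann, samples = raex.simulate_methylation(small_sim_panel)
        dend = raex.cluster_samples(beta)
        assert dend.linkage_matrix.shape[0] == len(beta.columns) - 1

    def test_constant_sample_named_in_error(self):
        m = pd.DataFrame({"flat": [0.5, 0.5, 0.5], "ok": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="flat"):
            raex.cluster_samples(m)


class TestPromoter:
    def test_plus_strand_window(self):
        assert raex.promoter_window(10_000, "+") == (9_000, 10_500)

    def test_minus_strand_upstream_on_larger_coordinates(self):
        assert raex.promoter_window(10_000, "-") == (9_500, 11_000)

    def test_signal_compare_exact_small_groups(self):
        res = raex.promoter_signal_compare([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)

    def test_identical_signal_null(self):
        res = raex.promoter_signal_compare([1.0, 2.0], [1.0, 2.0])
        assert res.p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            raex.promoter_signal_compare([], [1.0])


class TestAnnotationParsing:
    def test_450k_style_csv(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text(
            "IlmnID,CHR,MAPINFO,UCSC_RefGene_Name,UCSC_RefGene_Group,"
            "Relation_to_UCSC_CpG_Island,Site_Class\n"
            "cg1,1,1000,GENE1;GENE2,TSS200;Body,Island,CpG\n"
            "ch1,2,2000,,,,non-CpG\n"
        )
        ann = MethAnnotation.from_csv(path)
        assert ann.probes.loc["cg1", "island_relation"] == "Island"
        assert len(ann.memberships) == 2
        assert set(ann.memberships["gene_region"]) == {"TSS200", "Body"}
        assert ann.probes.loc["ch1", "site_class"] == "non-CpG"
        assert ann.probes.loc["ch1", "island_relation"] == "OpenSea"
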