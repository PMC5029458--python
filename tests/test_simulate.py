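"""Ground-truth generator: determinism, fair coins, recovery, mixtures."""

import numpy as np
import pandas as pd
import pytest

import raex


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            raex.SimConfig(class_proportions={"BA": 0.5, "RANDOM_MA": 0.1})

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            raex.SimConfig(class_proportions={"BA": 0.5, "WEIRD": 0.5})

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            raex.SimConfig(beta_noise_sd=-0.1)

    def test_founders_lower_bound(self):
        with pytest.raises(ValueError):
            raex.SimConfig(founders_per_polyclonal=0)


class TestDeterminism:
    def test_identical_seed_identical_panel(self):
        a = raex.simulate_panel(raex.SimConfig(n_genes=60, seed=3))
        b = raex.simulate_panel(raex.SimConfig(n_genes=60, seed=3))
        pd.testing.assert_frame_equal(a.cdna.values, b.cdna.values)
        pd.testing.assert_frame_equal(a.gdna.values, b.gdna.values)
        pd.testing.assert_frame_equal(a.truth.choices, b.truth.choices)

    def test_different_seed_different_panel(self):
        a = raex.simulate_panel(raex.SimConfig(n_genes=60, seed=3))
        b = raex.simulate_panel(raex.SimConfig(n_genes=60, seed=4))
        assert not a.cdna.values.equals(b.cdna.values)

    def test_methylation_deterministic(self, small_sim_panel):
        b1, _, _ = raex.simulate_methylation(small_sim_panel)
        b2, _, _ = raex.simulate_methylation(small_sim_panel)
        pd.testing.assert_frame_equal(b1, b2)


class TestAlleleChoices:
    def test_fair_coin_across_genes_and_clones(self):
        cfg = raex.SimConfig(
            n_genes=600,
            seed=5,
            class_proportions={"BA": 0.4, "RANDOM_MA": 0.6},
            n_clones={"NSC_parental": 4},
        )
        panel = raex.simulate_panel(cfg)
        choices = panel.truth.choices
        rm = choices[choices["chosen_allele"] != ""]
        n = len(rm)
        assert n > 1000
        frac_a = (rm["chosen_allele"] == "A").mean()
        assert abs(frac_a - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_reset_states_are_biallelic_for_random_ma(self):
        cfg = raex.SimConfig(
            n_genes=200,
            seed=5,
            class_proportions={"BA": 0.2, "RANDOM_MA": 0.6, "IMPRINTED": 0.2},
            n_clones={"NSC_parental": 2, "iPSC_early": 2},
        )
        panel = raex.simulate_panel(cfg)
        truth = panel.truth.genes.set_index("gene_id")
        ch = panel.truth.choices.set_index(
            ["gene_id", "developmental_state"]
        )["a_fraction"]
        rm = truth[truth["truth_class"] == "RANDOM_MA"].index
        imp = truth[truth["truth_class"] == "IMPRINTED"].index
        assert (ch.loc[[(g, "iPSC_early") for g in rm]] == 0.5).all()
        assert (ch.loc[[(g, "NSC_parental") for g in rm]] != 0.5).all()
        # imprints survive reprogramming
        assert (ch.loc[[(g, "iPSC_early") for g in imp]] != 0.5).all()


class TestZeroNoiseRecovery:
    def test_classification_recovers_truth_exactly(self, noise_free_panel):
        p = noise_free_panel
        panel = raex.call_clone_panel(p.gdna, p.cdna, p.probes, p.samples)
        truth = p.truth.genes.set_index("gene_id")
        calls = panel.calls[panel.calls["allelic_class"] != "ND"].copy()
        calls["truth"] = truth.loc[calls["gene_id"], "truth_class"].to_numpy()
        expected = calls["truth"].map(
            {"BA": "BA", "EQTL_SK": "SK", "IMPRINTED": "MA",
             "RANDOM_MA": "MA", "X_INACTIVATED": "MA"}
        )
        assert (calls["allelic_class"] == expected).all()

    def test_x_genes_flagged_and_near_complete(self, noise_free_panel):
        p = noise_free_panel
        panel = raex.call_clone_panel(p.gdna, p.cdna, p.probes, p.samples)
        truth = p.truth.genes.set_index("gene_id")
        x_genes = truth[truth["truth_class"] == "X_INACTIVATED"].index
        xcalls = panel.calls[panel.calls["gene_id"].isin(x_genes)]
        xcalls = xcalls[xcalls["allelic_class"] != "ND"]
        assert (xcalls["excluded_reason"] == "chrX").all()
        # ratio 19:1 puts |delta-beta| at 0.45, the bimodal chrX signature
        assert (xcalls["score"] > 0.4).all()


class TestPolyclonal:
    def test_mixture_fraction_binomial_property(self):
        # with >= 100 founders the stochastic alleles average out: the
        # true mixture |delta-beta| stays below the skew threshold for
        # more than 99% of random-MA genes
        cfg = raex.SimConfig(
            n_genes=4000,
            seed=2,
            class_proportions={"BA": 0.2, "RANDOM_MA": 0.8},
        )
        panel = raex.simulate_polyclonal(raex.simulate_panel(cfg))
        truth = panel.truth.genes.set_index("gene_id")
        rm = truth[truth["truth_class"] == "RANDOM_MA"].index
        dev = (panel.polyclonal_fractions.loc[rm] - 0.5).abs()
        assert (dev < 0.1).mean() > 0.99

    def test_deterministic_classes_unchanged_by_mixing(self):
        cfg = raex.SimConfig(
            n_genes=300,
            seed=2,
            class_proportions={"BA": 0.4, "EQTL_SK": 0.3, "IMPRINTED": 0.3},
        )
        panel = raex.simulate_polyclonal(raex.simulate_panel(cfg))
        truth = panel.truth.genes.set_index("gene_id")
        frac = panel.polyclonal_fractions
        ba = truth[truth["truth_class"] == "BA"].index
        assert (frac.loc[ba] == 0.5).all()
        sk = truth[truth["truth_class"] == "EQTL_SK"].index
        # cis-genetic skew is a fixed property of the genotype: the
        # polyclonal fraction equals the clonal one
        major = truth.loc[sk, "a_fraction_major"]
        skew_a = truth.loc[sk, "skew_allele"] == "A"
        expected = major.where(skew_a, 1 - major)
        assert np.allclose(frac.loc[sk], expected)

    def test_single_founder_is_a_clone(self):
        cfg = raex.SimConfig(
            n_genes=400, seed=9, class_proportions={"RANDOM_MA": 1.0}
        )
        panel = raex.simulate_polyclonal(raex.simulate_panel(cfg), founders=1)
        dev = (panel.polyclonal_fractions - 0.5).abs()
        # every gene fully committed to one allele, as in a clone
        assert np.allclose(dev, 1 / 3)


class TestMethylationCoupling:
    def test_null_effect_gives_equal_distributions(self):
        cfg = raex.SimConfig(
            n_genes=150, seed=21, promoter_effect=0.0, body_effect=0.0,
            class_proportions={"BA": 0.5, "RANDOM_MA": 0.5},
        )
        panel = raex.simulate_panel(cfg)
        beta, ann, samples = raex.simulate_methylation(panel)
        truth = panel.truth.genes.set_index("gene_id")
        rm = set(truth[truth["truth_class"] == "RANDOM_MA"].index)
        tss = ann.memberships[
            ann.memberships["gene_id"].isin(rm)
            & (ann.memberships["gene_region"] == "TSS200")
        ]["cpg_id"]
        res = raex.paired_region_test_by_gene(
            beta, ann,
            {g: ([samples["sample_id"].iloc[0]], [samples["sample_id"].iloc[1]]) for g in rm},
            "TSS200",
        )
        assert res.p_value > 0.01

    def test_body_probes_move_opposite_to_promoter(self, small_sim_panel):
        beta, ann, samples = raex.simulate_methylation(small_sim_panel)
        truth = small_sim_panel.truth.genes.set_index("gene_id")
        imp = truth[truth["truth_class"] == "IMPRINTED"].index
        ba = truth[truth["truth_class"] == "BA"].index
        mem = ann.memberships

        def region_mean(genes, region):
            ids = mem[(mem["gene_id"].isin(genes)) & (mem["gene_region"] == region)]["cpg_id"]
            return beta.loc[ids].mean().mean()

        assert region_mean(imp, "TSS200") > region_mean(ba, "TSS200") + 0.1
        assert region_mean(imp, "Body") < region_mean(ba, "Body")
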