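"""Simulator ground truth, competition, and end-to-end recovery."""

import numpy as np
import pandas as pd
import pytest

import otsp
from otsp.metrics import clonal_frequencies
from otsp.nb import fit_matrix
from otsp.normalize import normalize_clonotypes, primer_pair_totals
from otsp.scaling import nb_mean_scaling_factors_from_matrix
from otsp.simulate import (
    SimConfig,
    emit_reads,
    make_bias_model,
    simulate_experiment,
    simulate_repertoire,
    simulate_st_matrix,
    two_clone_mixture,
)


class TestBiasModel:
    def test_zero_sds_give_equal_means(self):
        model = make_bias_model(seed=1, v_sd=0, j_sd=0, interaction_sd=0)
        assert np.allclose(model.pair_means(), model.pair_means().iloc[0])
        assert np.allclose(model.true_scaling_factors().factors, 1.0)

    def test_no_interaction_factorizes(self):
        model = make_bias_model(seed=2, interaction_sd=0)
        m = np.exp(model.pair_log_means())
        outer = np.outer(np.exp(model.v_effects), np.exp(model.j_effects))
        assert np.allclose(m, np.exp(model.baseline) * outer)

    def test_seed_reproducibility(self):
        a = make_bias_model(seed=3)
        b = make_bias_model(seed=3)
        assert np.array_equal(a.v_effects, b.v_effects)
        assert np.array_equal(a.interaction, b.interaction)

    def test_effects_centered(self):
        model = make_bias_model(seed=4)
        assert model.v_effects.mean() == pytest.approx(0.0, abs=1e-12)
        assert model.j_effects.mean() == pytest.approx(0.0, abs=1e-12)
        assert model.interaction.mean(axis=1) == pytest.approx(0.0, abs=1e-12)
        assert model.interaction.mean(axis=0) == pytest.approx(0.0, abs=1e-12)

    def test_true_factors_mean_one(self, bias_model):
        assert bias_model.true_scaling_factors().factors.mean() == pytest.approx(
            1.0, abs=1e-12
        )


class TestSTMatrix:
    def test_poisson_high_depth_concentrates(self, bias_model):
        cfg = SimConfig(d=0.0, n_samples=10, depth=5_000_000, seed=5)
        mat, true_factors = simulate_st_matrix(bias_model, cfg)
        cvs = mat.std(axis=1) / mat.mean(axis=1)
        assert cvs.median() < 0.02
        est = mat.mean(axis=1) / mat.mean(axis=1).mean()
        assert np.corrcoef(np.log(est), np.log(true_factors.factors))[0, 1] > 0.999

    def test_factor_estimate_consistency_in_n(self, bias_model):
        r = {}
        for n in (3, 30):
            cfg = SimConfig(n_samples=n, depth=520_000, seed=6)
            mat, truth = simulate_st_matrix(bias_model, cfg)
            est = nb_mean_scaling_factors_from_matrix(mat)
            r[n] = otsp.scaling_concordance(est, truth)
        assert r[30] > r[3] > 0.9


class TestRepertoire:
    def test_monoclonal_and_uniform(self):
        t1, _ = simulate_repertoire(1, seed=7)
        assert len(t1) == 1 and t1["abundance"].iloc[0] == 1.0
        t2, _ = simulate_repertoire(10, sigma=0.0, seed=8)
        assert np.allclose(t2["abundance"], 0.1)

    def test_two_clone_mixture_is_fifty_fifty(self):
        t, pmap = two_clone_mixture(seed=9, pair_a=(3, 5), pair_b=(10, 2))
        assert np.allclose(t["abundance"], 0.5)
        assert t["v_gene"].tolist() == ["TRBV3", "TRBV10"]
        assert pmap.v_map["TRBV3"] == 3

    def test_clonotype_keys_unique(self):
        t, _ = simulate_repertoire(300, seed=10)
        assert not t.duplicated(["cdr3_nt", "v_gene", "j_gene"]).any()


class TestExperiment:
    def test_no_st_mass_means_all_clonotype_reads(self, bias_model):
        truth, _ = simulate_repertoire(30, seed=11)
        cfg = SimConfig(seed=12, depth=20_000, st_mass=0.0, gdna_mass=1.0)
        obs, st = simulate_experiment(truth, bias_model, cfg)
        assert st.sum() == 0 and obs["count"].sum() > 0

    def test_no_bias_is_unbiased_around_truth(self):
        model = make_bias_model(seed=13, v_sd=0, j_sd=0, interaction_sd=0)
        truth, _ = simulate_repertoire(20, sigma=0.5, seed=14)
        props = np.zeros(20)
        for rep in range(30):
            cfg = SimConfig(seed=100 + rep, depth=50_000, st_mass=0.0, gdna_mass=1.0)
            obs, _ = simulate_experiment(truth, model, cfg)
            merged = truth.merge(obs[["cdr3_nt", "count"]], on="cdr3_nt", how="left")
            props += merged["count"].fillna(0).to_numpy() / obs["count"].sum()
        props /= 30
        assert np.allclose(props, truth["abundance"], atol=0.01)

    def test_competition_reduces_detected_clonotypes(self, bias_model):
        """Raising spike-in mass at fixed gDNA starves clonotype reads."""
        truth, _ = simulate_repertoire(300, sigma=1.5, seed=15)
        detected = []
        # clonotype read shares ~99%, 77%, 50%, 25%, 9%: steps large enough
        # that the expected-detection trend dominates sampling noise
        for st_mass in (0.01, 0.3, 1.0, 3.0, 10.0):
            n = []
            for rep in range(8):
                cfg = SimConfig(seed=200 + rep, depth=3_000, st_mass=st_mass,
                                gdna_mass=1.0)
                obs, _ = simulate_experiment(truth, bias_model, cfg)
                n.append(len(obs))
            detected.append(np.mean(n))
        assert all(a > b for a, b in zip(detected, detected[1:]))


class TestEmitReads:
    def test_byte_identical_given_seed(self, small_library):
        counts = pd.Series(
            np.arange(12), index=otsp.demux.template_multiindex(4, 3)
        )
        cfg = SimConfig(seed=16, error_rate=0.01)
        a = emit_reads(counts, None, small_library, cfg)
        b = emit_reads(counts, None, small_library, cfg)
        assert a == b

    def test_high_error_rate_degrades_assignment(self, small_library):
        counts = pd.Series(
            np.full(12, 30), index=otsp.demux.template_multiindex(4, 3)
        )
        lost = {}
        for err in (0.0, 0.3):
            cfg = SimConfig(seed=17, error_rate=err)
            reads = emit_reads(counts, None, small_library, cfg)
            vec, _, summary = otsp.demux_sample(reads, small_library)
            lost[err] = summary.n_ambiguous + summary.n_clonotype
        assert lost[0.0] == 0 and lost[0.3] > 0


class TestFullPipelineRecovery:
    def test_normalization_moves_proportions_toward_truth(self, bias_model):
        """simulate → emit → demux → factors → normalize: normalized clone
        proportions are closer to truth (total variation) than raw ones."""
        library = otsp.generate_barcode_library(seed=18)
        truth, pmap = simulate_repertoire(25, sigma=0.8, seed=19)
        # independent ST-only calibration (count level, 20 samples)
        st_cfg = SimConfig(seed=20, n_samples=20, depth=520_000)
        st_mat, _ = simulate_st_matrix(bias_model, st_cfg)
        factors = nb_mean_scaling_factors_from_matrix(st_mat)
        # one mixed sample, read level
        cfg = SimConfig(seed=21, depth=12_000, st_mass=0.5, gdna_mass=1.0,
                        error_rate=0.001)
        obs, st_counts = simulate_experiment(truth, bias_model, cfg)
        reads = emit_reads(st_counts, obs, library, cfg)
        vec, clono_reads, summary = otsp.demux_sample(reads, library)
        assert summary.n_st + summary.n_clonotype + summary.n_ambiguous == len(reads)
        assert (vec - st_counts).abs().sum() <= 0.01 * st_counts.sum()

        normalized, _ = normalize_clonotypes(obs, factors, pmap)
        merged = truth.merge(
            normalized[["cdr3_nt", "count", "normalized_count"]],
            on="cdr3_nt", how="left",
        ).fillna({"count": 0, "normalized_count": 0})

        def tv(col):
            p = merged[col].to_numpy(dtype=float)
            p = p / p.sum()
            return 0.5 * np.abs(p - merged["abundance"].to_numpy()).sum()

        assert tv("normalized_count") < tv("count")
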