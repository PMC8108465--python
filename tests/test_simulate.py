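"""Synthetic genotypes, QTN spiking, noise model and the two studies."""

import numpy as np
import pytest
from scipy import stats

from hybridforge.config import AnalysisConfig
from hybridforge.simulate import (
    QTNSet,
    SimOneConfig,
    SimTwoConfig,
    add_prediction_noise,
    classify_pve,
    gen_full_study,
    gen_inbred_genotypes,
    genetic_value,
    match_hits_to_qtns,
    permutation_threshold,
    run_sim_one,
    run_sim_two,
    spike_in_qtns,
)
from hybridforge.io import mean_fill

from conftest import make_gm


class TestGenInbredGenotypes:
    def test_deterministic_given_seed(self):
        a = gen_inbred_genotypes(30, 100, seed=9)
        b = gen_inbred_genotypes(30, 100, seed=9)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_zero_residual_het_means_no_heterozygotes(self):
        gm = gen_inbred_genotypes(50, 200, seed=9, residual_het_rate=0.0)
        assert not (gm.dosages == 1.0).any()

    def test_maf_spectrum_matches_request(self):
        lo, hi = 0.1, 0.5
        gm = gen_inbred_genotypes(
            400, 20_000, seed=10, maf_range=(lo, hi), residual_het_rate=0.0
        )
        maf = np.array([v.maf for v in gm.variants])
        # target frequencies are uniform; folding to MAF keeps uniformity
        ks = stats.kstest(maf, "uniform", args=(lo, hi - lo)).statistic
        assert ks < 0.05

    def test_blocks_carry_ld(self):
        gm = gen_inbred_genotypes(
            300, 50, seed=11, ld_block_len=25, block_rho=0.95
        )
        r2_adj = np.corrcoef(gm.dosages[:, 10], gm.dosages[:, 11])[0, 1] ** 2
        r2_far = np.corrcoef(gm.dosages[:, 10], gm.dosages[:, 40])[0, 1] ** 2
        assert r2_adj > 0.3 and r2_far < 0.1


class TestSpikeInQtns:
    def test_effects_follow_geometric_law(self, small_panel):
        gm = gen_inbred_genotypes(200, 2000, seed=12)
        q = spike_in_qtns(gm, n=20, seed=13)
        assert q.effects[0] == pytest.approx(0.96)
        assert q.effects[19] == pytest.approx(0.96**20)
        assert q.effects[19] == pytest.approx(0.44200, abs=5e-6)

    def test_all_within_maf_window(self):
        gm = gen_inbred_genotypes(200, 2000, seed=12)
        q = spike_in_qtns(gm, n=20, seed=14)
        maf = np.array([gm.variants[i].maf for i in q.indices])
        assert ((maf >= 0.25) & (maf <= 0.35)).all()
        assert len(set(q.indices)) == 20

    def test_too_few_eligible_variants_rejected(self):
        gm = make_gm(np.zeros((10, 5)))
        with pytest.raises(ValueError, match="found 0"):
            spike_in_qtns(gm, n=3)


class TestGeneticValue:
    def test_single_qtn_identity(self):
        gm = make_gm([[0.0], [1.0], [2.0]])
        q = QTNSet(np.array([0]), np.array([1.0]), np.array([0.5]))
        np.testing.assert_allclose(genetic_value(gm, q), [0.0, 1.0, 2.0])

    def test_zero_dosages_give_zero(self):
        gm = make_gm(np.zeros((4, 3)))
        q = QTNSet(np.arange(3), np.ones(3), np.full(3, 0.3))
        np.testing.assert_allclose(genetic_value(gm, q), 0.0)

    def test_three_qtn_hand_sum(self):
        gm = make_gm([[2.0, 1.0, 0.0], [0.0, 2.0, 2.0]])
        q = QTNSet(np.arange(3), np.array([0.5, 0.25, 1.0]), np.full(3, 0.3))
        np.testing.assert_allclose(
            genetic_value(gm, q), [2 * 0.5 + 1 * 0.25, 2 * 0.25 + 2 * 1.0]
        )

    def test_missing_dosage_propagates(self):
        gm = make_gm([[np.nan], [2.0]])
        q = QTNSet(np.array([0]), np.array([1.0]), np.array([0.5]))
        y = genetic_value(gm, q)
        assert np.isnan(y[0]) and y[1] == 2.0


class TestClassifyPve:
    def test_symmetric_qtns_all_major(self):
        gm = make_gm(np.tile([[0.0], [2.0]], (1, 10)))
        q = QTNSet(np.arange(10), np.ones(10), np.full(10, 0.5))
        out = classify_pve(q, gm)
        np.testing.assert_allclose(out.pve, 0.1)
        assert out.classes == ["major"] * 10

    def test_single_qtn_is_everything(self):
        gm = make_gm([[0.0], [2.0]])
        q = QTNSet(np.array([0]), np.array([0.3]), np.array([0.5]))
        out = classify_pve(q, gm)
        assert out.pve[0] == pytest.approx(1.0)
        assert out.classes == ["major"]

    def test_geometric_effects_uniform_frequency_oracle(self):
        # brute-force normalized PVE at f = 0.30 for all QTNs
        f = 0.30
        n = 20
        beta = 0.96 ** np.arange(1, n + 1)
        raw = beta * f * (1 - f)
        pve = raw / raw.sum()
        expect = [
            "major" if v >= 0.07 else "moderate" if v >= 0.045 else "minor"
            for v in pve
        ]
        D = np.vstack([np.full((30, n), 0.0), np.full((70, n), 0.0)])
        D[: int(100 * f) * 1] = 2.0  # 30% alt-homozygous lines
        gm = make_gm(D)
        q = QTNSet(np.arange(n), beta, np.full(n, f))
        out = classify_pve(q, gm)
        assert out.classes == expect


class TestPredictionNoise:
    def test_perfect_accuracy_is_identity(self, rng):
        y = rng.normal(size=100)
        np.testing.assert_array_equal(add_prediction_noise(y, 1.0, 1), y)

    def test_half_accuracy_noise_variance(self, rng):
        y = rng.normal(0, 2.0, size=200_000)
        y2 = add_prediction_noise(y, 0.5, seed=2)
        assert np.var(y2 - y) == pytest.approx(np.var(y), rel=0.02)

    @pytest.mark.parametrize("r2", [0.8, 0.5, 0.2])
    def test_empirical_squared_correlation(self, r2, rng):
        y = rng.normal(size=10_000)
        y2 = add_prediction_noise(y, r2, seed=3)
        got = np.corrcoef(y, y2)[0, 1] ** 2
        assert got == pytest.approx(r2, abs=0.03)

    def test_invalid_r2_rejected(self):
        with pytest.raises(ValueError):
            add_prediction_noise(np.ones(3), 0.0, 1)


@pytest.fixture(scope="module")
def setup():
    gm = gen_inbred_genotypes(150, 500, seed=15)
    rng = np.random.default_rng(16)
    return mean_fill(gm.dosages), rng.normal(size=150)


class TestPermutationThreshold:

    def test_monotone_in_alpha(self, setup):
        G, y = setup
        alphas = [0.05, 0.25, 0.5, 0.75, 0.95]
        thr = permutation_threshold(G, y, alphas, n_perm=200, seed=4)
        assert (np.diff(thr) >= 0).all()

    def test_alpha_one_is_max_of_minima(self, setup):
        G, y = setup
        thr = permutation_threshold(G, y, [1.0], n_perm=150, seed=5)[0]
        thr95 = permutation_threshold(G, y, [0.95], n_perm=150, seed=5)[0]
        assert thr >= thr95

    def test_reproducible_under_seed(self, setup):
        G, y = setup
        a = permutation_threshold(G, y, [0.05], n_perm=150, seed=6)
        b = permutation_threshold(G, y, [0.05], n_perm=150, seed=6)
        assert a[0] == b[0]


class TestMatchHits:
    def _gm(self):
        return gen_inbred_genotypes(100, 60, seed=17, ld_block_len=6,
                                    n_chrom=2, spacing_bp=500_000)

    def test_no_hits(self):
        gm = self._gm()
        q = spike_in_qtns(gm, n=3, maf_window=(0.05, 0.5), seed=18)
        detected, n_false = match_hits_to_qtns(np.array([]), q, gm)
        assert detected == set() and n_false == 0

    def test_hits_exactly_at_qtns(self):
        gm = self._gm()
        q = spike_in_qtns(gm, n=3, maf_window=(0.05, 0.5), seed=18)
        detected, n_false = match_hits_to_qtns(q.indices, q, gm)
        assert n_false == 0
        assert detected == set(int(i) for i in q.indices)

    def test_linked_and_unlinked_clusters(self):
        # 2 chroms x 30 snps; QTN at index 5; cluster at 4-6 linked,
        # cluster at 40-42 (chr2) unlinked
        gm = self._gm()
        D = gm.dosages.copy()
        D[:, 4] = D[:, 5]  # force perfect LD with the QTN
        rng = np.random.default_rng(19)
        D[:, 40] = rng.choice([0.0, 2.0], 100)
        D[:, 41] = rng.choice([0.0, 2.0], 100)
        gm = make_gm(D, positions=[v.pos for v in gm.variants],
                     chrom=[v.chrom for v in gm.variants])
        q = QTNSet(np.array([5]), np.array([1.0]), np.array([0.3]))
        detected, n_false = match_hits_to_qtns(
            np.array([4, 40, 41]), q, gm
        )
        assert detected == {5} and n_false == 1  # FDR would be 0.5


class TestSimOne:
    def test_grid_cardinality_at_study_scale(self):
        cfg = SimOneConfig()
        assert cfg.grid_size == 36
        assert cfg.total_scans == 18_000

    def test_smoke_run_monotone_in_population_size(self):
        cfg = SimOneConfig(
            population_sizes=(80, 400), accuracy_levels=(1.0,),
            reps=5, n_variants=1500, n_perm=100, seed=42,
        )
        gm = gen_inbred_genotypes(400, 1500, seed=42)
        grid = run_sim_one(cfg, gm)
        p_small = grid.power(80, 1.0, "major")
        p_large = grid.power(400, 1.0, "major")
        assert p_large >= p_small

    def test_oversized_population_rejected(self):
        cfg = SimOneConfig(population_sizes=(500,), accuracy_levels=(1.0,),
                           reps=1, n_variants=100)
        gm = gen_inbred_genotypes(100, 100, seed=1)
        with pytest.raises(ValueError, match="largest population"):
            run_sim_one(cfg, gm)


class TestSimTwo:
    def test_gradient_count_at_study_scale(self):
        assert SimTwoConfig().n_gradients == 19

    def test_zero_effect_has_no_power(self):
        gm = gen_inbred_genotypes(200, 800, seed=20)
        rng = np.random.default_rng(21)
        base = rng.normal(size=200)
        cfg = SimTwoConfig(gradients=(1e-9,), snps_per_gradient=30,
                           population_sizes=(200,), seed=22)
        out = run_sim_two(cfg, gm, base)
        assert out["power"].iloc[0] <= 0.05

    def test_empty_gradients_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SimTwoConfig(gradients=())


class TestFullStudyBundle:
    def test_truth_table_row_count(self):
        b = gen_full_study(seed=2)
        # 3 additive + dominant + masker + masked + 4 yield loci
        assert len(b.truth) == 10
        assert set(b.truth["trait"]) == {"flowering", "height", "yield"}

    def test_strong_additive_signal_with_low_noise(self):
        b = gen_full_study(seed=3, residual_sd=0.01, env_sd=0.0,
                           n_maternal=400, n_testers=2)
        from hybridforge.gwas import association_scan
        from hybridforge.pheno import fit_line_blup

        blup = fit_line_blup(b.traits, "flowering")
        mat = b.parents.subset_samples(b.design.maternal_ids)
        y = blup.reindex(b.design.maternal_ids).to_numpy()
        res = association_scan(mat, y, None)
        top = b.truth[b.truth["trait"] == "flowering"]["variant"].iloc[0]
        j = mat.variant_index()[top]
        assert res.table["p"][j] < 1e-20

    def test_reproducible_under_seed(self):
        a = gen_full_study(seed=5, n_maternal=40, n_testers=2)
        b = gen_full_study(seed=5, n_maternal=40, n_testers=2)
        np.testing.assert_array_equal(a.f1.dosages, b.f1.dosages)
        assert a.traits.df["value"].equals(b.traits.df["value"])
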