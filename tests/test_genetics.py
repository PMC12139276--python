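import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enteroguild import genetics, synthetic
from enteroguild.types import GRM, GenotypeMatrix


def _geno(dosages):
    dosages = np.asarray(dosages, dtype=float)
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=[f"snp{j}" for j in range(dosages.shape[1])],
        individual_ids=[f"i{j}" for j in range(dosages.shape[0])],
    )


class TestSnpQC:
    def test_low_maf_dropped_boundary_missing_kept(self):
        # snp0: MAF 0.04 -> dropped; snp1: exactly 10% missing -> kept;
        # snp2: 20% missing -> dropped; snp3/4: clean -> kept
        n = 50
        rng = np.random.default_rng(0)
        dos = np.column_stack(
            [
                np.concatenate([np.ones(4), np.zeros(n - 4)]),  # freq 0.04
                rng.binomial(2, 0.3, n).astype(float),
                rng.binomial(2, 0.3, n).astype(float),
                rng.binomial(2, 0.4, n).astype(float),
                rng.binomial(2, 0.25, n).astype(float),
            ]
        )
        dos[:5, 1] = np.nan  # 10% exactly
        dos[:10, 2] = np.nan  # 20%
        out = genetics.snp_qc(_geno(dos), maf_min=0.05, missing_max=0.10)
        assert out.snp_ids == ["snp1", "snp3", "snp4"]
        assert np.isfinite(out.dosages).all()

    def test_mean_imputation_value(self):
        dos = np.array([[0.0], [2.0], [np.nan], [2.0]])
        out = genetics.snp_qc(_geno(dos), maf_min=0.0, missing_max=0.5)
        # observed freq = 4/6, imputed value = 2p = 4/3
        assert out.dosages[2, 0] == pytest.approx(4 / 3)

    def test_keep_list_restricts_panel(self):
        rng = np.random.default_rng(1)
        dos = rng.binomial(2, 0.3, size=(40, 5)).astype(float)
        out = genetics.snp_qc(_geno(dos), keep_list=["snp0", "snp3"])
        assert out.snp_ids == ["snp0", "snp3"]

    def test_all_dropped_is_error(self):
        dos = np.zeros((20, 2))
        with pytest.raises(ValueError, match="all SNPs"):
            genetics.snp_qc(_geno(dos))


class TestVanRadenGRM:
    def test_hand_computed_single_snp(self):
        g = _geno([[0.0], [1.0], [2.0]])
        grm = genetics.vanraden_grm(g)  # observed p = 0.5
        expected = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
        np.testing.assert_allclose(grm.G, expected, atol=1e-12)
        assert grm.scaling == pytest.approx(0.5)

    def test_all_mean_individual_has_zero_row(self):
        g = _geno([[0.0, 2.0], [2.0, 0.0], [1.0, 1.0]])
        grm = genetics.vanraden_grm(g)
        np.testing.assert_allclose(grm.G[2], 0.0, atol=1e-12)

    def test_hwe_simulation_mean_diagonal_near_one(self):
        g = synthetic.simulate_genotypes(400, 2000, 0.05, 0.5, 0.0, seed=2)
        grm = genetics.vanraden_grm(g)
        assert 0.95 <= np.diag(grm.G).mean() <= 1.05

    def test_duplicating_individual_preserves_others(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, 0.3, size=(10, 50)).astype(float)
        p = dos.mean(axis=0) / 2
        grm = genetics.vanraden_grm(_geno(dos), allele_freqs=p)
        dup = np.vstack([dos, dos[0]])
        g2 = GenotypeMatrix(
            dosages=dup,
            snp_ids=[f"snp{j}" for j in range(50)],
            individual_ids=[f"i{j}" for j in range(11)],
        )
        grm2 = genetics.vanraden_grm(g2, allele_freqs=p)
        np.testing.assert_allclose(grm2.G[:10, :10], grm.G, atol=1e-12)
        np.testing.assert_allclose(grm2.G[10, :10], grm.G[0], atol=1e-12)

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError, match="scaling"):
            genetics.vanraden_grm(_geno(np.zeros((5, 3))))

    def test_missing_dosages_rejected(self):
        dos = np.array([[0.0, np.nan], [1.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            genetics.vanraden_grm(_geno(dos))


class TestGblupGibbs:
    def test_per_draw_identity_and_determinism(self):
        g = synthetic.simulate_genotypes(80, 300, seed=4)
        grm = genetics.vanraden_grm(g)
        y, _ = synthetic.simulate_heritable_es(g, 0.4, 50, seed=5)
        a = genetics.gblup_gibbs(y, np.ones((80, 1)), grm, n_iter=2000, burn_in=200, thin=2, seed=6)
        b = genetics.gblup_gibbs(y, np.ones((80, 1)), grm, n_iter=2000, burn_in=200, thin=2, seed=6)
        np.testing.assert_array_equal(a.h2, b.h2)
        np.testing.assert_array_equal(a.h2, a.sigma2_a / (a.sigma2_a + a.sigma2_e))

    def test_eigen_and_naive_samplers_agree(self):
        # independent cross-check on a small strictly-PD kernel
        rng = np.random.default_rng(7)
        n = 50
        Z = rng.normal(size=(n, 120))
        G = Z @ Z.T / 120 + 0.05 * np.eye(n)
        grm = GRM(G=(G + G.T) / 2, individual_ids=[f"i{j}" for j in range(n)], scaling=1.0)
        u = np.linalg.cholesky(grm.G) @ rng.standard_normal(n) * np.sqrt(0.4)
        y = u + rng.normal(scale=np.sqrt(0.6), size=n)
        X = np.ones((n, 1))
        eig = genetics.gblup_gibbs(y, X, grm, n_iter=12000, burn_in=2000, thin=2, seed=8)
        naive = genetics.gblup_gibbs_naive(y, X, grm, n_iter=12000, burn_in=2000, thin=2, seed=9)
        # agreement within Monte-Carlo error of two short chains
        assert eig.sigma2_a.mean() == pytest.approx(naive.sigma2_a.mean(), abs=0.12)
        assert eig.h2.mean() == pytest.approx(naive.h2.mean(), abs=0.08)

    def test_heritable_signal_ranks_above_null(self):
        # direction sanity at the sampler's identification limit: the
        # posterior mean for data with h2=0.3 exceeds the null data's
        g = synthetic.simulate_genotypes(200, 1000, seed=10)
        grm = genetics.vanraden_grm(g)
        y1, _ = synthetic.simulate_heritable_es(g, 0.6, 200, seed=11)
        y0 = np.random.default_rng(12).normal(size=200)
        X = np.ones((200, 1))
        p1 = genetics.gblup_gibbs(y1, X, grm, n_iter=6000, burn_in=500, thin=2, seed=13)
        p0 = genetics.gblup_gibbs(y0, X, grm, n_iter=6000, burn_in=500, thin=2, seed=13)
        assert p1.h2.mean() > p0.h2.mean()

    def test_short_burn_in_warns(self):
        g = synthetic.simulate_genotypes(40, 100, seed=14)
        grm = genetics.vanraden_grm(g)
        y = np.random.default_rng(15).normal(size=40)
        with pytest.warns(RuntimeWarning, match="burn-in"):
            genetics.gblup_gibbs(y, np.ones((40, 1)), grm, n_iter=3000, burn_in=20, thin=2, seed=16)

    def test_dimension_mismatch_rejected(self):
        g = synthetic.simulate_genotypes(30, 50, seed=17)
        grm = genetics.vanraden_grm(g)
        with pytest.raises(ValueError, match="dimension"):
            genetics.gblup_gibbs(np.ones(10), np.ones((10, 1)), grm, n_iter=100)


class TestBuildDesign:
    def test_factor_dummies_and_centered_covariate(self):
        rng = np.random.default_rng(0)
        meta = pd.DataFrame(
            {
                "batch": rng.choice(["a", "b", "c"], 30),
                "sex": rng.choice(["M", "F"], 30),
                "age": rng.normal(60, 8, 30),
            }
        )
        X, names = genetics.build_design(meta)
        assert names[0] == "intercept"
        assert X.shape == (30, 1 + 2 + 1 + 1)
        assert X[:, -1].sum() == pytest.approx(0.0, abs=1e-9)

    def test_rank_deficiency_detected(self):
        meta = pd.DataFrame({"batch": ["a", "b", "a", "b"], "sex": ["M", "F", "M", "F"]})
        with pytest.raises(ValueError, match="rank deficient"):
            genetics.build_design(meta, factors=("batch", "sex"), covariates=())


class TestHPD:
    def test_constant_draws(self):
        lo, hi = genetics.hpd_interval(np.full(200, 0.3))
        assert (lo, hi) == (0.3, 0.3)

    def test_grid_matches_bruteforce(self):
        draws = np.arange(100) / 100.0
        lo, hi = genetics.hpd_interval(draws, 0.95)
        m = int(np.ceil(0.95 * 100))
        xs = np.sort(draws)
        widths = [(xs[i + m - 1] - xs[i], xs[i], xs[i + m - 1]) for i in range(100 - m + 1)]
        bw, blo, bhi = min(widths)
        assert (lo, hi) == (blo, bhi)

    def test_hpd_narrower_than_equal_tail_for_skewed_posterior(self):
        rng = np.random.default_rng(18)
        draws = rng.beta(30, 70, size=20000)
        lo, hi = genetics.hpd_interval(draws, 0.95)
        qlo, qhi = np.quantile(draws, [0.025, 0.975])
        assert (hi - lo) < (qhi - qlo)

    def test_summary_needs_draws(self):
        g = synthetic.simulate_genotypes(30, 100, seed=19)
        grm = genetics.vanraden_grm(g)
        y = np.random.default_rng(20).normal(size=30)
        post = genetics.gblup_gibbs(y, np.ones((30, 1)), grm, n_iter=400, burn_in=200, thin=5, seed=21)
        with pytest.raises(ValueError, match="100"):
            genetics.h2_summary(post)
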