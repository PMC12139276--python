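import numpy as np
import pandas as pd
import pytest

from enteroguild import synthetic
from enteroguild.types import SampleESFractions


class TestSimulateGuilds:
    def test_driver_dominates_and_columns_stochastic(self):
        t = synthetic.simulate_guilds(10, 2, driver_weight=0.6, sparsity=0.5, seed=1)
        assert np.allclose(t.W_true.sum(axis=0), 1.0)
        assert (t.W_true.max(axis=0) >= 0.6).all()
        assert len(set(t.driver_ids)) == 2

    def test_driver_is_unique_argmax_even_with_codominance(self):
        # driver weight low enough that another genus can sit close behind
        t = synthetic.simulate_guilds(80, 5, driver_weight=0.45, sparsity=0.5, seed=3)
        for j in range(5):
            col = t.W_true[:, j]
            order = np.sort(col)[::-1]
            assert order[0] > order[1]  # strict argmax
            assert t.genus_ids[int(np.argmax(col))] == t.driver_ids[j]

    def test_deterministic_under_seed(self):
        a = synthetic.simulate_guilds(20, 3, seed=7)
        b = synthetic.simulate_guilds(20, 3, seed=7)
        np.testing.assert_array_equal(a.W_true, b.W_true)
        assert a.driver_ids == b.driver_ids

    def test_rejects_more_guilds_than_genera(self):
        with pytest.raises(ValueError):
            synthetic.simulate_guilds(3, 4)


class TestSimulateSamples:
    def test_deep_sequencing_recovers_expected_composition(self, small_guild_truth):
        # law of large numbers: at depth 1e6 the empirical column
        # frequencies approach W_true @ H_true column-wise
        table, st = synthetic.simulate_samples(
            small_guild_truth, 5, depth_log_mean=float(np.log(1e6)), depth_log_sd=0.0, seed=2
        )
        expected = small_guild_truth.W_true @ st.H_true
        freqs = table.counts / table.counts.sum(axis=0)
        l1 = np.abs(freqs - expected).sum(axis=0)
        assert (l1 <= 0.01).all()

    def test_mean_guild_fraction_matches_dirichlet_moment(self, small_guild_truth):
        # symmetric Dirichlet(1,..,1) over k=4 guilds has mean 1/4;
        # Monte-Carlo oracle at n=400
        _, st = synthetic.simulate_samples(small_guild_truth, 400, seed=3)
        assert np.allclose(st.H_true.mean(axis=1), 0.25, atol=0.05)

    def test_zero_weight_genus_gets_zero_counts(self, small_guild_truth):
        table, _ = synthetic.simulate_samples(
            small_guild_truth, 50, depth_log_mean=float(np.log(1e5)), seed=4
        )
        zero_rows = np.flatnonzero(small_guild_truth.W_true.sum(axis=1) == 0)
        assert (table.counts[zero_rows] == 0).all()

    def test_rejects_nonpositive_sample_count(self, small_guild_truth):
        with pytest.raises(ValueError):
            synthetic.simulate_samples(small_guild_truth, 0)

    def test_deterministic_under_seed(self, small_guild_truth):
        t1, s1 = synthetic.simulate_samples(small_guild_truth, 20, seed=9)
        t2, s2 = synthetic.simulate_samples(small_guild_truth, 20, seed=9)
        np.testing.assert_array_equal(t1.counts, t2.counts)
        np.testing.assert_array_equal(s1.H_true, s2.H_true)

    def test_stress_shift_moves_group_means_by_stated_amount(self, small_guild_truth):
        g0, g1 = small_guild_truth.guild_names[:2]
        _, st = synthetic.simulate_samples(
            small_guild_truth, 2000, seed=5, stress_shift={g0: -0.1, g1: +0.1}
        )
        stressed = st.group_labels["group"].to_numpy() == "stress"
        diff = st.H_true[:, stressed].mean(axis=1) - st.H_true[:, ~stressed].mean(axis=1)
        assert diff[0] == pytest.approx(-0.1, abs=0.02)
        assert diff[1] == pytest.approx(+0.1, abs=0.02)

    def test_unknown_guild_in_stress_shift(self, small_guild_truth):
        with pytest.raises(ValueError, match="unknown guild"):
            synthetic.simulate_samples(small_guild_truth, 5, stress_shift={"nope": 0.1})


class TestSimulateGenotypes:
    def test_empirical_frequencies_match_drawn(self):
        g = synthetic.simulate_genotypes(400, 2000, 0.05, 0.5, 0.0, seed=1)
        emp = g.allele_freqs()
        # binomial CI oracle: sd of p-hat is sqrt(p(1-p)/(2n)) <= 0.018,
        # so |emp - p| < 0.06 is a >3-sigma band per SNP
        frac_ok = np.mean(np.abs(emp - g.true_freqs) < 0.06)
        assert frac_ok >= 0.95

    def test_no_missing_when_rate_zero(self):
        g = synthetic.simulate_genotypes(50, 100, missing_rate=0.0, seed=2)
        assert np.isfinite(g.dosages).all()

    def test_missing_rate_realized(self):
        g = synthetic.simulate_genotypes(200, 500, missing_rate=0.1, seed=3)
        assert np.mean(~np.isfinite(g.dosages)) == pytest.approx(0.1, abs=0.01)

    def test_half_frequency_gives_mean_dosage_one(self):
        g = synthetic.simulate_genotypes(500, 200, maf_low=0.5, maf_high=0.5, seed=4)
        assert g.dosages.mean() == pytest.approx(1.0, abs=0.02)

    def test_rejects_bad_frequency_range(self):
        with pytest.raises(ValueError):
            synthetic.simulate_genotypes(10, 10, maf_low=0.4, maf_high=0.2)


class TestSimulateHeritableES:
    def test_zero_heritability_means_no_genetic_values(self):
        g = synthetic.simulate_genotypes(100, 200, seed=5)
        y, truth = synthetic.simulate_heritable_es(g, 0.0, 50, seed=6)
        assert (truth.u_true == 0).all()
        assert (truth.causal_effects == 0).all()

    def test_realized_variance_ratio_near_target(self):
        # Monte-Carlo oracle: ratio var(u)/(var(u)+var(e)) across 10 seeds
        ratios = []
        for seed in range(10):
            g = synthetic.simulate_genotypes(400, 500, seed=seed)
            y, truth = synthetic.simulate_heritable_es(g, 0.30, 100, seed=seed + 50)
            e = y - truth.u_true
            ratios.append(truth.u_true.var() / (truth.u_true.var() + e.var()))
        assert all(0.2 <= r <= 0.4 for r in ratios)

    def test_doubling_genetic_values_renormalizes_h2(self):
        # closed form: h2' = 4v/(4v + e) when u doubles and e is unchanged
        g = synthetic.simulate_genotypes(200, 300, seed=7)
        y, truth = synthetic.simulate_heritable_es(g, 0.30, 50, seed=8)
        e = y - truth.u_true
        v, w = truth.u_true.var(), e.var()
        h2_doubled = (4 * v) / (4 * v + w)
        assert h2_doubled == pytest.approx(4 * v / (4 * v + w))
        assert h2_doubled > v / (v + w)

    def test_rejects_h2_of_one(self):
        g = synthetic.simulate_genotypes(10, 20, seed=9)
        with pytest.raises(ValueError):
            synthetic.simulate_heritable_es(g, 1.0, 5)

    def test_fixed_design_shifts_phenotype(self):
        g = synthetic.simulate_genotypes(200, 100, seed=10)
        meta = pd.DataFrame(
            {"batch": ["b1"] * 100 + ["b2"] * 100, "age": np.linspace(50, 70, 200)}
        )
        y0, _ = synthetic.simulate_heritable_es(g, 0.2, 20, seed=11)
        y1, _ = synthetic.simulate_heritable_es(g, 0.2, 20, fixed_design=meta, seed=11)
        assert not np.allclose(y0, y1)


class TestSimulateTraits:
    def test_noise_free_trait_is_collinear_with_guild(self, small_guild_truth):
        _, st = synthetic.simulate_samples(small_guild_truth, 60, seed=12)
        name = small_guild_truth.guild_names[2]
        tr = synthetic.simulate_traits(st, [(name, "bw", 5.0)], noise_sd=0.0, seed=13)
        r = np.corrcoef(tr["bw"], st.H_true[2])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_guild_rejected(self, small_guild_truth):
        _, st = synthetic.simulate_samples(small_guild_truth, 10, seed=14)
        with pytest.raises(ValueError, match="unknown guild"):
            synthetic.simulate_traits(st, [("missing", "bw", 1.0)])

    def test_negative_cortisol_association_is_detectable(self, small_guild_truth):
        # regression power oracle at the stress-cohort size n=91
        from enteroguild.association import es_trait_regression

        hits = 0
        for seed in range(10):
            _, st = synthetic.simulate_samples(small_guild_truth, 91, seed=seed + 20)
            name = small_guild_truth.guild_names[0]
            tr = synthetic.simulate_traits(st, [(name, "cortisol", -1.0)], 0.1, seed=seed)
            fr = SampleESFractions(
                fractions=st.H_true / st.H_true.sum(axis=0),
                sample_ids=list(st.group_labels["sample_id"]),
                es_names=small_guild_truth.guild_names,
            )
            res = es_trait_regression(fr, tr["cortisol"], "cortisol")
            row = res[res["es"] == name].iloc[0]
            hits += (row["slope"] < 0) and (row["p"] < 0.05)
        assert hits >= 9
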