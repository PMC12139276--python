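import numpy as np
import pytest

from enteroguild import characterize
from enteroguild.types import ESDecomposition, SampleESFractions


def _dec(W, H=None, genus_ids=None):
    W = np.asarray(W, dtype=float)
    k = W.shape[1]
    if H is None:
        H = np.ones((k, 3))
    H = np.asarray(H, dtype=float)
    return ESDecomposition(
        W=W,
        H=H,
        k=k,
        loss=0.0,
        n_iter=0,
        seed=0,
        genus_ids=genus_ids or [f"g{i}" for i in range(W.shape[0])],
        sample_ids=[f"s{j}" for j in range(H.shape[1])],
    )


class TestMakeProfile:
    def test_dominant_genus_becomes_driver_and_name(self):
        W = np.array([[0.60], [0.25], [0.15]])
        prof = characterize.make_profile(
            _dec(np.column_stack([W[:, 0], [0.1, 0.1, 0.8]]),
                 genus_ids=["Clostridium", "Prevotella", "Lactobacillus"])
        )
        assert prof.driver_genus[0] == "Clostridium"
        assert prof.es_names[0] == "ES-Clos"

    def test_codominant_column_takes_the_larger_genus(self):
        W = np.array([[0.48, 0.2], [0.45, 0.2], [0.07, 0.6]])
        prof = characterize.make_profile(_dec(W, genus_ids=["A", "B", "C"]))
        assert prof.driver_genus[0] == "A"

    def test_exact_tie_breaks_lexicographically_with_warning(self):
        W = np.array([[0.5, 0.1], [0.5, 0.1], [0.0, 0.8]])
        with pytest.warns(RuntimeWarning, match="tie"):
            prof = characterize.make_profile(_dec(W, genus_ids=["Zeta", "Alpha", "Mu"]))
        assert prof.driver_genus[0] == "Alpha"

    def test_normalizations_and_reconstruction_identity(self):
        rng = np.random.default_rng(1)
        W = rng.random((8, 3))
        prof = characterize.make_profile(_dec(W))
        np.testing.assert_allclose(prof.contributions.sum(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(prof.assignment_prob.sum(axis=1), 1.0, atol=1e-12)
        # W is recoverable from contributions and the original column masses
        np.testing.assert_allclose(prof.contributions * W.sum(axis=0), W, atol=1e-12)

    def test_zero_weight_row_flagged_not_normalized(self):
        W = np.array([[0.6, 0.3], [0.0, 0.0], [0.4, 0.7]])
        prof = characterize.make_profile(_dec(W))
        assert prof.zero_weight_genera == ["g1"]
        np.testing.assert_array_equal(prof.assignment_prob[1], 0.0)

    def test_degenerate_all_zero_column_rejected(self):
        W = np.array([[0.6, 0.0], [0.4, 0.0]])
        with pytest.raises(ValueError, match="degenerate"):
            characterize.make_profile(_dec(W))

    def test_name_collision_gets_suffix(self):
        W = np.array([[0.6, 0.1], [0.1, 0.6], [0.3, 0.3]])
        prof = characterize.make_profile(
            _dec(W, genus_ids=["Lactobacillus", "Lactococcus", "Other"])
        )
        assert len(set(prof.es_names)) == 2


class TestSampleFractions:
    def test_columns_normalized(self):
        H = np.array([[2.0, 1.0], [2.0, 0.0]])
        fr = characterize.sample_fractions(_dec(np.eye(2), H=H))
        np.testing.assert_allclose(fr.fractions[:, 0], [0.5, 0.5])
        np.testing.assert_allclose(fr.fractions[:, 1], [1.0, 0.0])

    def test_invariant_to_per_sample_rescaling(self):
        rng = np.random.default_rng(2)
        H = rng.random((3, 5)) + 0.1
        scale = rng.random(5) * 10 + 0.5
        a = characterize.sample_fractions(_dec(rng.random((4, 3)), H=H))
        b = characterize.sample_fractions(_dec(rng.random((4, 3)), H=H * scale))
        np.testing.assert_allclose(a.fractions, b.fractions, atol=1e-12)

    def test_zero_column_rejected_with_sample_name(self):
        H = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="s1"):
            characterize.sample_fractions(_dec(np.eye(2), H=H))


class TestTopContributors:
    def test_threshold_boundary(self):
        W = np.array([[0.039, 0.039], [0.05, 0.02], [0.911, 0.941]])
        prof = characterize.make_profile(_dec(W))
        table = characterize.top_contributors(prof, 0.04)
        assert "g0" not in table.index  # 0.039 everywhere -> pooled
        assert "g1" in table.index  # 0.05 in one signature is enough
        np.testing.assert_allclose(table.sum(axis=0), 1.0, atol=1e-12)

    def test_listed_set_matches_enumeration(self):
        rng = np.random.default_rng(3)
        W = rng.dirichlet(np.ones(10), size=3).T
        prof = characterize.make_profile(_dec(W))
        table = characterize.top_contributors(prof, 0.04)
        expected = {f"g{i}" for i in range(10) if (prof.contributions[i] > 0.04).any()}
        assert set(table.index) - {"others"} == expected


class TestMinimalESSet:
    def _fractions(self, cols):
        cols = np.asarray(cols, dtype=float).T
        return SampleESFractions(
            fractions=cols,
            sample_ids=[f"s{j}" for j in range(cols.shape[1])],
            es_names=[f"ES{i}" for i in range(cols.shape[0])],
        )

    def test_cumulative_coverage_rule(self):
        fr = self._fractions([[0.5, 0.3, 0.15, 0.05]] * 4)
        out = characterize.minimal_es_set(fr, ["a"] * 4, coverage=0.9)
        assert out["groups"]["a"]["n_min"] == 3
        assert out["groups"]["a"]["primary_es"] == "ES0"

    def test_single_dominant_signature(self):
        fr = self._fractions([[1.0, 0.0]] * 3)
        out = characterize.minimal_es_set(fr, ["x"] * 3, coverage=0.9)
        assert out["groups"]["x"]["n_min"] == 1

    def test_full_coverage_needs_all_positive_signatures(self):
        fr = self._fractions([[0.4, 0.35, 0.25]] * 3)
        out = characterize.minimal_es_set(fr, ["x"] * 3, coverage=1.0)
        assert out["groups"]["x"]["n_min"] == 3

    def test_monotone_in_coverage(self):
        rng = np.random.default_rng(4)
        fr = self._fractions(rng.dirichlet(np.ones(5), size=30))
        labels = ["a"] * 15 + ["b"] * 15
        prev = 0
        for cov in (0.5, 0.7, 0.9, 0.99):
            out = characterize.minimal_es_set(fr, labels, coverage=cov)
            n = out["groups"]["a"]["n_min"]
            assert n >= prev
            prev = n

    def test_frequency_across_groups(self):
        fr = self._fractions([[0.9, 0.1]] * 2 + [[0.1, 0.9]] * 2)
        out = characterize.minimal_es_set(fr, ["a", "a", "b", "b"], coverage=0.8)
        assert out["es_frequency"]["ES0"] == 0.5
        assert out["es_frequency"]["ES1"] == 0.5


class TestMatchES:
    def test_profile_matches_itself_identically(self):
        rng = np.random.default_rng(5)
        prof = characterize.make_profile(_dec(rng.random((12, 4))))
        m = characterize.match_es(prof, prof)
        assert m["mean_cosine"] == pytest.approx(1.0, abs=1e-12)
        assert all(p["es_a"] == p["es_b"] for p in m["pairs"])

    def test_permuted_columns_recovered(self):
        rng = np.random.default_rng(6)
        W = rng.random((12, 4))
        perm = [2, 0, 3, 1]
        a = characterize.make_profile(_dec(W))
        b = characterize.make_profile(_dec(W[:, perm]))
        m = characterize.match_es(a, b)
        mapping = {p["es_a"]: p["es_b"] for p in m["pairs"]}
        for j, pj in enumerate(perm):
            assert mapping[a.es_names[pj]] == b.es_names[j]
        assert m["mean_cosine"] == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_genus_universes_rejected(self):
        a = characterize.make_profile(_dec(np.eye(3) + 0.1, genus_ids=["a", "b", "c"]))
        b = characterize.make_profile(_dec(np.eye(3) + 0.1, genus_ids=["x", "y", "z"]))
        with pytest.raises(ValueError, match="no genera"):
            characterize.match_es(a, b)
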