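"""Likelihood engine: oracle equivalence, closed forms, fit properties."""

import numpy as np
import pytest

from conftest import random_leaf_pattern, random_tree
from coevosite import oracle
from coevosite.phylo import (
    ConservationPattern,
    OptimizerSettings,
    PairScore,
    PatternError,
    Phylogeny,
    PhylogenyError,
    classify_pair,
    fit_pair,
    fit_pair_batch,
    fit_sigma,
    fit_sigma_batch,
    log_weight_sum,
    pair_loglik,
    pair_loglik_batch,
    site_loglik,
    site_loglik_batch,
)


class TestLogWeightSum:
    def test_decoupled_zero_field_counts_configurations(self):
        """Every free node contributes a factor 2 when beta = h = sigma = 0."""
        t = Phylogeny(("r", "a", "b"), np.array([-1, 0, 0]), np.zeros(3), np.zeros(3), 1)
        assert log_weight_sum(t) == pytest.approx(3 * np.log(2), abs=1e-12)

    def test_perfect_coupling_limit(self):
        """With both leaves clamped present and huge beta the agreement term
        dominates and the root is forced present."""
        t = Phylogeny(
            ("r", "a", "b"), np.array([-1, 0, 0]), np.array([0.0, 60.0, 60.0]), np.zeros(3), 1
        )
        val = log_weight_sum(t, {"a": 1, "b": 1})
        assert val == pytest.approx(120.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        t = random_tree(rng, n)
        clamps = {}
        for v in t.leaves[: max(1, t.leaves.size // 2)]:
            clamps[int(v)] = int(rng.integers(0, 2))
        got = log_weight_sum(t, clamps, 0.5)
        want = oracle.enum_log_weight_sum(t, clamps, 0.5)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_clamp_on_unknown_node_rejected(self):
        t = Phylogeny(("r", "a", "b"), np.array([-1, 0, 0]), np.zeros(3), np.zeros(3), 1)
        with pytest.raises(PhylogenyError):
            log_weight_sum(t, {"zz": 1})

    def test_bit_identical_across_calls(self):
        rng = np.random.default_rng(3)
        t = random_tree(rng, 9)
        clamps = {int(t.leaves[0]): 1}
        assert log_weight_sum(t, clamps, 0.3) == log_weight_sum(t, clamps, 0.3)


class TestSiteLoglik:
    def test_decoupled_star_closed_form(self, star_tree):
        """On a star with beta = 0 the hidden nodes cancel and the likelihood
        is a product of independent Bernoulli terms: k(h+s) - n log(1+e^(h+s))."""
        h, s = 0.4, 0.7
        t = star_tree.with_params(h=np.full(6, h))
        for k in range(5):
            lv = np.array([1] + [1] * k + [0] * (4 - k), dtype=np.int8)
            got = float(site_loglik_batch(t, lv, s))
            want = k * (h + s) - 4 * np.log1p(np.exp(h + s))
            assert got == pytest.approx(want, abs=1e-10)

    def test_deterministic_conservation_limit(self):
        """All-present data under near-infinite coupling has probability ~1."""
        t = Phylogeny(
            ("r", "ref", "a", "b"),
            np.array([-1, 0, 0, 0]),
            np.array([0.0, 50.0, 50.0, 50.0]),
            np.zeros(4),
            1,
        )
        ll = float(site_loglik_batch(t, np.array([1, 1, 1]), 0.0))
        assert ll == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 4, 9])
    def test_normalization_over_observable_patterns(self, seed):
        """exp(site_loglik) sums to 1 over all 2^(n-1) observable patterns."""
        rng = np.random.default_rng(seed)
        t = random_tree(rng, 9)
        nl = t.leaves.size
        ref_col = int(np.flatnonzero(t.leaves == t.reference)[0])
        total = 0.0
        for bits in range(2 ** (nl - 1)):
            lv = np.zeros(nl, dtype=np.int8)
            others = [i for i in range(nl) if i != ref_col]
            for j, col in enumerate(others):
                lv[col] = (bits >> j) & 1
            lv[ref_col] = 1
            total += np.exp(float(site_loglik_batch(t, lv, 0.7)))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_reference_absent_rejected(self):
        rng = np.random.default_rng(0)
        t = random_tree(rng, 7)
        lv = np.zeros(t.leaves.size, dtype=np.int8)
        with pytest.raises(PatternError):
            site_loglik_batch(t, lv, 0.0)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            t = random_tree(rng, int(rng.integers(5, 10)))
            lv = random_leaf_pattern(rng, t)
            sigma = float(rng.uniform(-2, 2))
            got = float(site_loglik_batch(t, lv, sigma))
            want = oracle.enum_site_loglik(t, lv, sigma)
            assert got == pytest.approx(want, rel=1e-11, abs=1e-11)


class TestFitSigma:
    def test_star_tree_logit_closed_form(self, star_tree):
        """sigma_hat = logit(k/n) - h on the decoupled star tree."""
        lv = np.array([[1, 1, 1, 1, 0]], dtype=np.int8)  # k=3 of n=4
        s, llh, ll0 = fit_sigma_batch(star_tree, lv)
        assert s[0] == pytest.approx(np.log(3), abs=1e-4)
        assert llh[0] >= ll0[0]

    def test_background_typical_pattern_gives_zero_score(self):
        """A pattern at the background mode has sigma_hat = 0 and D = 0."""
        h = np.log(3)  # background presence probability 3/4
        t = Phylogeny(
            ("r", "ref", "a", "b", "c", "d"),
            np.array([-1, 0, 0, 0, 0, 0]),
            np.zeros(6),
            np.array([0.0, 0.0, h, h, h, h]),
            1,
        )
        lv = np.array([[1, 1, 1, 1, 0]], dtype=np.int8)  # k/n = 3/4 = e^h/(1+e^h)
        s, llh, ll0 = fit_sigma_batch(t, lv)
        assert s[0] == pytest.approx(0.0, abs=1e-4)
        assert llh[0] - ll0[0] == pytest.approx(0.0, abs=1e-8)

    def test_monotone_in_added_presence(self):
        """Flipping one species from absent to present never lowers sigma_hat."""
        rng = np.random.default_rng(5)
        t = random_tree(rng, 11)
        lv = random_leaf_pattern(rng, t)
        ref_col = int(np.flatnonzero(t.leaves == t.reference)[0])
        s0, _, _ = fit_sigma_batch(t, lv[None, :])
        for col in range(lv.size):
            if col == ref_col or lv[col] == 1:
                continue
            lv2 = lv.copy()
            lv2[col] = 1
            s1, _, _ = fit_sigma_batch(t, lv2[None, :])
            assert s1[0] >= s0[0] - 1e-6

    def test_scalar_api_returns_site_score(self, star_tree):
        pat = ConservationPattern("s", "g", {"ref": 1, "a": 1, "b": 1, "c": 1, "d": 0})
        score = fit_sigma(star_tree, pat)
        assert score.sigma_hat == pytest.approx(np.log(3), abs=1e-4)
        assert score.D >= -1e-6


class TestPairLoglik:
    def test_factorizes_at_zero_coupling(self):
        rng = np.random.default_rng(2)
        t = random_tree(rng, 9)
        lvX = random_leaf_pattern(rng, t)
        lvY = random_leaf_pattern(rng, t)
        pair = float(pair_loglik_batch(t, t, lvX, lvY, 0.4, -0.3, 0.0))
        single = float(site_loglik_batch(t, lvX, 0.4)) + float(site_loglik_batch(t, lvY, -0.3))
        assert pair == pytest.approx(single, abs=1e-10)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(4):
            t = random_tree(rng, 7)
            lvX = random_leaf_pattern(rng, t)
            lvY = random_leaf_pattern(rng, t)
            got = float(pair_loglik_batch(t, t, lvX, lvY, 0.3, -0.2, 0.7))
            want = oracle.enum_pair_loglik(t, t, lvX, lvY, 0.3, -0.2, 0.7)
            assert got == pytest.approx(want, rel=1e-11, abs=1e-11)

    def test_symmetric_under_site_swap(self):
        rng = np.random.default_rng(13)
        t = random_tree(rng, 8)
        lvX = random_leaf_pattern(rng, t)
        lvY = random_leaf_pattern(rng, t)
        a = float(pair_loglik_batch(t, t, lvX, lvY, 0.5, -0.1, 0.9))
        b = float(pair_loglik_batch(t, t, lvY, lvX, -0.1, 0.5, 0.9))
        assert a == pytest.approx(b, abs=1e-10)

    def test_topology_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        t1 = random_tree(rng, 7)
        t2 = random_tree(rng, 9)
        p1 = ConservationPattern("x", "g", {t1.names[v]: 1 for v in t1.leaves})
        with pytest.raises(PhylogenyError):
            pair_loglik(t1, t2, p1, p1, 0.0, 0.0, 0.0)


class TestFitPair:
    def test_identical_patterns_positively_coupled(self, star_tree):
        lv = np.array([1, 1, 0, 1, 0], dtype=np.int8)
        res = fit_pair_batch(star_tree, star_tree, lv[None, :], lv[None, :])
        assert res["J"][0] > 0
        assert (res["loglik_joint"] - res["loglik_indep"])[0] > 0

    def test_complementary_patterns_negatively_coupled(self, star_tree):
        lvX = np.array([1, 1, 1, 0, 0], dtype=np.int8)
        lvY = np.array([1, 0, 0, 1, 1], dtype=np.int8)
        res = fit_pair_batch(star_tree, star_tree, lvX[None, :], lvY[None, :])
        assert res["J"][0] < 0

    def test_deltaL_nonnegative_and_swap_invariant(self):
        rng = np.random.default_rng(21)
        t = random_tree(rng, 9)
        lvX = np.stack([random_leaf_pattern(rng, t) for _ in range(6)])
        lvY = np.stack([random_leaf_pattern(rng, t) for _ in range(6)])
        res = fit_pair_batch(t, t, lvX, lvY)
        dl = res["loglik_joint"] - res["loglik_indep"]
        assert np.all(dl >= -1e-6)
        res_sw = fit_pair_batch(t, t, lvY, lvX)
        dl_sw = res_sw["loglik_joint"] - res_sw["loglik_indep"]
        assert np.allclose(dl, dl_sw, atol=1e-4)

    def test_matches_dense_grid_search(self):
        """deltaL agrees with an independent coarse-global + fine-local grid
        search (step 0.01) on a small tree."""
        rng = np.random.default_rng(11)
        t = random_tree(rng, 7)
        lvX = random_leaf_pattern(rng, t)
        lvY = random_leaf_pattern(rng, t)
        res = fit_pair_batch(t, t, lvX[None, :], lvY[None, :])
        dl_fit = float(res["loglik_joint"][0] - res["loglik_indep"][0])

        def gridmax(c1, c2, c3, w, step):
            s1 = np.arange(c1 - w, c1 + w + 1e-9, step)
            s2 = np.arange(c2 - w, c2 + w + 1e-9, step)
            js = np.arange(c3 - w, c3 + w + 1e-9, step)
            best, arg = -np.inf, None
            for j in js:
                S1, S2 = np.meshgrid(s1, s2, indexing="ij")
                ll = pair_loglik_batch(
                    t, t, lvX, lvY, S1.ravel(), S2.ravel(), np.full(S1.size, float(j))
                )
                i = int(np.argmax(ll))
                if ll[i] > best:
                    best, arg = float(ll[i]), (S1.ravel()[i], S2.ravel()[i], float(j))
            return best, arg

        _, coarse = gridmax(0.0, 0.0, 0.0, 10.0, 1.0)
        _, mid = gridmax(*coarse, 1.2, 0.05)
        joint, _ = gridmax(*mid, 0.1, 0.01)
        _, llh, _ = fit_sigma_batch(t, np.stack([lvX, lvY]))
        dl_grid = joint - float(llh.sum())
        assert dl_fit == pytest.approx(dl_grid, abs=1e-3)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "deltaL,J,expected",
        [
            (5.0, 0.3, "positive"),
            (1.0, 0.3, "none"),
            (3.0, -0.2, "negative"),
            (3.0, 0.0, "none"),
        ],
    )
    def test_rule(self, deltaL, J, expected):
        score = PairScore(0.0, 0.0, J, deltaL, 0.0)
        assert classify_pair(score, cutoff=2.0) == expected

    def test_cutoff_must_be_positive(self):
        with pytest.raises(ValueError):
            classify_pair(PairScore(0, 0, 1.0, 3.0, 0.0), cutoff=0.0)


class TestStructure:
    def test_rerooting_leaves_weight_sum_unchanged(self):
        """The MRF is undirected: re-orienting the tree around a different
        internal root changes nothing."""
        rng = np.random.default_rng(31)
        t = random_tree(rng, 9)
        internal = [v for v in range(t.n_nodes) if v not in t.leaves.tolist() and v != t.root]
        if not internal:
            pytest.skip("no alternative internal root in this draw")
        new_root = internal[0]
        # re-orient parents along the path from new_root to the old root
        parent = t.parent.copy()
        beta = t.beta.copy()
        path = [new_root]
        while parent[path[-1]] >= 0:
            path.append(int(parent[path[-1]]))
        new_parent = parent.copy()
        new_beta = beta.copy()
        for child, par in zip(path, path[1:]):
            new_parent[par] = child
            new_beta[par] = beta[child]  # the edge keeps its coupling
        new_parent[new_root] = -1
        new_beta[new_root] = 0.0
        t2 = Phylogeny(t.names, new_parent, new_beta, t.h, t.reference)
        clamps = {int(t.leaves[0]): 1, int(t.leaves[-1]): 0}
        assert log_weight_sum(t, clamps, 0.4) == pytest.approx(
            log_weight_sum(t2, clamps, 0.4), abs=1e-9
        )

    def test_invalid_trees_rejected(self):
        with pytest.raises(PhylogenyError):
            Phylogeny(("a", "b"), np.array([-1, -1]), np.zeros(2), np.zeros(2), 1)
        with pytest.raises(PhylogenyError):
            Phylogeny(("a", "b", "c"), np.array([-1, 0, 0]), np.zeros(3), np.zeros(3), 0)

    def test_optimizer_settings_validated(self):
        with pytest.raises(ValueError):
            OptimizerSettings(sigma_bounds=(1.0, 2.0))
        with pytest.raises(ValueError):
            OptimizerSettings(loglik_tol=0.0)
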