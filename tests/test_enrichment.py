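"""Poisson/Skellam tests, category summaries, networks, rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from coevosite.controls import BootstrapSample
from coevosite.enrichment import (
    MiRNANetwork,
    PairCountSummary,
    benjamini_hochberg,
    build_network,
    compare_networks,
    expression_overlap,
    geneset_strategy_test,
    mwu_compare,
    network_from_overlap,
    poisson_enrichment,
    skellam_excess,
    skellam_pmf_convolution,
    summarize_category,
)


class TestPoisson:
    def test_partial_sum_example(self):
        """P(Poisson(2) >= 5) = 1 - F(4; 2) ~ 0.0527."""
        assert poisson_enrichment(5, 2.0) == pytest.approx(0.05265, abs=1e-4)

    def test_zero_observed_is_one(self):
        assert poisson_enrichment(0, 7.3) == 1.0
        assert poisson_enrichment(0, 0.0) == 1.0

    def test_super_uniform_under_null(self):
        """p-values from Poisson draws at the true mean are super-uniform."""
        rng = np.random.default_rng(0)
        mu = 4.0
        draws = rng.poisson(mu, 10_000)
        pvals = ss.poisson.sf(draws - 1, mu)
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            emp = float(np.mean(pvals <= alpha))
            se = np.sqrt(alpha * (1 - alpha) / 10_000)
            assert emp <= alpha + 3 * se


class TestSkellam:
    def test_symmetric_center_value(self):
        """P(D = 0) at mu = (1, 1) equals e^-2 I0(2) ~ 0.3085."""
        pmf0 = skellam_pmf_convolution(0, 1.0, 1.0)
        assert pmf0 == pytest.approx(np.exp(-2) * np.i0(2), abs=1e-12)
        assert pmf0 == pytest.approx(0.3085, abs=1e-4)

    def test_scipy_matches_convolution(self):
        """The Bessel-form pmf equals the brute-force Poisson convolution."""
        for k in range(-12, 13):
            a = float(ss.skellam.pmf(k, 3.0, 2.0))
            b = skellam_pmf_convolution(k, 3.0, 2.0)
            assert a == pytest.approx(b, abs=1e-10)

    def test_normalization(self):
        total = sum(skellam_pmf_convolution(k, 3.0, 2.0) for k in range(-50, 51))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_symmetric_tails_at_zero_difference(self):
        p_hi, p_lo = skellam_excess(4, 4, 2.5, 2.5)
        assert p_hi == pytest.approx(p_lo, abs=1e-12)
        assert p_hi > 0.5

    def test_degenerate_both_zero(self):
        assert skellam_excess(0, 0, 0.0, 0.0) == (1.0, 1.0)
        p_hi, p_lo = skellam_excess(3, 0, 0.0, 0.0)
        assert p_hi == 0.0 and p_lo == 1.0

    def test_super_uniform_under_null(self):
        rng = np.random.default_rng(1)
        mu_p, mu_n = 3.0, 2.0
        d = rng.poisson(mu_p, 10_000) - rng.poisson(mu_n, 10_000)
        p_hi = ss.skellam.sf(d - 1, mu_p, mu_n)
        for alpha in (0.01, 0.05, 0.1, 0.25):
            emp = float(np.mean(p_hi <= alpha))
            se = np.sqrt(alpha * (1 - alpha) / 10_000)
            assert emp <= alpha + 3 * se


def _mk_samples(n_control, B, seed, rescale=1.0):
    rng = np.random.default_rng(seed)
    return [
        BootstrapSample(indices=rng.integers(0, n_control, n_control), rescale=rescale)
        for _ in range(B)
    ]


class TestSummarizeCategory:
    def test_zero_observed_p_one(self):
        ctl_dl = np.zeros(50)
        ctl_J = np.zeros(50)
        s = summarize_category(
            "c", np.array([0.1, 0.2]), np.array([1.0, -1.0]), ctl_dl, ctl_J,
            _mk_samples(50, 20, 0), pair_cutoff=2.0,
        )
        assert s.n_corr == 0
        assert s.p_enrichment == 1.0

    def test_counts_and_invariant(self):
        dl = np.array([3.0, 2.5, 1.0, 4.0])
        J = np.array([0.5, -0.5, 2.0, 1.0])
        ctl_dl = np.concatenate([np.full(5, 3.0), np.zeros(95)])
        ctl_J = np.ones(100)
        s = summarize_category("c", dl, J, ctl_dl, ctl_J, _mk_samples(100, 50, 1))
        assert s.n_corr == 3 == s.n_pos + s.n_neg
        assert s.n_pos == 2 and s.n_neg == 1
        assert s.mean_abs_J == pytest.approx(np.mean([0.5, 0.5, 1.0]))

    def test_planted_excess_detected(self):
        """A category with many more correlated pairs than its control is
        flagged at small p."""
        rng = np.random.default_rng(3)
        dl = rng.exponential(3.0, 100)  # many above cutoff
        J = np.abs(rng.normal(1, 0.3, 100))
        ctl_dl = rng.exponential(0.5, 500)  # few above cutoff
        ctl_J = rng.normal(0, 1, 500)
        s = summarize_category("planted", dl, J, ctl_dl, ctl_J, _mk_samples(500, 50, 2))
        assert s.p_enrichment < 0.01

    def test_null_calibrated(self):
        """Control pairs tested against their own bootstrap show no
        systematic enrichment beyond the nominal rate."""
        rng = np.random.default_rng(4)
        hits = 0
        n_cat = 60
        for i in range(n_cat):
            pool = rng.exponential(1.0, 200)
            Js = rng.normal(0, 1, 200)
            obs_idx = rng.integers(0, 200, 200)
            s = summarize_category(
                f"null{i}", pool[obs_idx], Js[obs_idx], pool, Js,
                _mk_samples(200, 40, 100 + i),
            )
            hits += s.p_enrichment < 0.05
        se = np.sqrt(0.05 * 0.95 / n_cat)
        assert hits / n_cat <= 0.05 + 3 * se


class TestGenesetStrategy:
    def _rows(self, n_same, n_diff, dl_same, dl_diff, J_same, J_diff, rng):
        return pd.DataFrame(
            {
                "deltaL": np.concatenate([
                    np.full(n_same, dl_same) + rng.normal(0, 0.1, n_same),
                    np.full(n_diff, dl_diff) + rng.normal(0, 0.1, n_diff),
                ]),
                "J": np.concatenate([
                    np.full(n_same, J_same), np.full(n_diff, J_diff)
                ]),
                "same_gene": np.array([True] * n_same + [False] * n_diff),
            }
        )

    def test_complex_like_structure_recovered(self):
        """Planted positive same-gene and negative different-gene couplings
        give the expected per-stratum excess pattern."""
        rng = np.random.default_rng(5)
        real = self._rows(60, 60, 3.0, 3.0, +1.0, -1.0, rng)
        ctl = self._rows(300, 300, 0.3, 0.3, +0.1, -0.1, rng)
        samples = {
            "same_gene": _mk_samples(300, 30, 6),
            "different_gene": _mk_samples(300, 30, 7),
        }
        out = geneset_strategy_test("cplx", real, ctl, samples)
        assert out["same_gene"].p_excess_positive < 0.01
        assert out["different_gene"].p_excess_negative < 0.01
        assert out["different_gene"].p_excess_positive > 0.5

    def test_single_gene_set_has_trivial_different_stratum(self):
        rng = np.random.default_rng(8)
        real = self._rows(10, 0, 3.0, 0.0, 1.0, 0.0, rng)
        ctl = self._rows(50, 0, 0.5, 0.0, 0.1, 0.0, rng)
        out = geneset_strategy_test(
            "single", real, ctl, {"same_gene": _mk_samples(50, 10, 9)}
        )
        assert out["different_gene"].p_excess_positive == 1.0

    def test_bh_fdr(self):
        q, rej = benjamini_hochberg([0.001, 0.01, 0.5, 0.9], alpha=0.05)
        assert rej[0] and rej[1] and not rej[2]


class TestNetworks:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["family1", "family2", "deltaL", "J"])

    def test_top_percentile_edges(self):
        rows = [
            ("a", "b", 3.0, 1.0),
            ("a", "b", 3.0, 1.0),
            ("a", "b", 3.0, 1.0),
            ("c", "d", 3.0, 1.0),
        ]
        net = build_network(self._pairs(rows), percentile=0.5)
        assert frozenset(("a", "b")) in net.edges
        assert frozenset(("c", "d")) not in net.edges

    def test_degree_counts_incident_edges(self):
        rows = [("a", "b", 3.0, 1.0)] * 2 + [("a", "c", 3.0, 1.0)] * 2
        net = build_network(self._pairs(rows), percentile=1.0)
        assert net.degree("a") == 2
        assert net.degree("b") == 1

    def test_edge_retention_monotone_in_percentile(self):
        rng = np.random.default_rng(10)
        fams = [f"f{i}" for i in range(8)]
        rows = []
        for _ in range(300):
            a, b = rng.choice(8, 2, replace=False)
            rows.append((fams[a], fams[b], float(rng.exponential(2)), float(rng.normal())))
        df = self._pairs(rows)
        sizes = [len(build_network(df, percentile=p).edges) for p in (0.1, 0.3, 0.5, 0.9)]
        assert sizes == sorted(sizes)

    def test_planted_communities(self):
        """Correlated pairs concentrated within two groups keep the retained
        edges inside the groups."""
        rng = np.random.default_rng(11)
        g1 = [f"a{i}" for i in range(4)]
        g2 = [f"b{i}" for i in range(4)]
        rows = []
        for grp in (g1, g2):
            for x in grp:
                for y in grp:
                    if x < y:
                        rows += [(x, y, 5.0, 1.0)] * 4
        for x in g1[:2]:
            rows.append((x, g2[0], 5.0, 1.0))  # sparse cross links
        net = build_network(self._pairs(rows), percentile=0.5)
        cross = [e for e in net.edges if any(n in g1 for n in e) and any(n in g2 for n in e)]
        assert not cross

    def test_self_edges_excluded(self):
        net = build_network(self._pairs([("a", "a", 5.0, 1.0)]), percentile=1.0)
        assert len(net.edges) == 0


class TestExpressionOverlap:
    def test_identity_and_orthogonality(self):
        expr = pd.DataFrame(
            [[1, 1, 0], [1, 1, 0], [0, 0, 2]], index=["a", "b", "c"],
        )
        ov = expression_overlap(expr)
        assert ov.loc["a", "b"] == pytest.approx(1.0)
        assert ov.loc["a", "c"] == pytest.approx(0.0)

    def test_half_overlap(self):
        expr = pd.DataFrame([[1, 1, 0], [1, 0, 1]], index=["a", "b"])
        ov = expression_overlap(expr)
        assert ov.loc["a", "b"] == pytest.approx(0.5)

    def test_zero_rows_dropped_with_warning(self):
        expr = pd.DataFrame([[1, 2], [0, 0]], index=["a", "z"])
        with pytest.warns(UserWarning):
            ov = expression_overlap(expr)
        assert "z" not in ov.index


class TestCompareNetworks:
    def _net(self, nodes, edges):
        return MiRNANetwork(
            nodes=tuple(nodes),
            weights={frozenset(e): 1.0 for e in edges},
            edges=frozenset(frozenset(e) for e in edges),
        )

    def test_identical_networks_minimal_p(self):
        nodes = [f"f{i}" for i in range(7)]
        edges = [("f0", "f1"), ("f2", "f3"), ("f4", "f5")]
        net = self._net(nodes, edges)
        p, table = compare_networks(net, net)
        assert table[0, 1] == 0 and table[1, 0] == 0
        assert p < 0.05

    def test_hand_table_matches_hypergeometric(self):
        """Shared 6, A-only 2, B-only 2, neither 10 — Fisher's exact p equals
        scipy's value for that table."""
        table = np.array([[6, 2], [2, 10]])
        _, want = ss.fisher_exact(table, alternative="two-sided")
        # construct two networks realizing that table on 20 node pairs
        nodes = [f"n{i}" for i in range(7)]  # C(7,2) = 21 pairs, use 20
        import itertools

        pairs = list(itertools.combinations(nodes, 2))[:20]
        edgesA = pairs[:6] + pairs[6:8]
        edgesB = pairs[:6] + pairs[8:10]
        netA = self._net(nodes, edgesA)
        netB = self._net(nodes, edgesB)
        p, tab = compare_networks(netA, netB)
        # the leftover 21st pair lands in the 'neither' cell
        assert tab[0, 0] == 6 and tab[0, 1] == 2 and tab[1, 0] == 2
        _, got_p = ss.fisher_exact(tab, alternative="two-sided")
        assert p == pytest.approx(got_p)
        assert p == pytest.approx(want, rel=0.2)

    def test_random_rewiring_null_uniform(self):
        """p-values against degree-free random rewirings are roughly uniform."""
        rng = np.random.default_rng(13)
        nodes = [f"n{i}" for i in range(10)]
        import itertools

        allp = list(itertools.combinations(nodes, 2))
        base = self._net(nodes, [allp[i] for i in rng.choice(len(allp), 10, replace=False)])
        pvals = []
        for _ in range(200):
            other = self._net(
                nodes, [allp[i] for i in rng.choice(len(allp), 10, replace=False)]
            )
            p, _ = compare_networks(base, other)
            pvals.append(p)
        # no excess of small p beyond chance
        assert np.mean(np.asarray(pvals) <= 0.05) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_too_few_common_nodes(self):
        with pytest.raises(ValueError):
            compare_networks(self._net(["a"], []), self._net(["b"], []))


class TestMWU:
    def test_identical_groups_p_one_ish(self):
        vals = np.arange(10.0)
        assert mwu_compare(vals, vals) > 0.6

    def test_shifted_groups_tiny_p(self):
        rng = np.random.default_rng(14)
        a = rng.normal(3, 1, 50)
        b = rng.normal(0, 1, 50)
        assert mwu_compare(a, b) < 1e-4

    def test_single_observations_exact(self):
        assert mwu_compare([1.0], [2.0]) == pytest.approx(1.0)

    def test_all_tied_returns_one(self):
        assert mwu_compare([1.0, 1.0], [1.0, 1.0]) == 1.0


class TestPairCountSummaryInvariant:
    def test_count_consistency_enforced(self):
        with pytest.raises(ValueError):
            PairCountSummary("c", 3, 1, 1, 0, 0, 0, 0, 1, 1, 1)
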