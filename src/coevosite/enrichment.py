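"""Enrichment statistics for correlated site pairs and miRNA networks.

Counts of significantly correlated control pairs across bootstrap samples
behave like Poisson variables (variance scales with the mean), so observed
counts are tested against the bootstrap mean with an upper-tail Poisson
test.  Positive and negative correlated counts are uncorrelated across
bootstrap samples, so their difference is tested with a Skellam
distribution.  miRNA-family networks built from correlated pairs are
compared to co-expression / co-targeting networks by Fisher's exact test on
shared edges, and score distributions between groups by Mann-Whitney U.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairCountSummary",
    "MiRNANetwork",
    "poisson_enrichment",
    "skellam_excess",
    "summarize_category",
    "geneset_strategy_test",
    "build_network",
    "expression_overlap",
    "compare_networks",
    "mwu_compare",
]


@dataclass(frozen=True)
class PairCountSummary:
    category: str
    n_corr: int
    n_pos: int
    n_neg: int
    mu: float
    mu_pos: float
    mu_neg: float
    mean_abs_J: float
    p_enrichment: float
    p_excess_positive: float
    p_excess_negative: float

    def __post_init__(self):
        if self.n_corr != self.n_pos + self.n_neg:
            raise ValueError("n_corr must equal n_pos + n_neg")


@dataclass(frozen=True)
class MiRNANetwork:
    """Undirected weighted family-family graph with a thresholded edge set."""

    nodes: tuple
    weights: dict  # frozenset({a, b}) -> weight
    edges: frozenset  # retained edges after percentile thresholding

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if node in e)


def poisson_enrichment(observed: int, control_mean: float) -> float:
    """Upper-tail Poisson p-value: P(Poisson(mu) >= observed)."""
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    if observed == 0:
        return 1.0
    if control_mean <= 0:
        import warnings

        warnings.warn("control mean is 0 with a positive observed count; p -> 0 limit")
        return 0.0
    return float(stats.poisson.sf(observed - 1, control_mean))


def skellam_excess(n_pos: int, n_neg: int, mu_pos: float, mu_neg: float):
    """Two one-sided Skellam tests on the positive-negative count difference.

    D ~ Skellam(mu_pos, mu_neg) models the difference of two independent
    Poisson counts.  Returns (P(D >= n_pos - n_neg), P(D <= n_pos - n_neg)).
    """
    if mu_pos < 0 or mu_neg < 0:
        raise ValueError("Poisson means must be >= 0")
    d = n_pos - n_neg
    if mu_pos == 0 and mu_neg == 0:
        # degenerate point mass at 0
        return (1.0 if d <= 0 else 0.0, 1.0 if d >= 0 else 0.0)
    mu_pos = max(mu_pos, 1e-12)
    mu_neg = max(mu_neg, 1e-12)
    p_hi = float(stats.skellam.sf(d - 1, mu_pos, mu_neg))
    p_lo = float(stats.skellam.cdf(d, mu_pos, mu_neg))
    return p_hi, p_lo


def skellam_pmf_convolution(k: int, mu_pos: float, mu_neg: float, trunc: int = 200) -> float:
    """Skellam pmf by brute-force convolution of two Poisson pmfs.

    Independent fallback/cross-check for the Bessel-function form.
    """
    js = np.arange(0, trunc + 1)
    # P(D = k) = sum_j P(N+ = k + j) P(N- = j)
    valid = k + js >= 0
    return float(
        np.sum(stats.poisson.pmf(k + js[valid], mu_pos) * stats.poisson.pmf(js[valid], mu_neg))
    )


def _control_counts_per_sample(control_deltaL, control_J, samples, cutoff):
    """Rescaled (n_corr, n_pos, n_neg) per bootstrap sample."""
    dl = np.asarray(control_deltaL, float)
    J = np.asarray(control_J, float)
    rows = []
    for s in samples:
        d = dl[s.indices]
        j = J[s.indices]
        corr = d >= cutoff
        rows.append(
            (
                corr.sum() * s.rescale,
                (corr & (j > 0)).sum() * s.rescale,
                (corr & (j < 0)).sum() * s.rescale,
            )
        )
    return np.asarray(rows, float)


def summarize_category(
    category: str,
    deltaL,
    J,
    control_deltaL,
    control_J,
    bootstrap_samples,
    pair_cutoff: float = 2.0,
) -> PairCountSummary:
    """Observed correlated-pair counts vs. bootstrap control expectations.

    deltaL / J : arrays over the category's real site pairs.
    control_deltaL / control_J : arrays over the control pairs from which
    ``bootstrap_samples`` (with rescaling factors) were drawn.
    """
    deltaL = np.asarray(deltaL, float)
    J = np.asarray(J, float)
    if deltaL.size == 0:
        return PairCountSummary(category, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0)
    corr = deltaL >= pair_cutoff
    n_pos = int((corr & (J > 0)).sum())
    n_neg = int((corr & (J < 0)).sum())
    n_corr = n_pos + n_neg
    mean_abs_J = float(np.abs(J[corr]).mean()) if corr.any() else 0.0
    counts = _control_counts_per_sample(control_deltaL, control_J, bootstrap_samples, pair_cutoff)
    mu, mu_pos, mu_neg = counts.mean(axis=0)
    p_enr = poisson_enrichment(n_corr, mu) if n_corr else 1.0
    p_pos, p_neg = skellam_excess(n_pos, n_neg, mu_pos, mu_neg)
    return PairCountSummary(
        category=category,
        n_corr=n_corr,
        n_pos=n_pos,
        n_neg=n_neg,
        mu=float(mu),
        mu_pos=float(mu_pos),
        mu_neg=float(mu_neg),
        mean_abs_J=mean_abs_J,
        p_enrichment=float(p_enr),
        p_excess_positive=float(p_pos),
        p_excess_negative=float(p_neg),
    )


def geneset_strategy_test(
    set_id: str,
    pair_rows: pd.DataFrame,
    control_rows: pd.DataFrame,
    bootstrap_samples_by_stratum: dict,
    pair_cutoff: float = 2.0,
) -> dict:
    """Per-stratum (same_gene / different_gene) excess-correlation tests.

    ``pair_rows`` / ``control_rows`` need columns deltaL, J, same_gene.
    Returns {stratum: PairCountSummary}; an empty stratum yields p = 1.
    """
    out = {}
    for stratum, mask in (
        ("same_gene", pair_rows["same_gene"]),
        ("different_gene", ~pair_rows["same_gene"]),
    ):
        sub = pair_rows[mask]
        cmask = control_rows["same_gene"] if stratum == "same_gene" else ~control_rows["same_gene"]
        csub = control_rows[cmask]
        samples = bootstrap_samples_by_stratum.get(stratum, [])
        if len(sub) == 0 or len(csub) == 0 or not samples:
            out[stratum] = PairCountSummary(
                f"{set_id}:{stratum}", 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0
            )
            continue
        out[stratum] = summarize_category(
            f"{set_id}:{stratum}",
            sub["deltaL"].to_numpy(),
            sub["J"].to_numpy(),
            csub["deltaL"].to_numpy(),
            csub["J"].to_numpy(),
            samples,
            pair_cutoff,
        )
    return out


def benjamini_hochberg(pvals, alpha: float = 0.05):
    """BH-adjusted q-values and the rejection mask at the given FDR."""
    from statsmodels.stats.multitest import multipletests

    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return qvals, reject


def build_network(
    pair_rows: pd.DataFrame,
    edge_stat: str = "count",
    percentile: float = 0.5,
    pair_cutoff: float = 2.0,
) -> MiRNANetwork:
    """miRNA-family network from correlated site pairs.

    ``pair_rows`` needs columns family1, family2, deltaL, J.  Edge weight is
    the number of correlated pairs linking two families ('count') or the
    fraction of the families' co-occurring pairs that are positively
    correlated ('fraction_positive').  The binary edge set keeps the top
    ``percentile`` fraction of positive-weight edges; ties at the boundary
    are included, with family-id ordering only breaking presentation order.
    """
    if edge_stat not in ("count", "fraction_positive"):
        raise ValueError(f"unknown edge_stat {edge_stat!r}")
    nodes = sorted(set(pair_rows["family1"]) | set(pair_rows["family2"]))
    weights = {}
    for (a, b), grp in pair_rows.groupby(["family1", "family2"]):
        key = frozenset((a, b))
        if len(key) < 2:
            continue  # no self-edges
        corr = grp["deltaL"] >= pair_cutoff
        if edge_stat == "count":
            w = float(corr.sum())
        else:
            w = float((corr & (grp["J"] > 0)).sum() / len(grp)) if len(grp) else 0.0
        weights[key] = weights.get(key, 0.0) + w
    positive = {k: w for k, w in weights.items() if w > 0}
    if positive:
        cutoff = float(np.quantile(sorted(positive.values()), 1.0 - percentile))
        edges = frozenset(k for k, w in positive.items() if w >= cutoff)
    else:
        edges = frozenset()
    return MiRNANetwork(nodes=tuple(nodes), weights=weights, edges=edges)


def expression_overlap(expr: pd.DataFrame) -> pd.DataFrame:
    """Normalized dot product of expression rows across tissues.

    expr : families x tissues, nonnegative.  Zero-norm families are dropped
    with a warning; overlap(a, b) = <e_a, e_b> / (||e_a|| ||e_b||).
    """
    X = expr.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("expression values must be nonnegative")
    norms = np.linalg.norm(X, axis=1)
    keep = norms > 0
    if not np.all(keep):
        import warnings

        warnings.warn(
            f"dropping {np.sum(~keep)} all-zero expression rows: "
            + ", ".join(expr.index[~keep])
        )
    Xk = X[keep] / norms[keep, None]
    ov = Xk @ Xk.T
    idx = expr.index[keep]
    return pd.DataFrame(ov, index=idx, columns=idx)


def network_from_overlap(overlap: pd.DataFrame, percentile: float = 0.5) -> MiRNANetwork:
    """Threshold a symmetric similarity matrix into a network (top percentile)."""
    nodes = tuple(overlap.index)
    weights = {}
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            weights[frozenset((a, b))] = float(overlap.loc[a, b])
    vals = [w for w in weights.values() if w > 0]
    if vals:
        cutoff = float(np.quantile(vals, 1.0 - percentile))
        edges = frozenset(k for k, w in weights.items() if w > 0 and w >= cutoff)
    else:
        edges = frozenset()
    return MiRNANetwork(nodes=nodes, weights=weights, edges=edges)


def compare_networks(netA: MiRNANetwork, netB: MiRNANetwork):
    """Fisher's exact test on shared vs. distinct edges over common node pairs.

    Returns (p_value, 2x2 table) where the table counts all unordered node
    pairs of the common node set by membership in A and B edge sets.
    """
    common = sorted(set(netA.nodes) & set(netB.nodes))
    if len(common) < 2:
        raise ValueError("need at least 2 common nodes to compare networks")
    import itertools

    a11 = a10 = a01 = a00 = 0
    for x, y in itertools.combinations(common, 2):
        key = frozenset((x, y))
        inA = key in netA.edges
        inB = key in netB.edges
        if inA and inB:
            a11 += 1
        elif inA:
            a10 += 1
        elif inB:
            a01 += 1
        else:
            a00 += 1
    table = np.array([[a11, a10], [a01, a00]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), table


def mwu_compare(valuesA, valuesB) -> float:
    """Two-sided Mann-Whitney U p-value with tie correction."""
    a = np.asarray(valuesA, float)
    b = np.asarray(valuesB, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0
    method = "exact" if (a.size < 9 and b.size < 9 and
                         np.unique(np.concatenate([a, b])).size == a.size + b.size) else "auto"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def median_over_subsets(pvals_by_subset) -> float:
    """The reported p-value when the analysis ran on random site subsets."""
    return float(np.median(np.asarray(list(pvals_by_subset), float)))
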