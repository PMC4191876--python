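"""Empirical K-mer conservation statistics and background model fitting.

The background model must reproduce, per gene conservation class, (i) the
fraction of reference-UTR K-mers conserved in each other species and (ii)
the fraction simultaneously conserved in each species pair.  Pair
frequencies carry the phylogenetic signal: under shared ancestry,
f_st for sister species exceeds f_s * f_t, and only a tree-structured model
reproduces that excess.

Genes are grouped into conservation classes by quantile binning of their
mean per-species K-mer conservation; one parameter set (per-edge beta,
per-node h) is fitted per class by least-squares moment matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .phylo import Phylogeny, _log_weight_sum_batch, _ref_clamp

__all__ = [
    "KmerStats",
    "GeneClassAssignment",
    "BackgroundFit",
    "compute_kmer_stats",
    "model_marginals",
    "assign_gene_classes",
    "fit_background",
    "utr_kmer_patterns",
]


@dataclass(frozen=True)
class KmerStats:
    """Single and pairwise conservation frequencies of background K-mers.

    f_s[s] is the fraction of reference K-mers also present in species s;
    f_st[s, t] the fraction simultaneously present in s and t.
    """

    species: tuple
    f_s: pd.Series
    f_st: pd.DataFrame
    n_kmers: int

    def __post_init__(self):
        fs = self.f_s.to_numpy()
        fst = self.f_st.to_numpy()
        if np.any((fs < 0) | (fs > 1)):
            raise ValueError("f_s out of [0, 1]")
        bound = np.minimum.outer(fs, fs)
        if np.any(fst > bound + 1e-12) or np.any(fst < -1e-12):
            raise ValueError("f_st must satisfy 0 <= f_st <= min(f_s, f_t)")
        if self.n_kmers < 0:
            raise ValueError("n_kmers must be >= 0")


@dataclass(frozen=True)
class GeneClassAssignment:
    """Gene -> conservation class index, plus the per-class mean profile."""

    classes: pd.Series  # gene_id -> class index
    profiles: pd.DataFrame  # class index x species mean conservation

    @property
    def n_classes(self) -> int:
        return int(self.classes.max()) + 1


@dataclass(frozen=True)
class BackgroundFit:
    """Fitted background parameters per gene class."""

    trees: dict  # class index -> Phylogeny with fitted beta, h
    residuals: dict  # class index -> RMS moment mismatch
    converged: dict  # class index -> bool


def compute_kmer_stats(patterns: np.ndarray, species) -> KmerStats:
    """Empirical single and pair conservation frequencies.

    patterns : (n_kmers, n_species) 0/1 array, reference column all 1.
    """
    P = np.asarray(patterns, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] == 0:
        raise ValueError("need a non-empty (n_kmers, n_species) pattern matrix")
    species = tuple(species)
    if P.shape[1] != len(species):
        raise ValueError("species list does not match pattern columns")
    f_s = P.mean(axis=0)
    f_st = (P.T @ P) / P.shape[0]
    return KmerStats(
        species=species,
        f_s=pd.Series(f_s, index=species),
        f_st=pd.DataFrame(f_st, index=species, columns=species),
        n_kmers=P.shape[0],
    )


def model_marginals(tree: Phylogeny):
    """Exact per-species and per-pair presence probabilities at sigma = 0.

    Returns (p_s, p_st): p_s[i] = P(x_i = 1 | x_ref = 1) over the leaves in
    ``tree.leaves`` order, p_st the matching pairwise joint probabilities.
    Computed by batched clamped message passing (one pass for all clamping
    patterns), conditioning on reference presence throughout.
    """
    leaves = tree.leaves
    nl = leaves.size
    ref_col = int(np.flatnonzero(leaves == tree.reference)[0])
    base = _ref_clamp(tree)
    rows = [base]
    singles = []
    pairs = []
    for i in range(nl):
        c = base.copy()
        c[leaves[i]] = 1
        rows.append(c)
        singles.append(i)
    for i in range(nl):
        for j in range(i + 1, nl):
            c = base.copy()
            c[leaves[i]] = 1
            c[leaves[j]] = 1
            rows.append(c)
            pairs.append((i, j))
    lws = _log_weight_sum_batch(tree, np.asarray(rows), 0.0)
    log_z = lws[0]
    p_s = np.exp(lws[1 : 1 + nl] - log_z)
    p_s[ref_col] = 1.0
    p_st = np.empty((nl, nl))
    for (i, j), val in zip(pairs, np.exp(lws[1 + nl :] - log_z)):
        p_st[i, j] = p_st[j, i] = val
    p_st[np.arange(nl), np.arange(nl)] = p_s
    p_st[ref_col, :] = p_st[:, ref_col] = p_s
    p_st[ref_col, ref_col] = 1.0
    return p_s, p_st


def assign_gene_classes(per_gene_stats: pd.DataFrame, n_classes: int) -> GeneClassAssignment:
    """Quantile-bin genes by mean per-species conservation.

    per_gene_stats : DataFrame gene_id x species of per-gene K-mer
    conservation frequencies.  Ties broken deterministically by gene_id.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if len(per_gene_stats) < n_classes:
        raise ValueError(
            f"need at least {n_classes} genes for {n_classes} classes, "
            f"got {len(per_gene_stats)}"
        )
    mean_cons = per_gene_stats.mean(axis=1)
    order = mean_cons.to_frame("m").assign(g=mean_cons.index).sort_values(["m", "g"])
    ranks = pd.Series(np.arange(len(order)), index=order.index)
    cls = (ranks * n_classes // len(order)).astype(int)
    cls = cls.reindex(per_gene_stats.index)
    profiles = per_gene_stats.groupby(cls).mean()
    profiles.index.name = "class"
    return GeneClassAssignment(classes=cls.rename("class"), profiles=profiles)


def _pack(tree: Phylogeny):
    """Free parameter vector layout: beta for non-root nodes, then h."""
    non_root = np.flatnonzero(tree.parent >= 0)
    return non_root


def _moment_objective(theta, tree, non_root, f_s, f_st, iu):
    beta = np.zeros(tree.n_nodes)
    beta[non_root] = theta[: non_root.size]
    h = theta[non_root.size :]
    cand = tree.with_params(beta=beta, h=h)
    p_s, p_st = model_marginals(cand)
    return float(
        np.sum((p_s - f_s) ** 2) + np.sum((p_st[iu] - f_st[iu]) ** 2)
    )


def fit_background(
    topology: Phylogeny,
    stats: KmerStats,
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 500,
    tol: float = 1e-10,
) -> tuple:
    """Fit (beta, h) so model marginals reproduce the empirical frequencies.

    Least-squares moment matching of single and pair frequencies; the pair
    constraints make the problem overdetermined, so the fitted distribution
    (not the individual parameters) is the meaningful outcome.  Uses L-BFGS-B
    with finite-difference gradients and ``n_starts`` seeded restarts.

    Returns (fitted_tree, residual_rms, converged).
    """
    if list(stats.species) != topology.leaf_names:
        raise ValueError("stats species must match tree leaves (same order)")
    non_root = _pack(topology)
    f_s = stats.f_s.to_numpy()
    nl = f_s.size
    iu = np.triu_indices(nl, k=1)
    f_st = stats.f_st.to_numpy()
    rng = np.random.default_rng(seed)
    n_par = non_root.size + topology.n_nodes
    best = None
    x0_default = np.concatenate(
        [np.ones(non_root.size), np.zeros(topology.n_nodes)]
    )
    for start in range(max(1, n_starts)):
        x0 = x0_default if start == 0 else x0_default + rng.normal(0, 0.5, n_par)
        res = minimize(
            _moment_objective,
            x0,
            args=(topology, non_root, f_s, f_st, iu),
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": tol},
        )
        if best is None or res.fun < best.fun:
            best = res
    beta = np.zeros(topology.n_nodes)
    beta[non_root] = best.x[: non_root.size]
    h = best.x[non_root.size :]
    fitted = topology.with_params(beta=beta, h=h)
    n_constraints = nl + iu[0].size
    residual = float(np.sqrt(best.fun / n_constraints))
    return fitted, residual, bool(best.success)


def fit_background_classes(
    topology: Phylogeny,
    class_stats: dict,
    n_starts: int = 3,
    seed: int = 0,
) -> BackgroundFit:
    """Independent background fit per gene conservation class."""
    trees, residuals, converged = {}, {}, {}
    for ci, stats in sorted(class_stats.items()):
        tree, resid, ok = fit_background(topology, stats, n_starts=n_starts, seed=seed + ci)
        trees[ci] = tree
        residuals[ci] = resid
        converged[ci] = ok
    return BackgroundFit(trees=trees, residuals=residuals, converged=converged)


def utr_kmer_patterns(aln, k: int = 7) -> np.ndarray:
    """Presence/absence of every overlapping reference K-mer in each species.

    ``aln`` is a seedscan.StitchedAlignment; a K-mer counts as present in a
    species when the aligned columns carry the identical K-mer with no gaps,
    the same criterion applied to seed matches.  Returns an
    (n_kmers, n_species) 0/1 array over ``aln.species`` order.
    """
    ref = aln.reference_sequence()
    n_kmers = max(0, len(ref) - k + 1)
    out = np.zeros((n_kmers, len(aln.species)), dtype=np.int8)
    for i in range(n_kmers):
        kmer = ref[i : i + k]
        if "N" in kmer:
            continue
        for j, sp in enumerate(aln.species):
            out[i, j] = aln.span_identical(sp, i, i + k)
    return out
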