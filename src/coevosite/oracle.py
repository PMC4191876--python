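"""Exhaustive-enumeration reference implementations.

These compute the same quantities as :mod:`coevosite.phylo` by brute force —
summing the statistical weight over every configuration of the free nodes —
with no message passing or shared code path.  Configurations are enumerated
explicitly as rows of a (2^free, n_nodes) matrix and their weights computed
by direct evaluation of the energy function.  Exponential in the number of
free nodes; for validating the exact inference engine on small trees only.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .phylo import Phylogeny, _clamp_array

__all__ = [
    "enum_log_weight_sum",
    "enum_site_loglik",
    "enum_pair_log_weight_sum",
    "enum_pair_loglik",
]


def _all_configs(tree: Phylogeny, clamps: np.ndarray) -> np.ndarray:
    """(2^free, n_nodes) matrix of all configurations honoring the clamps."""
    free = np.flatnonzero(clamps < 0)
    nf = free.size
    base = np.broadcast_to(
        np.maximum(clamps, 0).astype(np.int64), (2**nf, tree.n_nodes)
    ).copy()
    bits = (np.arange(2**nf)[:, None] >> np.arange(nf)) & 1
    base[:, free] = bits
    return base


def _config_log_weights(tree: Phylogeny, X: np.ndarray, sigma: float) -> np.ndarray:
    """Direct evaluation of the energy for each configuration row."""
    w = X @ (tree.h + sigma)
    child = np.flatnonzero(tree.parent >= 0)
    agree = X[:, child] == X[:, tree.parent[child]]
    return w + agree @ tree.beta[child]


def enum_log_weight_sum(tree: Phylogeny, clamps=None, sigma: float = 0.0) -> float:
    """Brute-force log partition sum over all free-node configurations."""
    carr = clamps if isinstance(clamps, np.ndarray) else _clamp_array(tree, clamps)
    X = _all_configs(tree, carr)
    return float(logsumexp(_config_log_weights(tree, X, sigma)))


def _leaf_clamp_array(tree: Phylogeny, leaf_values) -> np.ndarray:
    c = np.full(tree.n_nodes, -1, dtype=np.int8)
    c[tree.leaves] = np.asarray(leaf_values, dtype=np.int8)
    return c


def _ref_clamp_array(tree: Phylogeny) -> np.ndarray:
    c = np.full(tree.n_nodes, -1, dtype=np.int8)
    c[tree.reference] = 1
    return c


def enum_site_loglik(tree: Phylogeny, leaf_values, sigma: float) -> float:
    """Brute-force conditional log-probability of one leaf pattern."""
    numer = enum_log_weight_sum(tree, _leaf_clamp_array(tree, leaf_values), sigma)
    denom = enum_log_weight_sum(tree, _ref_clamp_array(tree), sigma)
    return numer - denom


def enum_pair_log_weight_sum(treeX, treeY, clampsX, clampsY, s1, s2, J) -> float:
    """Brute-force log partition sum of the composite two-site chain.

    Enumerates the two chains' configuration sets and combines them through
    the coupling term J * sum_v x_v y_v as an outer sum.
    """
    cx = clampsX if isinstance(clampsX, np.ndarray) else _clamp_array(treeX, clampsX)
    cy = clampsY if isinstance(clampsY, np.ndarray) else _clamp_array(treeY, clampsY)
    X = _all_configs(treeX, cx)
    Y = _all_configs(treeY, cy)
    wx = _config_log_weights(treeX, X, s1)
    wy = _config_log_weights(treeY, Y, s2)
    cross = J * (X.astype(np.float64) @ Y.T.astype(np.float64))
    return float(logsumexp(wx[:, None] + wy[None, :] + cross))


def enum_pair_loglik(treeX, treeY, lvX, lvY, s1, s2, J) -> float:
    """Brute-force conditional log joint probability of two leaf patterns."""
    numer = enum_pair_log_weight_sum(
        treeX,
        treeY,
        _leaf_clamp_array(treeX, lvX),
        _leaf_clamp_array(treeY, lvY),
        s1,
        s2,
        J,
    )
    denom = enum_pair_log_weight_sum(
        treeX, treeY, _ref_clamp_array(treeX), _ref_clamp_array(treeY), s1, s2, J
    )
    return numer - denom
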