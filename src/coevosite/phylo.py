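"""Exact likelihood engine on a tree-structured Markov random field.

The model describes presence/absence of a short sequence element (a K-mer,
typically a miRNA seed match) across the leaves of a species phylogeny, with
unobserved ancestral states at internal nodes.  The statistical weight of a
full configuration ``x`` over all nodes is

    w(x) = prod_edges exp(beta_e * 1[x_u = x_v]) * prod_nodes exp(h_v * x_v)

where the per-edge coupling ``beta_e`` plays the role of a branch length
(agreement strength along a branch) and the per-node field ``h_v`` sets a
species/clade-dependent equilibrium presence probability.  A per-site
conservation score ``sigma`` tilts every node toward presence via an extra
factor ``exp(sigma * sum_v x_v)``; its maximum-likelihood value measures
preferential conservation beyond the background.  Two sites are coupled by a
composite-variable model with an interaction ``J * sum_v x_v y_v``.

All arithmetic is carried out in log domain (log-sum-exp message passing),
so overflow is impossible by construction.  The partition sums are exact:
upward message passing on a tree is exact inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "Phylogeny",
    "ConservationPattern",
    "SiteScore",
    "PairScore",
    "OptimizerSettings",
    "log_weight_sum",
    "site_loglik",
    "site_loglik_batch",
    "fit_sigma",
    "fit_sigma_batch",
    "pair_log_weight_sum",
    "pair_loglik",
    "fit_pair",
    "fit_pair_batch",
    "classify_pair",
]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _lse(a: np.ndarray, axis: int = -1) -> np.ndarray:
    """Log-sum-exp along one axis; tolerates -inf blocks without warnings."""
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(invalid="ignore"):
        out = np.log(np.sum(np.exp(a - m), axis=axis))
    return out + np.squeeze(m, axis=axis)


class PhylogenyError(ValueError):
    """Invalid tree structure or parameters."""


class PatternError(ValueError):
    """Invalid conservation pattern for the given tree."""


@dataclass(frozen=True)
class Phylogeny:
    """Rooted tree with per-edge couplings and per-node occupancy fields.

    Parameters
    ----------
    names : node names; index into this list is the node id.
    parent : parent node id per node, -1 for the root.
    beta : coupling on the edge to the parent (ignored for the root).
    h : occupancy field per node.
    reference : node id of the reference leaf (the species in which sites
        are observed; all likelihoods condition on its presence).
    """

    names: tuple
    parent: np.ndarray
    beta: np.ndarray
    h: np.ndarray
    reference: int

    # derived, filled in __post_init__
    children: tuple = field(default=None, repr=False, compare=False)
    postorder: np.ndarray = field(default=None, repr=False, compare=False)
    leaves: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        parent = np.asarray(self.parent, dtype=np.int64)
        beta = np.asarray(self.beta, dtype=np.float64)
        h = np.asarray(self.h, dtype=np.float64)
        n = parent.shape[0]
        if len(self.names) != n or beta.shape[0] != n or h.shape[0] != n:
            raise PhylogenyError("names/parent/beta/h length mismatch")
        roots = np.flatnonzero(parent < 0)
        if roots.size != 1:
            raise PhylogenyError(f"tree must have exactly one root, found {roots.size}")
        if not (np.all(np.isfinite(beta[parent >= 0])) and np.all(np.isfinite(h))):
            raise PhylogenyError("beta and h must be finite")
        children = [[] for _ in range(n)]
        for v in range(n):
            p = parent[v]
            if p >= 0:
                if p == v:
                    raise PhylogenyError("self-loop in parent array")
                children[p].append(v)
        # children-before-parents order; also detects cycles/disconnection
        order = []
        stack = [int(roots[0])]
        seen = 0
        while stack:
            v = stack.pop()
            order.append(v)
            seen += 1
            stack.extend(children[v])
        if seen != n:
            raise PhylogenyError("tree is not connected and acyclic")
        postorder = np.asarray(order[::-1], dtype=np.int64)
        leaves = np.asarray([v for v in range(n) if not children[v]], dtype=np.int64)
        if self.reference not in leaves:
            raise PhylogenyError("reference must be a leaf")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "children", tuple(tuple(c) for c in children))
        object.__setattr__(self, "postorder", postorder)
        object.__setattr__(self, "leaves", leaves)

    # -- convenience -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def leaf_names(self) -> list:
        return [self.names[v] for v in self.leaves]

    @property
    def reference_name(self) -> str:
        return self.names[self.reference]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise PhylogenyError(f"unknown node {name!r}") from None

    def with_params(self, beta=None, h=None) -> "Phylogeny":
        """Same topology with replaced parameter vectors."""
        return replace(
            self,
            beta=self.beta if beta is None else np.asarray(beta, dtype=np.float64),
            h=self.h if h is None else np.asarray(h, dtype=np.float64),
            children=None,
            postorder=None,
            leaves=None,
        )

    def decoupled(self) -> "Phylogeny":
        """Species-only variant: all edge couplings zeroed (no phylogeny)."""
        return self.with_params(beta=np.zeros(self.n_nodes))

    @classmethod
    def from_newick(cls, newick: str, reference: str, beta=1.0, h=0.0) -> "Phylogeny":
        """Build from a newick string; unnamed internal nodes are auto-named.

        ``beta``/``h`` may be scalars (uniform) or mappings node-name -> value.
        Branch lengths in the newick string are ignored; edge parameters come
        from ``beta``.
        """
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(newick), "newick")
        clades = list(tree.find_clades(order="preorder"))
        names, parent_ids = [], []
        idx = {}
        auto = 0
        parent_of = {}
        for cl in clades:
            for ch in cl.clades:
                parent_of[id(ch)] = id(cl)
        for cl in clades:
            name = cl.name
            if name is None:
                name = f"anc{auto}"
                auto += 1
            idx[id(cl)] = len(names)
            names.append(name)
            parent_ids.append(idx[parent_of[id(cl)]] if id(cl) in parent_of else -1)
        n = len(names)

        def expand(x):
            if isinstance(x, Mapping):
                return np.asarray([float(x.get(nm, 0.0)) for nm in names])
            return np.full(n, float(x))

        ref = names.index(reference)
        return cls(tuple(names), np.asarray(parent_ids), expand(beta), expand(h), ref)


@dataclass(frozen=True)
class ConservationPattern:
    """Binary presence/absence of one site across species.

    ``values`` maps species name -> {0, 1}.  Species without an alignable row
    for the site's gene are recorded as 0 (absence), never as missing: gaps
    and unalignable stretches count as evidence against conservation, and the
    gene-class background absorbs systematic absence.  The reference species
    is always present (sites are only observed in the reference genome).
    """

    site_id: str
    gene_id: str
    values: Mapping

    def leaf_vector(self, tree: Phylogeny) -> np.ndarray:
        """0/1 vector over ``tree.leaves`` order; absent species -> 0."""
        vec = np.zeros(tree.leaves.shape[0], dtype=np.int8)
        leaf_names = tree.leaf_names
        pos = {nm: i for i, nm in enumerate(leaf_names)}
        for sp, val in self.values.items():
            if sp not in pos:
                raise PatternError(f"species {sp!r} is not a leaf of the tree")
            if val not in (0, 1):
                raise PatternError(f"pattern value for {sp!r} must be 0 or 1")
            vec[pos[sp]] = val
        if vec[pos[tree.reference_name]] != 1:
            raise PatternError(f"site {self.site_id}: reference species must be present")
        return vec


@dataclass(frozen=True)
class SiteScore:
    """Fitted conservation score for one site."""

    sigma_hat: float
    loglik_at_hat: float
    loglik_at_zero: float

    @property
    def D(self) -> float:
        """Conservation log-likelihood ratio vs. the background (sigma = 0)."""
        return self.loglik_at_hat - self.loglik_at_zero


@dataclass(frozen=True)
class PairScore:
    """Jointly fitted two-site model for one site pair."""

    sigma1_joint: float
    sigma2_joint: float
    J_hat: float
    loglik_joint: float
    loglik_indep: float
    converged: bool = True

    @property
    def deltaL(self) -> float:
        """Log-likelihood ratio, coupled vs. independent evolution."""
        return self.loglik_joint - self.loglik_indep


@dataclass(frozen=True)
class OptimizerSettings:
    sigma_bounds: tuple = (-15.0, 15.0)
    J_bounds: tuple = (-10.0, 10.0)
    loglik_tol: float = 1e-6
    max_iter: int = 25
    n_starts: int = 3
    grid_points: int = 41

    def __post_init__(self):
        lo, hi = self.sigma_bounds
        jlo, jhi = self.J_bounds
        if not (np.isfinite([lo, hi, jlo, jhi]).all() and lo < 0 < hi and jlo < 0 < jhi):
            raise ValueError("bounds must be finite and contain 0")
        if self.loglik_tol <= 0:
            raise ValueError("loglik_tol must be positive")


# ---------------------------------------------------------------------------
# partition sums (single chain)
# ---------------------------------------------------------------------------


def _clamp_array(tree: Phylogeny, clamps: Mapping | None) -> np.ndarray:
    """Dict of node name/id -> {0,1} into an int8 array with -1 = free."""
    arr = np.full(tree.n_nodes, -1, dtype=np.int8)
    if clamps:
        for key, val in clamps.items():
            v = tree.index(key) if isinstance(key, str) else int(key)
            if not 0 <= v < tree.n_nodes:
                raise PhylogenyError(f"clamp on unknown node {key!r}")
            if val not in (0, 1):
                raise ValueError("clamp values must be 0 or 1")
            arr[v] = val
    return arr


def _traversal_plan(tree: Phylogeny):
    """Depth-level traversal plan for vectorized message passing.

    Nodes are grouped by depth (deepest first) so every group's children are
    already processed; within a group, children with duplicated parents are
    split into sub-batches so plain fancy-index adds accumulate correctly.
    Cached on the tree instance.
    """
    plan = getattr(tree, "_plan", None)
    if plan is not None:
        return plan
    n = tree.n_nodes
    depth = np.zeros(n, dtype=np.int64)
    for v in tree.postorder[::-1]:
        p = tree.parent[v]
        if p >= 0:
            depth[v] = depth[p] + 1
    groups = []
    for d in range(depth.max(), -1, -1):
        nodes = np.flatnonzero(depth == d)
        par = tree.parent[nodes]
        # split duplicated parents into rounds of unique parents
        rounds = []
        remaining = np.arange(nodes.size)[par[np.arange(nodes.size)] >= 0]
        while remaining.size:
            _, first = np.unique(par[remaining], return_index=True)
            sel = remaining[first]
            rounds.append((sel, par[sel]))
            remaining = np.setdiff1d(remaining, sel, assume_unique=True)
        groups.append((nodes, rounds))
    object.__setattr__(tree, "_plan", groups)
    return groups


def _log_weight_sum_batch(tree: Phylogeny, clamps: np.ndarray, sigma) -> np.ndarray:
    """Log partition sum, batched.

    clamps : (..., n_nodes) int8, entries in {-1, 0, 1}; -1 = summed over.
    sigma : broadcastable against clamps.shape[:-1].

    Returns log sum over free-node configurations of the total weight,
    shape = broadcast(clamps.shape[:-1], sigma.shape).
    """
    clamps = np.asarray(clamps, dtype=np.int8)
    sigma = np.asarray(sigma, dtype=np.float64)
    batch = np.broadcast_shapes(clamps.shape[:-1], sigma.shape)
    nb = len(batch)
    n = tree.n_nodes
    beta, h = tree.beta, tree.h
    cl = np.moveaxis(clamps, -1, 0)  # (n, ...) view
    cb = clamps.shape[:-1]
    acc = np.zeros((n,) + batch + (2,))
    exp = (slice(None),) + (None,) * nb  # lift per-node vectors over batch
    for nodes, rounds in _traversal_plan(tree):
        k = nodes.size
        # lift (k,) + clamp-batch so trailing axes right-align with batch
        cv = cl[nodes].reshape((k,) + (1,) * (nb - len(cb)) + cb)
        cv = np.broadcast_to(cv, (k,) + batch)
        f = np.broadcast_to(h[nodes][exp] + sigma, (k,) + batch)
        lm0 = np.where(cv == 1, -np.inf, 0.0) + acc[nodes, ..., 0]
        lm1 = np.where(cv == 0, -np.inf, f) + acc[nodes, ..., 1]
        if not rounds:  # root level
            with np.errstate(invalid="ignore"):
                return np.logaddexp(lm0, lm1)[0]
        b = beta[nodes][exp]
        with np.errstate(invalid="ignore"):
            msg0 = np.logaddexp(lm0 + b, lm1)
            msg1 = np.logaddexp(lm0, lm1 + b)
        for sel, par in rounds:
            acc[par, ..., 0] += msg0[sel]
            acc[par, ..., 1] += msg1[sel]
    raise AssertionError("unreachable: the shallowest level is the root")


def log_weight_sum(tree: Phylogeny, clamps: Mapping | None = None, sigma: float = 0.0) -> float:
    """Log of the sum over all free-node configurations of the MRF weight.

    ``clamps`` fixes observed node states (name or id -> 0/1); unclamped
    nodes, including all ancestral nodes, are summed over exactly.
    """
    return float(_log_weight_sum_batch(tree, _clamp_array(tree, clamps), float(sigma)))


def _leaf_clamps(tree: Phylogeny, leaf_values: np.ndarray) -> np.ndarray:
    """(..., n_leaves) 0/1 -> (..., n_nodes) clamps with internals free."""
    leaf_values = np.asarray(leaf_values, dtype=np.int8)
    out = np.full(leaf_values.shape[:-1] + (tree.n_nodes,), -1, dtype=np.int8)
    out[..., tree.leaves] = leaf_values
    return out


def _ref_clamp(tree: Phylogeny) -> np.ndarray:
    out = np.full(tree.n_nodes, -1, dtype=np.int8)
    out[tree.reference] = 1
    return out


def site_loglik_batch(tree: Phylogeny, leaf_values: np.ndarray, sigma) -> np.ndarray:
    """log P_sigma(pattern | reference present) for a batch of patterns.

    leaf_values : (..., n_leaves) 0/1 in ``tree.leaves`` order.
    sigma : broadcastable to the batch shape.
    """
    ref_col = int(np.flatnonzero(tree.leaves == tree.reference)[0])
    lv = np.asarray(leaf_values)
    if np.any(lv[..., ref_col] != 1):
        raise PatternError("pattern with reference absent")
    numer = _log_weight_sum_batch(tree, _leaf_clamps(tree, lv), sigma)
    denom = _log_weight_sum_batch(tree, _ref_clamp(tree), sigma)
    return numer - denom


def site_loglik(tree: Phylogeny, pattern: ConservationPattern, sigma: float) -> float:
    """Log-probability of one site's conservation pattern at score ``sigma``.

    Conditioned on presence in the reference species (sites absent from the
    reference are never observed).
    """
    return float(site_loglik_batch(tree, pattern.leaf_vector(tree), float(sigma)))


# ---------------------------------------------------------------------------
# 1-D maximization: coarse grid + golden-section refinement, batched
# ---------------------------------------------------------------------------


def _golden_max_batch(f, lo: np.ndarray, hi: np.ndarray, xbest, fbest, tol: float, max_iter: int = 80):
    """Vectorized golden-section maximization of f over per-item [lo, hi].

    Tracks the best point ever evaluated, so the result never falls below
    the incoming (xbest, fbest)."""
    a, b = lo.astype(float).copy(), hi.astype(float).copy()
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1, f2 = f(x1), f(x2)
    xbest = np.asarray(xbest, dtype=float).copy()
    fbest = np.asarray(fbest, dtype=float).copy()
    for x, fx in ((x1, f1), (x2, f2)):
        better = fx > fbest
        xbest[better] = x[better]
        fbest[better] = fx[better]
    for _ in range(max_iter):
        if np.all(b - a < tol):
            break
        left = f1 >= f2
        b = np.where(left, x2, b)
        a = np.where(left, a, x1)
        x1n = b - _GOLDEN * (b - a)
        x2n = a + _GOLDEN * (b - a)
        # re-use the surviving interior evaluation
        xnew = np.where(left, x1n, x2n)
        fnew = f(xnew)
        f2n = np.where(left, f1, fnew)
        f1n = np.where(left, fnew, f2)
        x1, x2, f1, f2 = x1n, x2n, f1n, f2n
        better = fnew > fbest
        xbest[better] = xnew[better]
        fbest[better] = fnew[better]
    return xbest, fbest


def fit_sigma_batch(tree: Phylogeny, leaf_values: np.ndarray, opts: OptimizerSettings | None = None):
    """Maximum-likelihood sigma for each pattern row, batched.

    Returns (sigma_hat, loglik_at_hat, loglik_at_zero), each shape (n,).
    Coarse grid over ``opts.sigma_bounds`` (always including 0) followed by
    golden-section refinement around the best grid point.
    """
    opts = opts or OptimizerSettings()
    lv = np.atleast_2d(np.asarray(leaf_values, dtype=np.int8))
    lo, hi = opts.sigma_bounds
    grid = np.linspace(lo, hi, opts.grid_points)
    grid = np.union1d(grid, [0.0])
    ll_grid = site_loglik_batch(tree, lv[:, None, :], grid[None, :])  # (n, G)
    if not np.all(np.isfinite(ll_grid)):
        raise FloatingPointError("non-finite site log-likelihood on the sigma grid")
    zero_idx = int(np.flatnonzero(grid == 0.0)[0])
    ll0 = ll_grid[:, zero_idx]
    best = np.argmax(ll_grid, axis=1)
    step = np.diff(grid).max()
    blo = np.maximum(grid[best] - step, lo)
    bhi = np.minimum(grid[best] + step, hi)

    def f(sig):
        return site_loglik_batch(tree, lv, sig)

    sig_hat, ll_hat = _golden_max_batch(
        f, blo, bhi, grid[best], ll_grid[np.arange(lv.shape[0]), best], tol=1e-7
    )
    return sig_hat, ll_hat, ll0


def fit_sigma(tree: Phylogeny, pattern: ConservationPattern, opts: OptimizerSettings | None = None) -> SiteScore:
    """Maximum-likelihood conservation score for one site.

    The returned ``SiteScore.D`` is the log-likelihood ratio against the
    background model (sigma = 0); D >= 0 up to optimizer tolerance because
    the background is nested.
    """
    try:
        s, llh, ll0 = fit_sigma_batch(tree, pattern.leaf_vector(tree)[None, :], opts)
    except FloatingPointError as exc:
        raise FloatingPointError(f"site {pattern.site_id}: {exc}") from exc
    return SiteScore(float(s[0]), float(llh[0]), float(ll0[0]))


# ---------------------------------------------------------------------------
# pair model (composite 4-state chain)
# ---------------------------------------------------------------------------

_X = np.array([0, 0, 1, 1], dtype=np.float64)  # composite state s -> x
_Y = np.array([0, 1, 0, 1], dtype=np.float64)  # composite state s -> y


def _check_shared_topology(treeX: Phylogeny, treeY: Phylogeny) -> None:
    if treeX.names != treeY.names or not np.array_equal(treeX.parent, treeY.parent):
        raise PhylogenyError("pair model requires identical topology and node names")
    if treeX.reference != treeY.reference:
        raise PhylogenyError("pair model requires the same reference leaf")


def _pair_log_weight_sum_batch(
    treeX: Phylogeny,
    treeY: Phylogeny,
    clampsX: np.ndarray,
    clampsY: np.ndarray,
    sigma1,
    sigma2,
    J,
) -> np.ndarray:
    """Log partition sum of the composite two-site chain, batched.

    clampsX/clampsY : (..., n_nodes) int8 in {-1, 0, 1} for each chain.
    sigma1/sigma2/J : broadcastable against the batch shape.
    """
    clampsX = np.asarray(clampsX, dtype=np.int8)
    clampsY = np.asarray(clampsY, dtype=np.int8)
    sigma1 = np.asarray(sigma1, dtype=np.float64)
    sigma2 = np.asarray(sigma2, dtype=np.float64)
    J = np.asarray(J, dtype=np.float64)
    batch = np.broadcast_shapes(
        clampsX.shape[:-1], clampsY.shape[:-1], sigma1.shape, sigma2.shape, J.shape
    )
    nb = len(batch)
    n = treeX.n_nodes
    clX = np.moveaxis(clampsX, -1, 0)
    clY = np.moveaxis(clampsY, -1, 0)
    cbX = clampsX.shape[:-1]
    cbY = clampsY.shape[:-1]
    acc = np.zeros((n,) + batch + (4,))
    exp = (slice(None),) + (None,) * nb
    Xs = _X.astype(np.int8)
    Ys = _Y.astype(np.int8)
    XX = _X[:, None] == _X[None, :]
    YY = _Y[:, None] == _Y[None, :]
    for nodes, rounds in _traversal_plan(treeX):
        k = nodes.size
        fx = (treeX.h[nodes][exp] + sigma1)[..., None] * _X
        fy = (treeY.h[nodes][exp] + sigma2)[..., None] * _Y
        lm = fx + fy + np.asarray(J)[..., None] * (_X * _Y)
        lm = np.broadcast_to(lm, (k,) + batch + (4,)).copy()
        cx = clX[nodes].reshape((k,) + (1,) * (nb - len(cbX)) + cbX)[..., None]
        cy = clY[nodes].reshape((k,) + (1,) * (nb - len(cbY)) + cbY)[..., None]
        bad = ((cx >= 0) & (cx != Xs)) | ((cy >= 0) & (cy != Ys))
        lm = np.where(bad, -np.inf, lm) + acc[nodes]
        if not rounds:  # root level
            return _lse(lm, axis=-1)[0]
        # per-node edge matrices E[s_parent, s_child]; the message
        # logsumexp_s(E + lm) is evaluated as a max-subtracted exp-matmul,
        # avoiding a (..., 4, 4) temporary on large batches
        E = (
            treeX.beta[nodes][:, None, None] * XX
            + treeY.beta[nodes][:, None, None] * YY
        )  # (k, 4, 4)
        Emax = E.max(axis=(1, 2))  # per node, keeps exp(E) in range
        expE = np.exp(E - Emax[:, None, None])
        m = np.max(lm, axis=-1, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        P = np.exp(lm - m)
        conv = np.einsum("k...s,kps->k...p", P, expE)
        with np.errstate(divide="ignore"):
            msg = np.log(conv) + m + Emax.reshape((k,) + (1,) * (nb + 1))
        for sel, par in rounds:
            acc[par] += msg[sel]
    raise AssertionError("unreachable")


def pair_log_weight_sum(
    treeX: Phylogeny,
    treeY: Phylogeny,
    clampsX: Mapping | None,
    clampsY: Mapping | None,
    sigma1: float,
    sigma2: float,
    J: float,
) -> float:
    """Log partition sum of the coupled two-site model with given clamps."""
    _check_shared_topology(treeX, treeY)
    return float(
        _pair_log_weight_sum_batch(
            treeX,
            treeY,
            _clamp_array(treeX, clampsX),
            _clamp_array(treeY, clampsY),
            float(sigma1),
            float(sigma2),
            float(J),
        )
    )


def pair_loglik_batch(treeX, treeY, lvX, lvY, sigma1, sigma2, J) -> np.ndarray:
    """Batched log joint probability of two patterns under the coupled model."""
    refX = int(np.flatnonzero(treeX.leaves == treeX.reference)[0])
    lvX = np.asarray(lvX)
    lvY = np.asarray(lvY)
    if np.any(lvX[..., refX] != 1) or np.any(lvY[..., refX] != 1):
        raise PatternError("pattern with reference absent")
    numer = _pair_log_weight_sum_batch(
        treeX, treeY, _leaf_clamps(treeX, lvX), _leaf_clamps(treeY, lvY), sigma1, sigma2, J
    )
    denom = _pair_log_weight_sum_batch(
        treeX, treeY, _ref_clamp(treeX), _ref_clamp(treeY), sigma1, sigma2, J
    )
    return numer - denom


def pair_loglik(
    treeX: Phylogeny,
    treeY: Phylogeny,
    patX: ConservationPattern,
    patY: ConservationPattern,
    sigma1: float,
    sigma2: float,
    J: float,
) -> float:
    """Log joint probability of two conservation patterns under coupling J.

    The two trees must share topology and leaf set (their parameters may
    differ, e.g. when the sites lie in genes from different conservation
    classes).  At J = 0 this equals ``site_loglik(X) + site_loglik(Y)``
    exactly, because the composite chain factorizes.
    """
    _check_shared_topology(treeX, treeY)
    return float(
        pair_loglik_batch(
            treeX,
            treeY,
            patX.leaf_vector(treeX),
            patY.leaf_vector(treeY),
            float(sigma1),
            float(sigma2),
            float(J),
        )
    )


def fit_pair_batch(
    treeX: Phylogeny,
    treeY: Phylogeny,
    lvX: np.ndarray,
    lvY: np.ndarray,
    opts: OptimizerSettings | None = None,
):
    """Jointly fit (sigma1, sigma2, J) for a batch of site pairs.

    Coordinate ascent initialized at the independent optimum
    (sigma1_hat, sigma2_hat, J=0); each coordinate step is a coarse grid plus
    golden-section refinement that never decreases the objective, so
    deltaL >= 0 up to floating-point rounding by construction.

    Returns dict of arrays: sigma1, sigma2, J, loglik_joint, loglik_indep,
    converged.
    """
    _check_shared_topology(treeX, treeY)
    opts = opts or OptimizerSettings()
    lvX = np.atleast_2d(np.asarray(lvX, dtype=np.int8))
    lvY = np.atleast_2d(np.asarray(lvY, dtype=np.int8))
    npairs = lvX.shape[0]
    # canonicalize pair order (lexicographic) so the result is exactly
    # invariant under swapping the two sites; only meaningful when both
    # chains share parameters, which _check_shared_topology does not forbid
    same_params = np.array_equal(treeX.beta, treeY.beta) and np.array_equal(
        treeX.h, treeY.h
    )
    swapped = np.zeros(npairs, dtype=bool)
    if same_params:
        for i in range(npairs):
            if tuple(lvY[i]) < tuple(lvX[i]):
                swapped[i] = True
        if swapped.any():
            lvX, lvY = lvX.copy(), lvY.copy()
            tmp = lvX[swapped].copy()
            lvX[swapped] = lvY[swapped]
            lvY[swapped] = tmp
    s1, ll1, _ = fit_sigma_batch(treeX, lvX, opts)
    s2, ll2, _ = fit_sigma_batch(treeY, lvY, opts)
    ll_indep = ll1 + ll2

    clampX = _leaf_clamps(treeX, lvX)
    clampY = _leaf_clamps(treeY, lvY)
    refX = _ref_clamp(treeX)
    refY = _ref_clamp(treeY)
    # numerator (full clamps) and normalizer (reference-only clamps) share
    # one message-passing pass via a leading axis of size 2
    cX2 = np.stack([clampX, np.broadcast_to(refX, clampX.shape)])
    cY2 = np.stack([clampY, np.broadcast_to(refY, clampY.shape)])

    def L(a, b, c):
        # grid stages evaluate (npairs, G) parameter sheets; add a grid axis
        # to the per-pair clamps so everything broadcasts
        if max(np.ndim(a), np.ndim(b), np.ndim(c)) > 1:
            cx, cy = cX2[:, :, None, :], cY2[:, :, None, :]
        else:
            cx, cy = cX2, cY2
        both = _pair_log_weight_sum_batch(treeX, treeY, cx, cy, a, b, c)
        return both[0] - both[1]

    params = [s1.copy(), s2.copy(), np.zeros(npairs)]
    lo_v = np.array([opts.sigma_bounds[0], opts.sigma_bounds[0], opts.J_bounds[0]])
    hi_v = np.array([opts.sigma_bounds[1], opts.sigma_bounds[1], opts.J_bounds[1]])
    # axis steps plus ridge-aligned directions: for strongly (anti-)correlated
    # patterns the likelihood is nearly flat along sigma1 + sigma2 + J = const
    # (resp. sigma1 - sigma2 = const), which makes purely axis-aligned ascent
    # zigzag; line searches along these directions restore fast convergence
    directions = np.asarray(
        [
            (1.0, 0.0, 0.0),
            (0.0, 1.0, 0.0),
            (0.0, 0.0, 1.0),
            (1.0, 0.0, -1.0),
            (0.0, 1.0, -1.0),
            (1.0, 1.0, 0.0),
            (1.0, -1.0, 0.0),
            (1.0, 1.0, -2.0),
        ]
    )
    ndir = directions.shape[0]
    G = 9
    frac = np.linspace(0.0, 1.0, G)
    ar = np.arange(npairs)

    def feasible_t(dvecs):
        """Largest t-interval per (pair, direction) keeping params in bounds."""
        nd = dvecs.shape[0]
        tlo = np.full((npairs, nd), -np.inf)
        thi = np.full((npairs, nd), np.inf)
        for i in range(3):
            d_i = dvecs[:, i]
            nz = d_i != 0
            if not nz.any():
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                a = (lo_v[i] - params[i][:, None]) / d_i[None, :]
                b = (hi_v[i] - params[i][:, None]) / d_i[None, :]
            tlo[:, nz] = np.maximum(tlo[:, nz], np.minimum(a, b)[:, nz])
            thi[:, nz] = np.minimum(thi[:, nz], np.maximum(a, b)[:, nz])
        return tlo, thi

    def refine_along(dsel, tb, blo, bhi, fstart):
        """Golden refinement along a per-pair direction; updates params.
        1e-4 on the parameter axis is ~1e-8 on the log-likelihood near a
        quadratic optimum, well inside loglik_tol."""
        def ft(tv):
            tv = np.asarray(tv)
            if tv.ndim > 1:
                trial = [p[:, None] + tv * dsel[:, i, None] for i, p in enumerate(params)]
            else:
                trial = [p + tv * dsel[:, i] for i, p in enumerate(params)]
            return L(*trial)

        keep = fstart >= tb[1]
        xb = np.where(keep, 0.0, tb[0])
        fb = np.maximum(fstart, tb[1])
        tstar, fnew = _golden_max_batch(ft, blo, bhi, xb, fb, tol=1e-4)
        for i in range(3):
            params[i] = np.clip(params[i] + tstar * dsel[:, i], lo_v[i], hi_v[i])
        return fnew

    def greedy_step(fstart):
        """One batched grid over all directions, refine each pair's best."""
        tlo, thi = feasible_t(directions)
        tg = tlo[..., None] + (thi - tlo)[..., None] * frac
        trial = [
            params[i][:, None, None] + tg * directions[None, :, i, None]
            for i in range(3)
        ]
        cx, cy = cX2[:, :, None, None, :], cY2[:, :, None, None, :]
        both = _pair_log_weight_sum_batch(treeX, treeY, cx, cy, *trial)
        flat = (both[0] - both[1]).reshape(npairs, -1)
        best = np.argmax(flat, axis=1)
        di, gi = best // G, best % G
        tb = tg[ar, di, gi]
        step = (thi[ar, di] - tlo[ar, di]) / (G - 1)
        blo = np.maximum(tb - step, tlo[ar, di])
        bhi = np.minimum(tb + step, thi[ar, di])
        return refine_along(directions[di], (tb, flat[ar, best]), blo, bhi, fstart)

    def perpair_line_search(dsel, fstart):
        """Line search along a per-pair direction (grid + golden)."""
        tlo = np.full(npairs, -np.inf)
        thi = np.full(npairs, np.inf)
        for i in range(3):
            d_i = dsel[:, i]
            nz = d_i != 0
            if not nz.any():
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                a = (lo_v[i] - params[i]) / d_i
                b = (hi_v[i] - params[i]) / d_i
            tlo[nz] = np.maximum(tlo[nz], np.minimum(a, b)[nz])
            thi[nz] = np.minimum(thi[nz], np.maximum(a, b)[nz])
        dead = ~np.isfinite(tlo) | ~np.isfinite(thi) | (thi <= tlo)
        tlo = np.where(dead, 0.0, tlo)
        thi = np.where(dead, 0.0, thi)
        tg = tlo[:, None] + (thi - tlo)[:, None] * frac[None, :]

        def ft(tv):
            tv = np.asarray(tv)
            if tv.ndim > 1:
                trial = [p[:, None] + tv * dsel[:, i, None] for i, p in enumerate(params)]
            else:
                trial = [p + tv * dsel[:, i] for i, p in enumerate(params)]
            return L(*trial)

        llg = ft(tg)
        best = np.argmax(llg, axis=1)
        tb = tg[ar, best]
        step = (thi - tlo) / (G - 1)
        blo = np.maximum(tb - step, tlo)
        bhi = np.minimum(tb + step, thi)
        return refine_along(dsel, (tb, llg[ar, best]), blo, bhi, fstart)

    def gradient_direction(fcur):
        """Per-pair finite-difference gradient of L, normalized.

        The three perturbed evaluations run as one batched call."""
        eps = 1e-5
        trial = [
            p[:, None] + eps * np.asarray([i == j for i in range(3)], float)
            for j, p in enumerate(params)
        ]
        g = (L(*trial) - fcur[:, None]) / eps
        # zero out components pushing through an active bound
        for i in range(3):
            at_hi = params[i] >= hi_v[i] - 1e-9
            at_lo = params[i] <= lo_v[i] + 1e-9
            g[at_hi & (g[:, i] > 0), i] = 0.0
            g[at_lo & (g[:, i] < 0), i] = 0.0
        norms = np.linalg.norm(g, axis=1)
        ok = norms > 1e-12
        g[ok] /= norms[ok, None]
        g[~ok] = 0.0
        return g

    def cycling_sweep(fstart, full=True):
        """Line searches along the fixed directions (when ``full``), the
        local gradient, and a Powell-style acceleration step along the
        sweep's aggregate displacement (tracks curved ridges toward the
        parameter bounds)."""
        p0 = [p.copy() for p in params]
        fcur = fstart
        for k in range(ndir if full else 0):
            dvec = directions[k][None, :]
            tlo, thi = feasible_t(dvec)
            tlo, thi = tlo[:, 0], thi[:, 0]
            tg = tlo[:, None] + (thi - tlo)[:, None] * frac[None, :]
            dsel = np.broadcast_to(directions[k], (npairs, 3))

            def ft(tv):
                tv = np.asarray(tv)
                if tv.ndim > 1:
                    trial = [
                        p[:, None] + tv * dsel[:, i, None] for i, p in enumerate(params)
                    ]
                else:
                    trial = [p + tv * dsel[:, i] for i, p in enumerate(params)]
                return L(*trial)

            llg = ft(tg)
            best = np.argmax(llg, axis=1)
            tb = tg[ar, best]
            step = (thi - tlo) / (G - 1)
            blo = np.maximum(tb - step, tlo)
            bhi = np.minimum(tb + step, thi)
            fcur = refine_along(dsel, (tb, llg[ar, best]), blo, bhi, fcur)
        g = gradient_direction(fcur)
        if np.any(g != 0):
            fcur = perpair_line_search(g, fcur)
        dagg = np.stack([params[i] - p0[i] for i in range(3)], axis=1)
        norms = np.linalg.norm(dagg, axis=1)
        moved = norms > 1e-12
        if moved.any():
            dagg[moved] /= norms[moved, None]
            dagg[~moved] = 0.0
            fcur = perpair_line_search(dagg, fcur)
        return fcur

    fcur = L(*params)
    converged = np.zeros(npairs, dtype=bool)
    # fast greedy phases, then full cycling sweeps for robustness; once the
    # fixed directions are exhausted, later sweeps use only the gradient and
    # aggregate-displacement searches (cheap, and they track curved ridges);
    # convergence is declared only when a whole sweep makes no progress
    for sweep in range(opts.max_iter):
        if sweep < 2:
            for _ in range(3):
                fnew = greedy_step(fcur)
                done = np.all(fnew - fcur < opts.loglik_tol)
                fcur = fnew
                if done:
                    break
        fprev = fcur.copy()
        fcur = cycling_sweep(fcur, full=(sweep < 2))
        converged = fcur - fprev < opts.loglik_tol
        if np.all(converged):
            break
    s1_out, s2_out = params[0].copy(), params[1].copy()
    if swapped.any():
        s1_out[swapped], s2_out[swapped] = params[1][swapped], params[0][swapped]
    return {
        "sigma1": s1_out,
        "sigma2": s2_out,
        "J": params[2],
        "loglik_joint": fcur,
        "loglik_indep": ll_indep,
        "converged": converged,
    }


def fit_pair(
    treeX: Phylogeny,
    treeY: Phylogeny,
    patX: ConservationPattern,
    patY: ConservationPattern,
    opts: OptimizerSettings | None = None,
) -> PairScore:
    """Fit the coupled two-site model for one pair of sites.

    ``PairScore.deltaL`` compares the jointly maximized coupled model to the
    independently maximized single-site models; the per-site scores are
    re-fitted jointly because the independent sigma estimates can absorb part
    of the coupling contribution.
    """
    res = fit_pair_batch(
        treeX, treeY, patX.leaf_vector(treeX)[None, :], patY.leaf_vector(treeY)[None, :], opts
    )
    return PairScore(
        sigma1_joint=float(res["sigma1"][0]),
        sigma2_joint=float(res["sigma2"][0]),
        J_hat=float(res["J"][0]),
        loglik_joint=float(res["loglik_joint"][0]),
        loglik_indep=float(res["loglik_indep"][0]),
        converged=bool(res["converged"][0]),
    )


def classify_pair(score: PairScore, cutoff: float) -> str:
    """Correlation call for a fitted pair: 'positive', 'negative' or 'none'.

    A pair is correlated when deltaL reaches the cutoff; the direction is the
    sign of the fitted coupling.  An exact J = 0 tie is 'none'.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if score.deltaL >= cutoff:
        if score.J_hat > 0:
            return "positive"
        if score.J_hat < 0:
            return "negative"
    return "none"
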