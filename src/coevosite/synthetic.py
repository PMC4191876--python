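"""Synthetic data generation: exact model samplers and toy input bundles.

Everything the pipeline consumes can be generated here at toy scale:
random phylogenies with a conservation profile that decays away from the
reference species, exact samples of binary conservation patterns from the
tree MRF at planted (sigma, J), and a full file bundle (MAF alignment, UTR
BED, seed table, footprint BED, gene sets, expression matrix) with a
manifest of planted truths.

Sampling is exact, not MCMC: upward message passing with the reference leaf
clamped, a root draw from its conditional, then downward conditional draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .phylo import Phylogeny, _ref_clamp

__all__ = [
    "random_phylogeny",
    "sample_patterns",
    "sample_pattern_pairs",
    "SimulationSpec",
    "emit_toy_bundle",
]

_RNA = "ACGU"
_DNA = "ACGT"


def random_phylogeny(
    n_leaves: int,
    rng: np.random.Generator,
    loss_rate: float = 0.6,
    rate_sd: float = 0.3,
    eq_logit_root: float = 1.5,
    eq_logit_span: float = 4.0,
) -> Phylogeny:
    """Random time-calibrated Yule phylogeny with a realistic conservation profile.

    The topology is a Yule (pure-birth) tree grown in continuous time, so
    recently diverged relatives of the reference sit at the end of short
    branches while deep splits are long — the structure that makes
    background K-mer conservation high in close species and low in distant
    ones.  The model is generated as a rooted presence/absence Markov chain
    and converted exactly to the undirected (beta, h) parameterization:

    * per-branch persistence ``lambda_e = exp(-mu_e * len_e)`` — the child
      keeps the parent's state with probability ``lambda_e`` and otherwise
      redraws from its equilibrium; ``mu_e`` is ``loss_rate`` with lognormal
      rate heterogeneity of spread ``rate_sd``;
    * per-node equilibrium presence probability
      ``pi_v = sigmoid(eq_logit_root - eq_logit_span * t_v / T)`` decaying
      with node age ``t_v`` (root 0, tips T), emulating the global decline
      of alignable background conservation along the phylogeny.

    The conversion uses the identity that a rooted chain
    ``pi(x_root) * prod_e T_e(x_child | x_parent)`` is a pairwise MRF whose
    edge factor ``log T_e = a + b*x_p + c*x_c + d*x_p*x_c`` maps to an
    agreement coupling ``beta_e = d/2`` with field increments ``b + d/2``
    (parent) and ``c + d/2`` (child).  The reference is the first leaf.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    parent = [-1]
    t_birth = [0.0]
    tips = [0]
    now = 0.0
    while len(tips) < n_leaves:
        now += rng.exponential(1.0 / len(tips))
        v = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            tips.append(len(parent))
            parent.append(v)
            t_birth.append(now)
    T = now + rng.exponential(1.0 / len(tips))
    parent = np.asarray(parent)
    n = parent.size
    is_tip = ~np.isin(np.arange(n), parent)
    t_node = np.asarray(t_birth)
    t_node[is_tip] = T  # ultrametric: all extant species observed today
    if T <= 0:
        raise AssertionError("degenerate Yule tree")
    edge_len = np.zeros(n)
    edge_len[1:] = t_node[1:] - t_node[parent[1:]]
    mu = loss_rate * rng.lognormal(0.0, rate_sd, size=n)
    lam = np.exp(-mu * edge_len)
    pi = 1.0 / (1.0 + np.exp(-(eq_logit_root - eq_logit_span * t_node / T)))
    beta = np.zeros(n)
    h = np.zeros(n)
    h[0] = np.log(pi[0] / (1.0 - pi[0]))
    for c in range(1, n):
        p = parent[c]
        t11 = pi[c] + lam[c] * (1.0 - pi[c])
        t10 = pi[c] * (1.0 - lam[c])  # P(child present | parent absent)
        a = np.log1p(-t10)
        b = np.log1p(-t11) - a
        cc = np.log(t10) - a
        d = np.log(t11) - np.log(t10) - np.log1p(-t11) + np.log1p(-t10)
        beta[c] = d / 2.0
        h[p] += b + d / 2.0
        h[c] += cc + d / 2.0
    # the reference is the tip with the shortest terminal branch, so it has
    # a recently diverged sister species (as human does among vertebrates)
    tip_ids = np.flatnonzero(is_tip)
    ref_node = int(tip_ids[np.argmin(edge_len[tip_ids])])
    names = []
    li = 1
    for v in range(n):
        if v == ref_node:
            names.append("ref")
        elif is_tip[v]:
            names.append(f"sp{li}")
            li += 1
        else:
            names.append(f"anc{v}")
    return Phylogeny(tuple(names), parent, beta, h, ref_node)


def _upward_messages(tree: Phylogeny, clamps: np.ndarray, sigma: float):
    """Log upward messages per node (2-vectors), reference conditioning via clamps."""
    n = tree.n_nodes
    lm = np.zeros((n, 2))
    for v in tree.postorder:
        m = np.array([0.0, tree.h[v] + sigma])
        if clamps[v] == 0:
            m[1] = -np.inf
        elif clamps[v] == 1:
            m[0] = -np.inf
        for c in tree.children[v]:
            b = tree.beta[c]
            m = m + np.array(
                [
                    np.logaddexp(lm[c, 0] + b, lm[c, 1]),
                    np.logaddexp(lm[c, 0], lm[c, 1] + b),
                ]
            )
        lm[v] = m
    return lm


def sample_patterns(
    tree: Phylogeny,
    sigma: float,
    n: int,
    rng: np.random.Generator,
    condition_reference: bool = True,
) -> np.ndarray:
    """Exact ancestral sampling of ``n`` leaf patterns at score ``sigma``.

    Returns an (n, n_leaves) 0/1 array in ``tree.leaves`` order.  With
    ``condition_reference`` the reference leaf is clamped present, matching
    the observation process (only reference-present sites are recorded).
    """
    clamps = _ref_clamp(tree) if condition_reference else np.full(tree.n_nodes, -1, np.int8)
    lm = _upward_messages(tree, clamps, sigma)
    root = tree.root
    p_root = _softmax2(lm[root])
    nn = tree.n_nodes
    states = np.empty((n, nn), dtype=np.int8)
    states[:, root] = rng.random(n) < p_root
    # preorder: parents before children
    for v in tree.postorder[::-1]:
        for c in tree.children[v]:
            b = tree.beta[c]
            xp = states[:, v]
            # P(x_c | x_p) ∝ exp(b*1[x_c = x_p]) * m_up_c(x_c)
            logp1 = lm[c, 1] + b * (xp == 1)
            logp0 = lm[c, 0] + b * (xp == 0)
            p1 = 1.0 / (1.0 + np.exp(np.clip(logp0 - logp1, -700, 700)))
            states[:, c] = rng.random(n) < p1
    return states[:, tree.leaves]


def _softmax2(logv):
    m = np.max(logv)
    e = np.exp(logv - m)
    return e[1] / e.sum()


def _pair_upward_messages(treeX, treeY, clampsX, clampsY, s1, s2, J):
    from scipy.special import logsumexp

    X = np.array([0, 0, 1, 1], float)
    Y = np.array([0, 1, 0, 1], float)
    n = treeX.n_nodes
    lm = np.zeros((n, 4))
    for v in treeX.postorder:
        m = (treeX.h[v] + s1) * X + (treeY.h[v] + s2) * Y + J * X * Y
        m = m.copy()
        if clampsX[v] >= 0:
            m[X != clampsX[v]] = -np.inf
        if clampsY[v] >= 0:
            m[Y != clampsY[v]] = -np.inf
        for c in treeX.children[v]:
            E = treeX.beta[c] * (X[:, None] == X[None, :]) + treeY.beta[c] * (
                Y[:, None] == Y[None, :]
            )
            m = m + logsumexp(E + lm[c][None, :], axis=1)
        lm[v] = m
    return lm


def sample_pattern_pairs(
    treeX: Phylogeny,
    treeY: Phylogeny,
    sigma1: float,
    sigma2: float,
    J: float,
    n: int,
    rng: np.random.Generator,
) -> tuple:
    """Exact sampling of coupled pattern pairs on the 4-state composite chain.

    Returns (patternsX, patternsY), each (n, n_leaves).  At J = 0 this is
    distributionally identical to two independent ``sample_patterns`` draws.
    """
    from scipy.special import logsumexp

    X = np.array([0, 0, 1, 1], np.int8)
    Y = np.array([0, 1, 0, 1], np.int8)
    clamps = _ref_clamp(treeX)
    lm = _pair_upward_messages(treeX, treeY, clamps, clamps, sigma1, sigma2, J)
    root = treeX.root
    logp = lm[root] - logsumexp(lm[root])
    p = np.exp(logp)
    p = p / p.sum()
    nn = treeX.n_nodes
    states = np.empty((n, nn), dtype=np.int8)
    states[:, root] = rng.choice(4, size=n, p=p)
    for v in treeX.postorder[::-1]:
        for c in treeX.children[v]:
            E = treeX.beta[c] * (X[:, None] == X[None, :]) + treeY.beta[c] * (
                Y[:, None] == Y[None, :]
            )
            logw = E[states[:, v]] + lm[c][None, :]  # (n, 4)
            logw = logw - logsumexp(logw, axis=1, keepdims=True)
            w = np.exp(logw)
            w = w / w.sum(axis=1, keepdims=True)
            u = rng.random(n)
            states[:, c] = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)
    leaf_states = states[:, treeX.leaves]
    return X[leaf_states], Y[leaf_states]


# ---------------------------------------------------------------------------
# toy input bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulationSpec:
    """Everything needed to emit a self-consistent toy input bundle."""

    n_leaves: int = 10
    sigma_true: float = 3.0
    n_genes: int = 10
    utr_length: int = 400
    sites_per_gene: int = 5
    seed7: str = "GAGGUAG"
    n_footprints_per_gene: int = 2
    footprint_width: int = 40
    background_divergence: float = 0.15
    rng_seed: int = 0
    tree: Phylogeny | None = None
    extra_seeds: tuple = ()


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTU", "TGCAA"))[::-1]


def _seed_match_8mer(seed7: str) -> str:
    """Target-strand 8mer match: reverse complement of seed positions 2-8 plus A."""
    return _revcomp(seed7) + "A"


def _random_utr(length: int, rng, forbidden: str) -> str:
    """Random DNA without chance occurrences of the planted match core."""
    core = forbidden[:6]
    while True:
        seq = "".join(rng.choice(list(_DNA), size=length))
        if core not in seq and _revcomp(core) not in seq:
            return seq


def _mutate(s: str, rate: float, rng) -> str:
    out = []
    for ch in s:
        if rng.random() < rate:
            out.append(rng.choice([c for c in _DNA if c != ch]))
        else:
            out.append(ch)
    return "".join(out)


def emit_toy_bundle(spec: SimulationSpec, out_dir) -> dict:
    """Write a complete toy input bundle and return its manifest.

    Files: ``alignment.maf``, ``utrs.bed``, ``seeds.tsv``, ``footprints.bed``,
    ``genesets.gmt``, ``expression.tsv``, ``tree.nwk`` (plus sidecar
    ``tree_params.tsv``), and ``manifest.json`` with the planted truths.

    Sites are planted as 8mer matches; each sampled conservation pattern is
    realized in the alignment by writing the identical match at orthologous
    columns where present, and a substituted or gapped stretch (fair coin)
    where absent.  Background columns diverge per species at
    ``spec.background_divergence`` per site, scaled by leaf depth.
    """
    rng = np.random.default_rng(spec.rng_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = spec.tree or random_phylogeny(spec.n_leaves, rng)
    leaf_names = tree.leaf_names
    ref_name = tree.reference_name
    match8 = _seed_match_8mer(spec.seed7)
    L = spec.utr_length
    manifest = {"rng_seed": spec.rng_seed, "reference": ref_name, "genes": {}, "sites": []}

    # depth-scaled divergence so background K-mer conservation decays
    depth = np.zeros(tree.n_nodes)
    for v in tree.postorder[::-1]:
        p = tree.parent[v]
        if p >= 0:
            depth[v] = depth[p] + 1
    leaf_depth = {tree.names[v]: depth[v] for v in tree.leaves}
    max_depth = max(leaf_depth.values()) or 1.0

    maf_blocks = []
    utr_lines = []
    fp_lines = []
    site_rows = []
    for g in range(spec.n_genes):
        gene = f"gene{g}"
        ref_seq = _random_utr(L, rng, match8)
        # non-overlapping planted positions, away from UTR edges
        slots = np.arange(10, L - 20, 16)
        pos = np.sort(rng.choice(slots, size=spec.sites_per_gene, replace=False))
        ref_seq = list(ref_seq)
        for p in pos:
            ref_seq[p : p + 8] = match8
        ref_seq = "".join(ref_seq)
        patterns = sample_patterns(tree, spec.sigma_true, spec.sites_per_gene, rng)
        rows = {}
        for i, sp in enumerate(leaf_names):
            if sp == ref_name:
                rows[sp] = list(ref_seq)
                continue
            rate = spec.background_divergence * (0.3 + 0.7 * leaf_depth[sp] / max_depth)
            row = list(_mutate(ref_seq, rate, rng))
            for k, p in enumerate(pos):
                present = patterns[k, leaf_names.index(sp)]
                if present:
                    row[p : p + 8] = match8
                else:
                    if rng.random() < 0.5:
                        row[p : p + 8] = "-" * 8  # gap: evidence of absence
                    else:
                        mut = list(match8)
                        j = int(rng.integers(8))
                        mut[j] = rng.choice([c for c in _DNA if c != mut[j]])
                        row[p : p + 8] = mut
            rows[sp] = row
        maf_blocks.append((gene, {sp: "".join(rows[sp]) for sp in leaf_names}))
        utr_lines.append(f"chr{g}\t0\t{L}\t{gene}\t0\t+")
        for k, p in enumerate(pos):
            site_rows.append(
                {
                    "gene_id": gene,
                    "position": int(p),
                    "type": "8mer",
                    "pattern": {
                        sp: int(patterns[k, leaf_names.index(sp)]) for sp in leaf_names
                    },
                }
            )
        # footprints centered on a subset of planted sites; mark every site
        # a footprint happens to overlap (wide footprints can span neighbors)
        cov = rng.choice(len(pos), size=min(spec.n_footprints_per_gene, len(pos)), replace=False)
        gene_fps = []
        for c in sorted(cov):
            center = int(pos[c]) + 4
            a = max(0, center - spec.footprint_width // 2)
            gene_fps.append((a, a + spec.footprint_width))
            fp_lines.append(f"chr{g}\t{a}\t{a + spec.footprint_width}\t{gene}_fp{c}")
        for k, p in enumerate(pos):
            if any(a < p + 8 and p < b for a, b in gene_fps):
                site_rows[-len(pos) + k]["in_footprint"] = True
    manifest["sites"] = site_rows
    manifest["genes"] = {f"gene{g}": {"chrom": f"chr{g}", "length": L} for g in range(spec.n_genes)}

    with open(out / "alignment.maf", "w") as fh:
        fh.write("##maf version=1\n")
        for gene, rows in maf_blocks:
            chrom = f"chr{int(gene[4:])}"
            fh.write("a score=0\n")
            for sp in leaf_names:
                text = rows[sp]
                size = len(text.replace("-", ""))
                fh.write(f"s {sp}.{chrom} 0 {size} + {L} {text}\n")
            fh.write("\n")
    (out / "utrs.bed").write_text("\n".join(utr_lines) + "\n")
    (out / "footprints.bed").write_text("\n".join(fp_lines) + "\n" if fp_lines else "")
    seeds = [("fam-planted", spec.seed7, len(leaf_names))] + [
        (f"fam{i}", s, len(leaf_names)) for i, s in enumerate(spec.extra_seeds)
    ]
    (out / "seeds.tsv").write_text(
        "family_id\tseed7\tn_species\n"
        + "\n".join(f"{a}\t{b}\t{c}" for a, b, c in seeds)
        + "\n"
    )
    genes = [f"gene{g}" for g in range(spec.n_genes)]
    half = len(genes) // 2
    gmt = [
        "set_complexlike\tsynthetic\t" + "\t".join(genes[:half]),
        "set_pathwaylike\tsynthetic\t" + "\t".join(genes[half:]),
    ]
    (out / "genesets.gmt").write_text("\n".join(gmt) + "\n")
    fams = [s[0] for s in seeds]
    expr = rng.gamma(2.0, 1.0, size=(len(fams), 6))
    with open(out / "expression.tsv", "w") as fh:
        fh.write("family_id\t" + "\t".join(f"tissue{t}" for t in range(6)) + "\n")
        for i, f in enumerate(fams):
            fh.write(f + "\t" + "\t".join(f"{v:.4f}" for v in expr[i]) + "\n")
    from .io import write_tree

    write_tree(tree, out / "tree.nwk", out / "tree_params.tsv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
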