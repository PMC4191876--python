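"""Control seeds and conservation-matched control site pairs.

Control seeds are synthetic 7-mers statistically matched to real miRNA
seeds: drawn from a first-order Markov chain fitted to the dinucleotide
frequencies of the real seeds, filtered against (1) known vertebrate miRNA
seeds, (2) reverse complements of known RNA-binding-protein motifs, and
(3) an information-content floor of 0.4 bits; surviving candidates are
accepted with probability proportional to the empirical information-content
distribution of real seeds.

Two-tier matching to real sites: first control seeds are selected per miRNA
family by site count (+/-15% per site type) and by similarity of their
conservation-score histograms (10 equipopulated bins, relative squared
difference); then control site pairs are re-sampled with a biased bootstrap
whose weights are the ratio of real to control bin counts of mean pair
conservation, with per-sample rescaling factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ControlSeed",
    "MatchedControlSet",
    "BootstrapSample",
    "info_content",
    "generate_control_seeds",
    "match_controls_by_count",
    "match_controls_by_conservation",
    "biased_bootstrap",
]

_RNA = "ACGU"


@dataclass(frozen=True)
class ControlSeed:
    sequence: str
    info: float


@dataclass(frozen=True)
class MatchedControlSet:
    """Best-matching control seeds for one miRNA family, order randomized."""

    family_id: str
    controls: tuple  # control ids in randomized order
    metrics: dict  # control id -> histogram distance
    seed: int  # rng seed used for the ordering


@dataclass(frozen=True)
class BootstrapSample:
    """One bootstrap resample of control pairs."""

    indices: np.ndarray  # indices into the control pair list
    rescale: float  # n_real_pairs / n_sample_pairs

    def __post_init__(self):
        if self.rescale <= 0:
            raise ValueError("rescale factor must be positive")


def info_content(seed: str) -> float:
    """Information content of a 7-mer in bits: 2 minus composition entropy.

    I = 2 + sum_n f_n log2 f_n, with f_n the nucleotide frequencies within
    the seed; ranges from ~0 (maximally mixed) to 2 (single letter).
    """
    if any(c not in _RNA for c in seed):
        raise ValueError(f"seed {seed!r} must be over A, C, G, U")
    counts = [seed.count(c) for c in _RNA]
    total = len(seed)
    ent = -sum((c / total) * math.log2(c / total) for c in counts if c)
    return 2.0 - ent


def _dinucleotide_chain(seeds):
    """First-order transition matrix + marginal start distribution."""
    counts = np.zeros((4, 4))
    starts = np.zeros(4)
    idx = {c: i for i, c in enumerate(_RNA)}
    for s in seeds:
        for a, b in zip(s, s[1:]):
            counts[idx[a], idx[b]] += 1
        for c in s:
            starts[idx[c]] += 1
    counts += 1e-9  # avoid dead states
    trans = counts / counts.sum(axis=1, keepdims=True)
    starts = starts / starts.sum()
    return starts, trans


def _ic_histogram(seeds, bins):
    vals = [info_content(s) for s in seeds]
    hist, _ = np.histogram(vals, bins=bins)
    return hist / max(hist.sum(), 1)


def generate_control_seeds(
    real_seeds,
    forbidden_seeds,
    rbp_motifs,
    n: int = 5000,
    rng: np.random.Generator | None = None,
    min_info: float = 0.4,
    max_draws: int = 5_000_000,
    ic_reweight: bool = True,
):
    """Generate ``n`` control seeds matched to the real seed statistics.

    real_seeds : 7-mer RNA strings (or SeedDef with .seed7).
    forbidden_seeds : seeds of any known vertebrate miRNA (rejected exactly).
    rbp_motifs : RNA motifs; a candidate whose reverse complement equals any
        motif is rejected.
    """
    rng = rng or np.random.default_rng(0)
    seqs = [getattr(s, "seed7", s) for s in real_seeds]
    if not seqs:
        raise ValueError("need at least one real seed")
    starts, trans = _dinucleotide_chain(seqs)
    forbidden = {getattr(s, "seed7", s) for s in forbidden_seeds} | set(seqs)
    rc = str.maketrans("ACGU", "UGCA")
    motif_set = {m.upper().replace("T", "U") for m in rbp_motifs}
    bins = np.linspace(0.0, 2.0, 11)
    ic_target = _ic_histogram(seqs, bins)
    accept_p = ic_target / max(ic_target.max(), 1e-12)
    out = []
    draws = 0
    while len(out) < n:
        draws += 1
        if draws > max_draws:
            raise RuntimeError(
                f"control seed acceptance rate too low: {len(out)}/{n} "
                f"after {max_draws} draws"
            )
        letters = [rng.choice(4, p=starts)]
        for _ in range(6):
            letters.append(rng.choice(4, p=trans[letters[-1]]))
        cand = "".join(_RNA[i] for i in letters)
        if cand in forbidden:
            continue
        if cand.translate(rc)[::-1] in motif_set:
            continue
        ic = info_content(cand)
        if ic <= min_info:
            continue
        if ic_reweight:
            b = min(int(np.digitize(ic, bins)) - 1, len(accept_p) - 1)
            if rng.random() >= accept_p[b]:
                continue
        out.append(ControlSeed(sequence=cand, info=ic))
    return out


def match_controls_by_count(family_counts: dict, control_counts: dict, tolerance: float = 0.15):
    """Controls whose per-type site counts fall within +/-tolerance of the family's.

    family_counts : site type -> count for the real miRNA family.
    control_counts : control id -> {site type -> count}.
    Returns {site type: [control ids]} matched independently per type.
    """
    out = {}
    for st, c in family_counts.items():
        lo = math.ceil((1 - tolerance) * c - 1e-9)
        hi = math.floor((1 + tolerance) * c + 1e-9)
        out[st] = [
            cid
            for cid, counts in sorted(control_counts.items())
            if lo <= counts.get(st, 0) <= hi
        ]
        if not out[st]:
            import warnings

            warnings.warn(f"no count-matched controls for site type {st} (count {c})")
    return out


def _equipopulated_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin edges with (near-)equal occupancy on ``values``."""
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.quantile(np.asarray(values, float), qs)
    edges[0], edges[-1] = -np.inf, np.inf
    return edges


def match_controls_by_conservation(
    real_sigmas,
    control_sigmas: dict,
    n_ctrl: int,
    family_id: str = "",
    n_bins: int = 10,
    seed: int = 0,
    overlapping: dict | None = None,
) -> MatchedControlSet:
    """Select the control seeds whose sigma histograms best match the real one.

    Bins are equipopulated on the real sigma values; the matching metric is
    the relative squared difference sum_b (c_b - r_b)^2 / r_b.  Control
    sites overlapping any real site must be removed by the caller or passed
    via ``overlapping`` (control id -> boolean mask over its sigma values).
    The selected controls are returned in randomized order to avoid an
    implicit quality hierarchy.
    """
    real_sigmas = np.asarray(real_sigmas, dtype=float)
    if real_sigmas.size < n_bins:
        raise ValueError(f"need >= {n_bins} real sites for {n_bins} bins")
    edges = _equipopulated_bins(real_sigmas, n_bins)
    r, _ = np.histogram(real_sigmas, bins=edges)
    r = r.astype(float)
    metrics = {}
    for cid, sig in sorted(control_sigmas.items()):
        sig = np.asarray(sig, dtype=float)
        if overlapping is not None and cid in overlapping:
            sig = sig[~np.asarray(overlapping[cid], bool)]
        if sig.size == 0:
            continue
        c, _ = np.histogram(sig, bins=edges)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (c - r) ** 2 / np.where(r > 0, r, np.nan)
        metrics[cid] = float(np.nansum(term))
    if not metrics:
        raise ValueError("all control seeds were overlap-filtered to empty")
    ranked = sorted(metrics, key=lambda k: (metrics[k], k))[:n_ctrl]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ranked))
    return MatchedControlSet(
        family_id=family_id,
        controls=tuple(ranked[i] for i in order),
        metrics={k: metrics[k] for k in ranked},
        seed=seed,
    )


def biased_bootstrap(
    real_sbar,
    control_sbar,
    B: int = 100,
    n_bins: int = 10,
    seed: int = 0,
    weight_cap: float = 1e3,
):
    """Bootstrap control pairs re-weighted toward the real conservation mix.

    real_sbar / control_sbar : mean conservation score (sigma-bar) per pair.
    Bins are equipopulated on the real values; each control pair's sampling
    weight is proportional to real_bin_count / control_bin_count, so the
    resampled sigma-bar distribution matches the real one.  Identical
    histograms give equal weights — the plain unbiased bootstrap.  Each
    sample of size len(control_sbar) carries a rescaling factor
    n_real / n_sample for count comparisons.
    """
    real_sbar = np.asarray(real_sbar, dtype=float)
    control_sbar = np.asarray(control_sbar, dtype=float)
    if real_sbar.size == 0 or control_sbar.size == 0:
        raise ValueError("both pair sets must be non-empty")
    edges = _equipopulated_bins(real_sbar, n_bins)
    r, _ = np.histogram(real_sbar, bins=edges)
    c, _ = np.histogram(control_sbar, bins=edges)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, r / np.maximum(c, 1e-300), np.nan)
    if np.any(np.isnan(ratio) & (r > 0)):
        import warnings

        warnings.warn("empty control bin with nonzero real bin; weight capped")
    ratio = np.nan_to_num(ratio, nan=weight_cap)
    ratio = np.minimum(ratio, weight_cap)
    which = np.clip(np.digitize(control_sbar, edges) - 1, 0, n_bins - 1)
    w = ratio[which]
    if w.sum() <= 0:
        raise ValueError("all bootstrap weights are zero")
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    n_sample = control_sbar.size
    samples = []
    for _ in range(B):
        idx = rng.choice(control_sbar.size, size=n_sample, replace=True, p=p)
        samples.append(
            BootstrapSample(indices=idx, rescale=real_sbar.size / n_sample)
        )
    return samples, w
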