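"""End-to-end pipeline stages over the file-based interfaces.

Each stage reads/writes plain TSV artifacts in the run directory so stages
can be re-run independently; all randomness is derived from one global seed
through a deterministic per-stage offset.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import controls, enrichment, phylo, seedscan
from .io import read_bed, read_seed_table, read_tree

logger = logging.getLogger("coevosite")

# fixed per-stage seed offsets: one global seed reproducibly fans out
STAGE_SEED = {"simulate": 11, "scan": 23, "pairs": 37, "controls": 53, "enrich": 71}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) * 1_000_003 + STAGE_SEED[stage]) % (2**31 - 1)


def load_alignments(maf_path, utr_bed_path, tree) -> list:
    """Stitch every UTR interval in the BED over the MAF blocks."""
    blocks = seedscan.read_maf_blocks(maf_path)
    utrs = read_bed(utr_bed_path)
    species = tree.leaf_names
    out = []
    for utr in utrs.itertuples():
        sub = [
            b
            for b in blocks
            if tree.reference_name in b and b[tree.reference_name]["chrom"] == utr.chrom
        ]
        out.append(
            seedscan.stitch_maf(
                sub,
                {
                    "chrom": utr.chrom,
                    "start": utr.start,
                    "end": utr.end,
                    "strand": utr.strand,
                    "name": utr.name,
                },
                species,
                tree.reference_name,
            )
        )
    return out


def scan_stage(maf_path, utr_bed_path, seeds_path, tree_nwk, tree_params, out_dir, site_types=None):
    """MAF + UTRs + seeds -> site calls with conservation patterns."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = read_tree(tree_nwk, tree_params)
    seeds = read_seed_table(seeds_path)
    alns = load_alignments(maf_path, utr_bed_path, tree)
    calls = seedscan.build_site_matrix(
        alns, seeds, site_types or seedscan.ANALYSIS_TYPES
    )
    rows = []
    for c in calls:
        rows.append(
            {
                "site_id": c.site_id,
                "gene_id": c.gene_id,
                "seed": c.seed,
                "type": c.site_type,
                "position": c.position,
                "length": c.length,
                "pattern": "".join(
                    str(c.pattern.values[sp]) for sp in tree.leaf_names
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["site_id", "gene_id", "seed", "type", "position", "length", "pattern"],
    )
    df.to_csv(out / "sites.tsv", sep="\t", index=False)
    logger.info("scan: %d sites over %d genes", len(df), df["gene_id"].nunique() if len(df) else 0)
    return df, calls, tree


def score_sites_stage(sites_tsv, tree_nwk, tree_params, out_dir, opts=None):
    """Fit the conservation score sigma and log-likelihood ratio D per site."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = read_tree(tree_nwk, tree_params)
    df = pd.read_csv(sites_tsv, sep="\t", dtype={"pattern": str})
    if len(df) == 0:
        scored = df.assign(sigma_hat=[], D=[])
        scored.to_csv(out / "site_scores.tsv", sep="\t", index=False)
        return scored
    lv = np.array([[int(ch) for ch in p] for p in df["pattern"]], dtype=np.int8)
    sig, llh, ll0 = phylo.fit_sigma_batch(tree, lv, opts)
    scored = df.assign(sigma_hat=sig, D=llh - ll0)
    scored.to_csv(out / "site_scores.tsv", sep="\t", index=False, float_format="%.6g")
    return scored


def score_pairs_stage(
    scored_sites: pd.DataFrame,
    tree,
    out_dir,
    scope="same_utr",
    max_sites=200,
    n_subsets=5,
    seed=0,
    min_sigma=None,
    opts=None,
):
    """Enumerate in-scope pairs and fit the coupled model for each."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = scored_sites
    if min_sigma is not None:
        df = df[df["sigma_hat"] >= min_sigma]
    pair_meta = []
    lvX, lvY = [], []
    by_gene = {}
    records = list(df.itertuples())
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    rng = np.random.default_rng(seed)
    for gene in sorted(by_gene):
        sites = by_gene[gene]
        if len(sites) > max_sites:
            subsets = [
                rng.choice(len(sites), size=max_sites, replace=False)
                for _ in range(n_subsets)
            ]
        else:
            subsets = [np.arange(len(sites))]
        for si, idx in enumerate(subsets):
            chosen = [sites[i] for i in sorted(idx)]
            for i in range(len(chosen)):
                for j in range(i + 1, len(chosen)):
                    a, b = chosen[i], chosen[j]
                    pair_meta.append(
                        {
                            "site1": a.site_id,
                            "site2": b.site_id,
                            "gene_id": gene,
                            "family1": a.seed,
                            "family2": b.seed,
                            "distance": abs(a.position - b.position),
                            "same_gene": True,
                            "same_family": a.seed == b.seed,
                            "subset": si,
                            "sigma1_indep": a.sigma_hat,
                            "sigma2_indep": b.sigma_hat,
                        }
                    )
                    lvX.append([int(ch) for ch in a.pattern])
                    lvY.append([int(ch) for ch in b.pattern])
    if not pair_meta:
        cols = ["site1", "site2", "gene_id", "deltaL", "J", "sign"]
        empty = pd.DataFrame(columns=cols)
        empty.to_csv(out / "pair_scores.tsv", sep="\t", index=False)
        return empty
    res = phylo.fit_pair_batch(
        tree, tree, np.asarray(lvX, np.int8), np.asarray(lvY, np.int8), opts
    )
    pairs = pd.DataFrame(pair_meta).assign(
        sigma1=res["sigma1"],
        sigma2=res["sigma2"],
        J=res["J"],
        deltaL=res["loglik_joint"] - res["loglik_indep"],
        converged=res["converged"],
    )
    pairs["sbar"] = (pairs["sigma1_indep"] + pairs["sigma2_indep"]) / 2.0
    pairs.to_csv(out / "pair_scores.tsv", sep="\t", index=False, float_format="%.6g")
    return pairs


def enrich_stage(
    real_pairs: pd.DataFrame,
    control_pairs: pd.DataFrame,
    out_dir,
    pair_cutoff=2.0,
    B=100,
    n_bins=10,
    seed=0,
    close_distance=100,
):
    """Category summaries (close/distant x same/different family) vs controls."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, _ = controls.biased_bootstrap(
        real_pairs["sbar"].to_numpy(),
        control_pairs["sbar"].to_numpy(),
        B=B,
        n_bins=n_bins,
        seed=seed,
    )
    summaries = []
    cats = {
        "all": np.ones(len(real_pairs), bool),
        "close": real_pairs["distance"].to_numpy() < close_distance,
        "distant": real_pairs["distance"].to_numpy() >= close_distance,
        "close_same_family": (real_pairs["distance"].to_numpy() < close_distance)
        & real_pairs["same_family"].to_numpy(),
    }
    ctl_cats = {
        "all": np.ones(len(control_pairs), bool),
        "close": control_pairs["distance"].to_numpy() < close_distance,
        "distant": control_pairs["distance"].to_numpy() >= close_distance,
        "close_same_family": (control_pairs["distance"].to_numpy() < close_distance),
    }
    for name, mask in cats.items():
        cmask = ctl_cats[name]
        if mask.sum() == 0 or cmask.sum() == 0:
            continue
        csub = control_pairs[cmask]
        s, _ = controls.biased_bootstrap(
            real_pairs[mask]["sbar"].to_numpy(),
            csub["sbar"].to_numpy(),
            B=B,
            n_bins=min(n_bins, max(1, mask.sum() // 2)),
            seed=seed,
        )
        summaries.append(
            enrichment.summarize_category(
                name,
                real_pairs[mask]["deltaL"].to_numpy(),
                real_pairs[mask]["J"].to_numpy(),
                csub["deltaL"].to_numpy(),
                csub["J"].to_numpy(),
                s,
                pair_cutoff,
            )
        )
    df = pd.DataFrame([vars(s) for s in summaries])
    df.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.4g")
    return df
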