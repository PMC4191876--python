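"""File formats: trees with parameter sidecars, seed tables, BED, score tables.

Trees travel as plain newick (topology only) plus a tab-separated sidecar
holding the MRF parameters: one row per node with its field ``h`` and the
coupling ``beta`` on the edge to its parent.  Interval inputs are BED
(0-based half-open); seed families, site scores and pair scores are TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .phylo import Phylogeny

__all__ = [
    "write_tree",
    "read_tree",
    "read_seed_table",
    "read_bed",
    "write_site_table",
    "write_pair_table",
    "SeedDef",
]


@dataclass(frozen=True)
class SeedDef:
    """A miRNA family seed: the 7 letters at mature positions 2-8 (RNA)."""

    family_id: str
    seed7: str
    n_species: int = 0

    def __post_init__(self):
        if len(self.seed7) != 7 or any(c not in "ACGU" for c in self.seed7):
            raise ValueError(f"{self.family_id}: seed7 must be 7 letters over ACGU")


def _newick_of(tree: Phylogeny) -> str:
    def rec(v: int) -> str:
        ch = tree.children[v]
        if not ch:
            return tree.names[v]
        return "(" + ",".join(rec(c) for c in ch) + ")" + tree.names[v]

    return rec(tree.root) + ";"


def write_tree(tree: Phylogeny, newick_path, params_path) -> None:
    """Write topology as newick and parameters as a node/edge sidecar TSV."""
    Path(newick_path).write_text(_newick_of(tree) + "\n")
    rows = []
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        rows.append(
            {
                "node": tree.names[v],
                "parent": tree.names[p] if p >= 0 else ".",
                "beta": tree.beta[v] if p >= 0 else 0.0,
                "h": tree.h[v],
                "is_reference": int(v == tree.reference),
            }
        )
    pd.DataFrame(rows).to_csv(params_path, sep="\t", index=False)


def read_tree(newick_path, params_path) -> Phylogeny:
    """Read a tree written by :func:`write_tree`."""
    params = pd.read_csv(params_path, sep="\t")
    ref_rows = params.loc[params["is_reference"] == 1, "node"]
    if len(ref_rows) != 1:
        raise ValueError("sidecar must mark exactly one reference leaf")
    beta = dict(zip(params["node"], params["beta"]))
    h = dict(zip(params["node"], params["h"]))
    nwk = Path(newick_path).read_text().strip()
    return Phylogeny.from_newick(nwk, reference=str(ref_rows.iloc[0]), beta=beta, h=h)


def read_seed_table(path) -> list:
    """TSV with columns family_id, seed7[, n_species] -> list of SeedDef."""
    df = pd.read_csv(path, sep="\t")
    n = df["n_species"] if "n_species" in df else pd.Series(0, index=df.index)
    return [
        SeedDef(str(f), str(s), int(k))
        for f, s, k in zip(df["family_id"], df["seed7"], n)
    ]


def read_bed(path) -> pd.DataFrame:
    """BED file -> DataFrame(chrom, start, end, name, ...); validates coordinates."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": start,
                    "end": end,
                    "name": parts[3] if len(parts) > 3 else f"iv{lineno}",
                    "score": parts[4] if len(parts) > 4 else ".",
                    "strand": parts[5] if len(parts) > 5 else "+",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_site_table(calls, scores, path) -> None:
    """One row per scored site: ids, type, position, sigma_hat, D."""
    rows = []
    for call, sc in zip(calls, scores):
        rows.append(
            {
                "site_id": call.site_id,
                "gene_id": call.gene_id,
                "seed": call.seed,
                "type": call.site_type,
                "position": call.position,
                "sigma_hat": sc.sigma_hat,
                "D": sc.D,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_pair_table(pair_rows, path) -> None:
    """One row per scored pair (ids, sigma1, sigma2, J, deltaL, sign, ...)."""
    pd.DataFrame(pair_rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
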