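"""Seed-match scanning over stitched multi-species 3'UTR alignments.

Workflow: MAF blocks anchored on the reference genome are stitched over a
reference 3'UTR interval; the ungapped reference row is scanned for the five
canonical seed-match types (8mer, 7merA1, 7merm8, 6mer, offset 6mer, in
that precedence order); each match is classified as conserved in another
species iff that species carries the identical match string at the
orthologous alignment columns with no gap inside the span.  Gaps and
unalignable stretches count as absence — an alignment gap is evidence
against conservation, not missing data.

Coordinates are 0-based half-open throughout; site positions are reported
relative to the 3'UTR start in the reference species (transcript
orientation; minus-strand UTRs are reverse-complemented).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .io import SeedDef, read_bed
from .phylo import ConservationPattern

__all__ = [
    "StitchedAlignment",
    "SiteCall",
    "stitch_maf",
    "read_maf_blocks",
    "seed_sites",
    "conservation_pattern",
    "build_site_matrix",
    "filter_sites_by_intervals",
    "enumerate_pairs",
    "SITE_TYPES",
    "ANALYSIS_TYPES",
]

SITE_TYPES = ("8mer", "7merA1", "7merm8", "6mer", "offset6mer")
# default analysis set: 7mer and 8mer matches only (6mers have poor
# conservation signal-to-noise and are excluded downstream)
ANALYSIS_TYPES = ("8mer", "7merA1", "7merm8")

_COMP = str.maketrans("ACGTUN", "TGCAAN")
ABSENT = "*"  # filler for species stretches with no alignable row


def _revcomp_dna(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class StitchedAlignment:
    """Gapped rows over stitched MAF columns for one reference 3'UTR."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    species: list
    rows: dict  # species -> gapped string, all equal length
    reference: str

    def __post_init__(self):
        lens = {len(r) for r in self.rows.values()}
        if len(lens) > 1:
            raise ValueError(f"{self.gene_id}: unequal row lengths {lens}")
        ref_row = self.rows[self.reference]
        self._ref_cols = [i for i, c in enumerate(ref_row) if c != "-"]
        if len(self._ref_cols) != self.end - self.start:
            raise ValueError(
                f"{self.gene_id}: reference row covers {len(self._ref_cols)} bases, "
                f"UTR has {self.end - self.start}"
            )

    def reference_sequence(self) -> str:
        row = self.rows[self.reference]
        return "".join(row[i] for i in self._ref_cols)

    def columns(self, utr_start: int, utr_end: int) -> tuple:
        """Column span covering reference positions [utr_start, utr_end)."""
        return self._ref_cols[utr_start], self._ref_cols[utr_end - 1] + 1

    def span_identical(self, species: str, utr_start: int, utr_end: int) -> bool:
        """True iff ``species`` carries the identical ungapped reference
        subsequence at the orthologous columns."""
        c0, c1 = self.columns(utr_start, utr_end)
        ref_piece = self.rows[self.reference][c0:c1]
        sp_piece = self.rows[species][c0:c1]
        if ABSENT in sp_piece:
            return False
        # exact column-wise identity: any species gap opposite a reference
        # base (or insertion opposite a reference gap) breaks the site
        return sp_piece == ref_piece


@dataclass(frozen=True)
class SiteCall:
    """One seed-match occurrence in the reference UTR with its pattern."""

    site_id: str
    gene_id: str
    seed: str  # family or control id
    site_type: str
    position: int  # match start relative to UTR start (transcript orient.)
    length: int
    match: str
    pattern: ConservationPattern

    def __post_init__(self):
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")

    @property
    def span(self) -> tuple:
        return self.position, self.position + self.length


def read_maf_blocks(path):
    """Parse a MAF file into blocks of {species: (start, size, strand, srcsize, text)}.

    Species are taken from the part of the MAF source name before the first
    dot when present (UCSC style ``hg19.chr1``); otherwise the whole name.
    """
    blocks = []
    current = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("a"):
                if current:
                    blocks.append(current)
                current = {}
            elif line.startswith("s") and current is not None:
                parts = line.split()
                src, start, size, strand, srcsize, text = parts[1:7]
                sp, _, chrom = src.partition(".")
                current[sp] = {
                    "chrom": chrom or src,
                    "start": int(start),
                    "size": int(size),
                    "strand": strand,
                    "srcsize": int(srcsize),
                    "text": text.upper(),
                }
    if current:
        blocks.append(current)
    return blocks


def stitch_maf(
    maf_blocks,
    utr,
    species,
    reference: str,
    gene_id: str | None = None,
    ref_fill: str = "N",
) -> StitchedAlignment:
    """Stitch reference-anchored MAF blocks over one reference UTR interval.

    ``utr`` is a mapping/namespace with chrom, start, end, strand, name.
    Blocks are cropped to the UTR, concatenated in reference order; reference
    stretches covered by no block are filled with ``ref_fill`` (never matches
    a seed) in the reference row and with the absent marker in every other
    row — such stretches score as absence downstream.  Minus-strand UTRs are
    reverse-complemented into transcript orientation at the end.
    """
    chrom = utr["chrom"] if isinstance(utr, dict) else utr.chrom
    ustart = utr["start"] if isinstance(utr, dict) else utr.start
    uend = utr["end"] if isinstance(utr, dict) else utr.end
    strand = (utr.get("strand", "+") if isinstance(utr, dict) else utr.strand) or "+"
    name = gene_id or (utr.get("name") if isinstance(utr, dict) else utr.name)

    rel = []  # (ref_start, ref_end, block) relative to genome
    for blk in maf_blocks:
        if reference not in blk:
            continue
        ref = blk[reference]
        if ref["chrom"] != chrom and ref["chrom"]:
            continue
        b0, b1 = ref["start"], ref["start"] + ref["size"]
        if b1 <= ustart or b0 >= uend:
            continue
        rel.append((b0, b1, blk))
    rel.sort(key=lambda t: t[0])
    for (a0, a1, _), (b0, b1, _) in itertools.pairwise(rel):
        if b0 < a1:
            raise ValueError(
                f"{name}: overlapping MAF blocks on reference at [{b0}, {a1})"
            )

    out_rows = {sp: [] for sp in species}
    cursor = ustart

    def fill_gap(n):
        for sp in species:
            out_rows[sp].append((ref_fill if sp == reference else ABSENT) * n)

    for b0, b1, blk in rel:
        if b0 > cursor:
            fill_gap(b0 - cursor)
            cursor = b0
        ref = blk[reference]
        text = ref["text"]
        # crop block columns to [max(b0,ustart), min(b1,uend)) in ref coords
        keep0, keep1 = max(b0, cursor), min(b1, uend)
        # map reference positions to block columns
        cols = [i for i, c in enumerate(text) if c != "-"]
        c0 = cols[keep0 - b0]
        c1 = cols[keep1 - b0 - 1] + 1
        for sp in species:
            if sp in blk:
                out_rows[sp].append(blk[sp]["text"][c0:c1])
            else:
                out_rows[sp].append(ABSENT * (c1 - c0))
        cursor = keep1
    if cursor < uend:
        fill_gap(uend - cursor)

    rows = {sp: "".join(parts) for sp, parts in out_rows.items()}
    if strand == "-":
        rows = {sp: _revcomp_dna(r).replace(ABSENT, ABSENT) for sp, r in rows.items()}
    return StitchedAlignment(
        gene_id=name,
        chrom=chrom,
        start=ustart,
        end=uend,
        strand=strand,
        species=list(species),
        rows=rows,
        reference=reference,
    )


def _match_strings(seed: SeedDef) -> dict:
    """Target-strand (mRNA) match strings for the five site types.

    With the seed = mature miRNA positions 2-8 (s2..s8), the mRNA match is
    the reverse complement (in DNA letters): rc(2-8) pairs positions 8..2,
    and an adenine opposite miRNA position 1 extends 7merA1/8mer sites.
    """
    rc28 = _revcomp_dna(seed.seed7)  # 7 nt, pairs seed positions 8..2
    rc27 = rc28[1:]  # 6 nt, pairs positions 7..2
    rc38 = rc28[:6]  # 6 nt, pairs positions 8..3
    return {
        "8mer": rc28 + "A",
        "7merA1": rc27 + "A",
        "7merm8": rc28,
        "6mer": rc27,
        "offset6mer": rc38,
    }


# offset from a match start to the canonical core (the rc(2-7) hexamer) —
# used to de-duplicate the same underlying site across types
_CORE_OFFSET = {"8mer": 1, "7merm8": 1, "7merA1": 0, "6mer": 0, "offset6mer": 1}


def seed_sites(seed: SeedDef, utr_sequence: str) -> list:
    """All seed-match occurrences in a reference UTR sequence.

    Returns (position, site_type, match_string) tuples ordered by position.
    Each underlying site (identified by the position of its canonical seed
    core) is reported once, under the highest-precedence type that matches;
    'N' never matches anything.
    """
    seq = utr_sequence.upper().replace("U", "T")
    if any(c not in "ACGTN" for c in seq):
        raise ValueError("UTR sequence must be over A, C, G, T/U, N")
    matches = _match_strings(seed)
    claimed = set()
    out = []
    for st in SITE_TYPES:
        m = matches[st]
        start = 0
        while True:
            p = seq.find(m, start)
            if p < 0:
                break
            core = p + _CORE_OFFSET[st]
            if core not in claimed:
                claimed.add(core)
                out.append((p, st, m))
            start = p + 1
    return sorted(out)


def conservation_pattern(aln: StitchedAlignment, position: int, length: int, site_id: str) -> ConservationPattern:
    """Score one site's presence across species at orthologous columns.

    A species scores 1 iff its row carries the identical match string with
    no gap or absent marker inside the span; the reference scores 1 by
    construction.
    """
    values = {}
    for sp in aln.species:
        if sp == aln.reference:
            values[sp] = 1
        else:
            values[sp] = int(aln.span_identical(sp, position, position + length))
    return ConservationPattern(site_id=site_id, gene_id=aln.gene_id, values=values)


def build_site_matrix(alignments, seeds, site_types=ANALYSIS_TYPES) -> list:
    """Enumerate SiteCalls over genes x seeds, deterministically ordered.

    ``alignments``: iterable of StitchedAlignment with unique gene ids.
    Ordering is (gene, position, seed family).
    """
    seen_genes = set()
    calls = []
    for aln in alignments:
        if aln.gene_id in seen_genes:
            raise ValueError(f"duplicate gene id {aln.gene_id!r}")
        seen_genes.add(aln.gene_id)
        ref_seq = aln.reference_sequence()
        gene_calls = []
        for seed in seeds:
            for pos, st, match in seed_sites(seed, ref_seq):
                if st not in site_types:
                    continue
                site_id = f"{aln.gene_id}:{pos}:{seed.family_id}"
                pat = conservation_pattern(aln, pos, len(match), site_id)
                gene_calls.append(
                    SiteCall(
                        site_id=site_id,
                        gene_id=aln.gene_id,
                        seed=seed.family_id,
                        site_type=st,
                        position=pos,
                        length=len(match),
                        match=match,
                        pattern=pat,
                    )
                )
        calls.extend(sorted(gene_calls, key=lambda c: (c.position, c.seed)))
    return calls


def filter_sites_by_intervals(calls, intervals, utr_table=None) -> list:
    """Keep calls whose reference genomic span overlaps >= 1 interval by >= 1 base.

    ``intervals`` is a BED DataFrame (read_bed) or a path.  Site positions
    are UTR-relative; ``utr_table`` maps gene_id -> (chrom, utr_start,
    strand, utr_end) so spans can be placed on the genome.  For plus-strand
    UTRs genomic span = [utr_start + pos, utr_start + pos + len); minus
    strand counts from the UTR end.
    """
    if not hasattr(intervals, "itertuples"):
        intervals = read_bed(intervals)
    by_chrom = {}
    for iv in intervals.itertuples():
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    kept = []
    for call in calls:
        if utr_table is not None:
            chrom, ustart, uend, strand = utr_table[call.gene_id]
            if strand == "-":
                g1 = uend - call.position
                g0 = g1 - call.length
            else:
                g0 = ustart + call.position
                g1 = g0 + call.length
        else:
            chrom, g0, g1 = call.gene_id, call.position, call.position + call.length
        for a, b in by_chrom.get(chrom, ()):
            if a < g1 and g0 < b:
                kept.append(call)
                break
    return kept


def enumerate_pairs(
    calls,
    scope: str = "same_utr",
    gene_sets: dict | None = None,
    max_sites: int = 200,
    n_subsets: int = 5,
    seed: int = 0,
    close_distance: int = 100,
):
    """Enumerate annotated site pairs within a scope.

    scope 'same_utr': all pairs of sites in the same gene; 'gene_set': all
    pairs of sites within each gene set (requires ``gene_sets`` mapping
    set_id -> gene ids).  When a scoped site collection exceeds
    ``max_sites``, ``n_subsets`` random subsets of ``max_sites`` sites are
    drawn (seeded) and each pair is tagged with its subset index; downstream
    p-values are reported as the median over subsets.

    Yields dicts: site1, site2 (SiteCall), distance (reference-position
    distance, or None across genes), close (distance < close_distance),
    same_gene, same_family, subset, set_id.
    """
    rng = np.random.default_rng(seed)

    def pairs_of(site_list, set_id):
        if len(site_list) > max_sites:
            subsets = [
                rng.choice(len(site_list), size=max_sites, replace=False)
                for _ in range(n_subsets)
            ]
        else:
            subsets = [np.arange(len(site_list))]
        for si, idx in enumerate(subsets):
            chosen = [site_list[i] for i in sorted(idx)]
            for a, b in itertools.combinations(chosen, 2):
                same_gene = a.gene_id == b.gene_id
                dist = abs(a.position - b.position) if same_gene else None
                yield {
                    "site1": a,
                    "site2": b,
                    "distance": dist,
                    "close": (dist is not None and dist < close_distance),
                    "same_gene": same_gene,
                    "same_family": a.seed == b.seed,
                    "subset": si,
                    "set_id": set_id,
                }

    if scope == "same_utr":
        by_gene = {}
        for c in calls:
            by_gene.setdefault(c.gene_id, []).append(c)
        for gene in sorted(by_gene):
            yield from pairs_of(by_gene[gene], gene)
    elif scope == "gene_set":
        if gene_sets is None:
            raise ValueError("scope 'gene_set' requires gene_sets")
        by_gene = {}
        for c in calls:
            by_gene.setdefault(c.gene_id, []).append(c)
        for set_id in sorted(gene_sets):
            members = [c for g in sorted(gene_sets[set_id]) for c in by_gene.get(g, [])]
            yield from pairs_of(members, set_id)
    else:
        raise ValueError(f"unknown scope {scope!r}")


def read_gmt(path) -> dict:
    """GMT gene sets: set_id <tab> source <tab> member genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = tuple(parts[2:])
    return sets
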