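# Methods

## The model

`coevosite` scores the conservation of short sequence elements (miRNA seed
matches) in a reference species' 3'UTRs across a multiple-species alignment,
and detects correlated evolution between pairs of such sites.  The state of
a site in species (or ancestor) `v` is binary, `x_v ∈ {0, 1}` (present /
absent).  The background model is a Markov random field on the species tree
with hidden ancestral nodes: a configuration `x` over all nodes has weight

    w(x) = exp( Σ_edges β_e·1[x_u = x_v] + Σ_nodes h_v·x_v )

The per-edge coupling `β_e` plays the role of a branch length (agreement
strength along a branch) and the per-node field `h_v` sets a species- and
clade-dependent equilibrium presence probability — required because the
average conservation of background K-mers is not constant along the
phylogeny (alignment gaps, unalignable UTRs, and clade-specific UTR
expansion all depress it unevenly).  On a tree this MRF is formally
equivalent to a time-reversible two-state Markov model with non-constant
equilibrium; we keep the undirected parameterization because it makes the
conservation and coupling scores below single tilt parameters.

All likelihoods condition on presence in the reference species, because
sites are only ever observed in the reference genome; species with a gap or
no alignable sequence at a site score 0 (absence), never "missing" —
alignment gaps are treated as evidence against conservation, and the
gene-class background absorbs systematic absence from assembly quality.

**Site conservation.** A per-site score σ tilts every node toward presence:
`P_σ(pattern) ∝ Tr_hidden w(x)·exp(σ Σ_v x_v)`, the trace summing hidden
ancestral states exactly by upward message passing.  The ML estimate σ̂ and
the log-likelihood ratio `D = log L(σ̂) − log L(0)` quantify preferential
conservation beyond the background; `D ≥ 0` up to optimizer tolerance
because the background is nested at σ = 0.

**Pair coupling.** Two sites are combined into a composite 4-state variable
per node with an interaction `J·Σ_v x_v y_v`.  The jointly maximized
coupled likelihood against the product of independently maximized
single-site likelihoods gives `ΔL`; a pair is called correlated when ΔL
exceeds a cutoff (config knob `pair_cutoff`, default 2.0 in natural-log
units) with direction from the sign of Ĵ.  The per-site scores are
re-fitted inside the joint model because the independent σ̂ estimates can
absorb part of the coupling contribution.  Robustness to the cutoff choice
should be checked per analysis; every statistic downstream takes the cutoff
as a parameter.

## Exact inference and optimization

All partition sums are computed in log domain by upward message passing
(exact on trees, `O(states² · nodes)`), vectorized across sites, parameter
grids, and pairs by grouping tree nodes into depth levels.  Brute-force
enumeration oracles (`coevosite.oracle`) verify the engine to ~1e-11
relative error on small trees.

σ is maximized by a coarse grid over the bounds (default [−15, 15], 41
points, always including 0) followed by golden-section refinement around
the best grid point; the refinement tracks the best point ever evaluated,
so `D ≥ 0` holds exactly whenever 0 is on the grid.

The 3-parameter pair fit starts from the nested independent optimum
(σ̂₁, σ̂₂, 0) — which guarantees ΔL ≥ 0 up to floating-point rounding — and
ascends by batched line searches.  Fixed search directions include the
coordinate axes and ridge-aligned combinations such as (1, 1, −2) and
(1, −1, 0): for strongly correlated patterns the likelihood is nearly flat
along σ₁+σ₂+J = const, and axis-only ascent zigzags.  Early sweeps cycle
through all directions; later sweeps follow the local (finite-difference)
gradient plus a Powell-style step along the sweep's aggregate displacement,
which tracks the curved ridges that degenerate patterns (e.g. two
near-identical patterns) produce.  Convergence is declared when a full
sweep improves the log-likelihood by less than `loglik_tol` (default 1e-6);
pairs still moving after `max_iter` (default 25) sweeps are returned with
`converged = False`.  For such degenerate ridge cases — whose maximizer
sits near a corner of the (σ₁, σ₂, J) box and whose ΔL is far above any
sensible cutoff — the residual error is ≲ 1e-2 in log-likelihood units.
Pair results are made exactly swap-invariant by canonicalizing the order of
the two patterns before fitting.

J bounds default to [−10, 10].  Estimates at the bounds occur for
degenerate pattern pairs (identical or complementary across species) and
are the binary-data analogue of infinite log-odds in a 2×2 table with an
empty cell; medians and cutoff-based counts are the robust summaries.

## Background fitting

Empirical statistics: for each gene, every overlapping reference K-mer
(default K = 7) is scored present/absent per species under the same
identical-at-orthologous-columns rule as seed matches, giving per-species
frequencies `f_s` and per-pair joint frequencies `f_st`.  Pair frequencies
carry the phylogenetic information: under shared ancestry `f_st` exceeds
`f_s·f_t` for related species, the excess a species-independence model
cannot express.

Genes are grouped into conservation classes by quantile binning of their
mean per-species K-mer conservation (default 20 classes; deterministic,
gene-id tie-break).  Binning on the mean, rather than clustering full
profiles, is a deliberate simplification: it is monotone, reproducible, and
absorbs the dominant axis of UTR-level heterogeneity.

Per class, (β, h) are fitted by least-squares moment matching —
`Σ_s (p_s − f_s)² + Σ_{s<t} (p_st − f_st)²` with model marginals `p_s`,
`p_st` computed exactly by clamped message passing — using L-BFGS-B with
finite-difference gradients and 3 seeded restarts (stop at `ftol = 1e-10`
or 500 iterations).  With 46 species this is 990 pair constraints against
~180 parameters, so the fitted *distribution* is the meaningful outcome,
not the individual parameters.  Infeasible targets (e.g. anti-correlated
pair frequencies under agreement-only couplings) return the best
least-squares solution with `converged = False`.

## Seed-match scanning

The five canonical site types are written out explicitly on the mRNA
strand, with `rc` the reverse complement of the 7-letter seed (mature miRNA
positions 2–8):

| type       | match string      | length |
|------------|-------------------|--------|
| 8mer       | rc(2–8) + A       | 8      |
| 7merA1     | rc(2–7) + A       | 7      |
| 7merm8     | rc(2–8)           | 7      |
| 6mer       | rc(2–7)           | 6      |
| offset6mer | rc(3–8)           | 6      |

Precedence follows that order; each underlying site (identified by the
genomic position of its rc(2–7) core) is reported once under its
highest-precedence type.  `N` never matches.  The default analysis subset
is 8mer + both 7mers; 6mers have poor conservation signal-to-noise.

MAF blocks are stitched over reference UTR intervals (0-based half-open;
minus-strand UTRs reverse-complemented into transcript orientation);
reference stretches covered by no block are filled with `N` in the
reference row and an absent marker elsewhere.  A species is conserved at a
site iff its row is column-for-column identical to the reference across the
site span — no re-alignment, no shift tolerance, no gap forgiveness.
Choosing the longest 3'UTR isoform per gene is the caller's responsibility.

## Controls

Control seeds are drawn from a stationary first-order Markov chain fitted
to the dinucleotide frequencies of the real seeds, rejected if they (1)
equal any known miRNA seed, (2) have a reverse complement matching a known
RNA-binding-protein motif, or (3) have information content
`I = 2 + Σ_n f_n log₂ f_n ≤ 0.4` bits; survivors are accepted with
probability proportional to the real seeds' empirical information-content
histogram.  Note the acceptance step intentionally reshapes composition, so
the emitted pool's dinucleotide table is close to, but not exactly, the
chain's.  Forbidden-seed and motif lists are input files, not bundled data.

Matching is two-tiered.  Per miRNA family: controls with a similar site
count (±15%, per site type independently) and the most similar σ histogram
(10 equipopulated bins on the real values, relative squared difference
metric, overlap-filtered), returned in randomized order (default 50 per
family; configurable).  Per pair category: a biased bootstrap over control
pairs with sampling weights proportional to real/control bin-count ratios
of mean pair conservation σ̄ (10 equipopulated bins, weights capped at 1e3
when a control bin is empty), B = 100 samples, each carrying the rescaling
factor n_real/n_sample.  With identical histograms this reduces exactly to
the unbiased bootstrap.

## Significance

Counts of correlated control pairs across bootstrap samples are
Poisson-like (variance ≈ mean), so observed counts are tested with an
upper-tail Poisson test against the bootstrap mean; the estimation noise in
that mean (finitely many bootstrap samples) is ignored — a documented
limitation.  Positive and negative correlated counts are treated as
independent Poisson variables and their difference tested two-sidedly (as
two one-sided tails) with the Skellam distribution; a brute-force Poisson
convolution cross-checks the Bessel-function pmf.  Gene-set scans report
per-set, per-stratum (same-gene / different-gene) excesses with
Benjamini–Hochberg control at 5% FDR across sets.  Network comparisons use
two-sided Fisher's exact tests on shared vs. distinct edges over the common
node universe (edges = top 50% of weights by default, boundary ties
included); score-distribution comparisons use two-sided Mann–Whitney U with
tie correction.  When site subsets were drawn (more than 200 sites in
scope: 5 random subsets of 200), p-values are reported as the median over
subsets.

## Synthetic data

The generator emulates the study's data shapes at toy scale, with every
piece of randomness derived from one seed.

*Trees.* Yule (pure-birth) topologies grown in continuous time, so the
reference — chosen as the tip with the shortest terminal branch — has a
recently diverged sister, like a human reference among vertebrates.  The
model is constructed as a rooted presence/absence chain (per-branch
persistence `λ_e = exp(−μ_e·len_e)`, lognormal rate heterogeneity; per-node
equilibrium decaying with node age) and converted exactly into (β, h).
Defaults (`loss_rate` 0.6, `rate_sd` 0.3, `eq_logit_root` 1.5,
`eq_logit_span` 4.0) were chosen so the conditional background conservation
profile resembles deep vertebrate alignments: ~0.9 for the sister species
decaying to ~0.15 for the most distant clades.  A uniform-(β, h)
parameterization was rejected: it sits in the Ising ordered phase, where
conditioning on the reference cannot propagate and conservation collapses.

*Patterns.* Exact forward-filter / backward-sampling on the tree (and its
4-state composite version for coupled pairs) — no MCMC, no approximation;
sampler moments are tested against exact marginals and full enumeration.

*Bundles.* `emit_toy_bundle` writes MAF/BED/TSV/GMT/expression files with
planted 8mer sites realized from sampled patterns (absence rendered as a
substitution or a gap with equal probability, exercising both scoring
paths), background divergence scaled by leaf depth so toy K-mer statistics
decay like a real conservation profile, and a JSON manifest of planted
truths.  Scanning an emitted bundle recovers exactly the planted site
matrix.

What the toy data does *not* emulate: real nucleotide composition, repeats,
UTR length distributions, alignment-block boundary artifacts (the
conservation-neighborhood correlation between nearby K-mers that makes
matched controls essential on real data), isoform choice, and orthology
mapping.  Passing tests therefore demonstrate correctness of the machinery
and calibration under the model's own assumptions, not performance on real
alignments.

## Verification scale

The test suite and the acceptance script verify, at these problem sizes:
oracle equivalence on 200 random trees (≤ 20 nodes single-site, ≤ 10
pair); distribution normalization on 5-leaf trees; σ recovery from 2000
patterns and Ĵ recovery from 500 pairs (plus a 500-pair null) on a 46-leaf
tree (with a 300-pair null); background self-consistency on an 11-node
tree; statistical calibration with 10⁴-replicate nulls; and an end-to-end
run on a 46-leaf tree with 300 control and 100 planted pairs, 40 null
categories, and a species-only (star-tree) contrast.  Under these frozen conditions the σ̂
mean recovers the truth within a few percent, while per-pair coupling at
J = 1 sits in a weak-detectability regime: the median Ĵ is upward-biased
by boundary-saturated degenerate pairs, and the planted pairs' median ΔL
falls below the 95th percentile of the J = 0 null — individual J = 1 pairs
are detected a minority of the time, which is exactly why category-level
enrichment against matched controls (which is decisively detected) is the
method's unit of inference.

## Known limitations

- Presence/absence is the state space; there is no nucleotide substitution
  model, no context scoring, and no non-canonical site handling.
- One σ per site across all species (no lineage-specific selection beyond
  the background fields).
- ML estimates of J for individual degenerate pairs saturate at the search
  bounds; inference should use cutoff-based counts, not raw Ĵ values.
- Enrichment p-values ignore uncertainty in the bootstrap-estimated control
  mean.
- The background fit is least-squares moment matching, not full maximum
  likelihood over K-mer patterns.
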