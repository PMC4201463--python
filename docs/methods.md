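# Methods

This note documents the models, algorithms and numerical choices behind
`lcnpipe`, and what the synthetic-data generator does and does not emulate.

## Marker selection

A gene qualifies when all of the following hold:

- length ≥ `min_gene_length` (default 2000 bp; the bound is inclusive),
- every intron ≤ `max_intron_length` (default 500 bp, inclusive — a
  501 bp intron fails),
- copy number ≤ `max_copies` (default 1), where the copy number is the
  count of distinct genomic loci hit at E ≤ `copy_evalue_threshold`
  (default 1e-12) in a 12-column similarity table. Hits overlapping the
  gene's own annotated location merge into one self locus; remaining hits
  are clustered per subject sequence, merging hits within 1 kb. The 1 kb
  clustering radius is a package choice — only the E-value threshold is
  externally fixed — and is insensitive for genes a few kb long.

Linked groups chain qualifying genes per sequence region where each
consecutive gap (`next.start − prev.end`, i.e. gap distance, the
conservative reading of "distance between linked genes") is strictly
below `max_linked_distance` (default 30 kb; a gap of exactly 30 kb breaks
the chain). Runs longer than the maximum group size are split greedily
left-to-right into groups of four, then three; the rule is applied
literally, so a run of six yields one group of four and a discarded pair
(reported, not silently dropped). Runs below the minimum size are
likewise reported.

Two further criteria used when assembling real panels — homologues in
other genomes, and evidence of expression — require external resources;
they can be supplied as boolean columns in an auxiliary table and are
ignored when absent.

Coordinates are converted once at parse time: GFF3 1-based inclusive →
0-based half-open; minus-strand genes are reverse-complemented and exon
intervals flipped onto the extracted sequence, so every downstream stage
works in reference orientation.

## Probe design

90-mer probes stepped every 30 bp give 3× tiling density. Offsets are
0, 30, 60, … up to L − 90; when the last step does not land exactly at
L − 90, one extra probe is anchored at the 3′ end so every base is
covered (the tail rule is a package decision; how gene ends were handled
in practice is vendor-side). Probes containing more than `max_ambiguous`
non-ACGT characters (default 0) are dropped and reported. Interior bases
— those at least probe_length − step from both ends — are covered exactly
probe_length/step = 3 times.

## Contig consensus

Contigs bin to every locus they hit at E ≤ 1e-100; contigs qualifying for
several loci are flagged as potential paralogs but kept (removal is a
curation decision). Each contig is placed by its best hit (lowest
E-value, ties by bitscore then contig id) and reverse-complemented when
the hit is on the minus strand.

Merging uses set-union semantics per position: one covering contig
contributes its base; disagreeing contigs contribute the minimal IUPAC
code containing the union of their base sets (existing ambiguity codes
expand to their sets first). This makes the merge a join-semilattice —
commutative, associative, idempotent — and guarantees a position's base
set never shrinks when contigs are added. Union coding rather than
majority voting is deliberate: a diploid's two alleles are both real, and
contigs carry no read-depth information that could justify a vote.
Uncovered stretches between contigs are N-filled at the reference-implied
length so each individual yields exactly one record per locus. Contig
pairs whose overlap identity falls below 70% across ≥ 100 bp are flagged
(possible misassembly or paralogy); the thresholds are package choices
for what is a subjective curation step in practice.

## Likelihood machinery

Site patterns are compressed with multiplicities. Tip observations are
partial-likelihood vectors: unambiguous bases are one-hot, IUPAC codes
spread mass over their base set, gaps and N are all-ones (fully missing).
All models are time-reversible, so the likelihood is root-invariant; the
pruning pass roots arbitrarily at an internal node.

- **Models**: JC69, K80, F81, HKY85, GTR (exchangeabilities with GT as
  reference). Rate matrices are scaled to one expected substitution per
  unit branch length and diagonalized via the π^(1/2) similarity
  transform.
- **Among-site rates**: discrete gamma with four equal-probability
  categories represented by their conditional means (computed from the
  regularized incomplete gamma function, so the category rates average
  exactly 1).
- **Branch optimization**: coordinate-wise. Each sweep refreshes inside
  (subtree) and outside (rest-of-tree) partials; a branch's likelihood as
  a function of its own length is then expressed in the model's
  eigenbasis, making each trial length a single small matrix product.
  Lengths are optimized in log space by golden-section search within
  [1e-9, 10], starting from 0.05; sweeps stop when a sweep improves lnL
  by less than the tolerance (1e-6 for final fits) or after 50 sweeps,
  and the best visited configuration is kept (coordinate updates within a
  sweep use slightly stale partials, so monotonicity is enforced by
  bookkeeping rather than assumed).
- **Exhaustive search**: all (2n−5)!! unrooted topologies, enumerated by
  stepwise tip insertion (3 ≤ n ≤ 8). A coarse pass (two sweeps, loose
  line-search tolerance) ranks every topology; the best eight are refined
  to full tolerance. Ties within 1e-6 lnL break by lexicographically
  smallest canonical Newick. The two-stage design is purely a
  performance choice; the coarse ranking has to separate topologies
  differing by whole units of lnL, far above its noise.
- **Model selection**: each candidate in {JC69, K80, F81, HKY85, GTR} ×
  {+Γ₄, none} is optimized on a fixed neighbor-joining starting topology
  (JC distances), alternating branch-length and parameter optimization
  (kappa and alpha by bounded scalar search, alpha from a log grid
  refined around its argmax with an upper bound of 1e5; GTR
  exchangeabilities by Nelder–Mead in log space). Parameters enter at
  their nested-model values, so a richer model never scores below the
  model it contains (up to optimizer tolerance, ~1e-3 lnL). AIC
  = 2k − 2 lnL with k counting free model parameters plus 2n−3 branch
  lengths; AICc and BIC are available. Ten candidates instead of a full
  88-model scan: the chosen model's only downstream use is one ML tree,
  and the set spans the relevant complexity axis.
- **Bootstrap**: alignment columns are resampled with replacement
  (expressed as multinomial pattern weights); replicate r is seeded
  seed + r; each replicate repeats the exhaustive search (with a narrower
  refinement, justified as above). Support of a bipartition is the
  percentage of replicate ML trees containing it.

## Parsimony statistics

A column is parsimony-informative iff at least two distinct unambiguous
bases each occur in at least two sequences; ambiguity codes and gaps
support no state. GC% counts G, C and S in the numerator over
unambiguously AT/GC-classifiable characters (A, C, G, T, S, W).

Fitch counts treat ambiguity codes as their base sets and gaps/N as
missing (full set, contributing no steps). Per varying site, m_i is the
number of distinct observed unambiguous states minus one and g_i the
maximum possible steps on any binary tree — the number of tips carrying a
non-modal state, verified in the tests against brute-force maximization
over all 5-taxon topologies. CI = Σm/Σs, RI = (Σg − Σs)/(Σg − Σm); when
no site can be homoplasious (Σg = Σm) RI is reported as 1 with a warning.

## Rate calibration

Patristic distances (path sums of branch lengths in subs/site) are
averaged over all ingroup × outgroup pairs. Because the root split is the
most recent common ancestor of any such pair, that mean spans two
root-to-tip lineages and r = d̄ / (2 T_root). The divisor 2 is a
reconstruction validated against the reference panel: d̄ = 0.06 at
T = 15.9 Ma yields 1.887e-9 ≈ the panel's minimum rate 1.9e-9, and the
panel mean rate 3.611e-9 corresponds to d̄ ≈ 0.115 (the panel's printed
mean distance of 0.12 agrees at its two-decimal precision; the residual
is rounding, not forced to agree).

## Rate-distribution fitting

- **Normal**: ML mean and sd (divisor n). The standard error of the mean
  (sd/√n) is always reported next to sd because summaries of rate panels
  often conflate the two — on the reference panel sd = 9.59e-10 while
  se = 1.357e-10, and it is the latter that matches the panel's published
  spread figure.
- **Gamma ML**: Newton iteration on ln k − ψ(k) = ln x̄ − mean(ln x),
  initialized at the moment estimator (x̄/s)², relative tolerance 1e-10,
  shape capped at 1e6 for degenerate samples; scale = x̄/k. On the
  reference panel this gives shape 14.09, scale 2.563e-10 — the estimator
  that reproduces the panel's published shape value.
- **Gamma PPCC**: Pearson correlation between the ordered sample and
  unit-scale gamma quantiles at Filliben order-statistic medians
  (m₁ = 1 − 0.5^(1/n), m_n = 0.5^(1/n), else (i − 0.3175)/(n + 0.365)),
  maximized over a log-spaced shape grid and refined by bounded scalar
  search between the grid neighbors of the argmax. The scale is the
  regression slope (with intercept) of the ordered sample on those
  quantiles; the ML-consistent alternative x̄/shape is reported alongside,
  since the two differ whenever the QQ line has a non-zero intercept.
  Caveat established by simulation during development: at n = 50 the
  PPCC criterion is nearly flat in shape for weakly skewed samples (the
  optimum can run toward the normal limit), so the PPCC shape is a
  diagnostic of fit, not the preferred point estimate; it concentrates
  once skewness is pinned (larger n, or smaller true shape).
- **QQ envelopes**: 10 000 simulated samples of size n from the fitted
  distribution; pointwise 2.5/97.5 percentiles of each order statistic.

## Topology census

A tree's topology key is its set of non-trivial bipartitions (restricted
to a taxon subset when given, degree-2 nodes suppressed), invariant to
rotation, taxon order, branch lengths and supports. A tree counts as
supported for its class iff every internal bipartition has bootstrap
support ≥ the threshold (inclusive at 80). "Supported at all nodes" means
all internal branches of the unrooted tree — three on six taxa; the
per-class supported counts and the overall count are both reported, since
either convention is defensible.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions of the reference panel:
six taxa (four ingroup, two outgroup), root age 1.59e7 years, per-locus
rates gamma(14.076, 3.098e-10), locus lengths 1806–3168 bp, HKY with
GC ≈ 33% and kappa 2, topology weights 34:2:1 over the three built-in
arrangements (the census proportions of the panel), contigs of 400 bp
overlapping by 100, heterozygosity 2e-3 per overlap site (no external
value exists; this is a realistic plant nuclear figure).

- **Gene trees** are ultrametric in time with node ages at fixed
  fractions of the root age (ingroup crown 0.63, outgroup crown 0.3),
  multiplied by the locus rate. With jitter off (the default) every
  cross-root tip pair distance equals exactly 2 T r, making the
  calibration stage's round trip exact; a lognormal branch jitter is
  available for realism but breaks the analytic invariants.
- **The planted rate is the locus-average rate.** Exon sites evolve at
  `exon_rate_multiplier` (default 0.5 — a placeholder contrast, chosen
  as "exons clearly slower", with no external estimate behind it)
  relative to introns, and in full-dataset simulation the site
  multipliers are normalized to mean 1 over the locus. Without this
  convention the alignment-wide substitution rate would be a fixed ~18%
  below the tree's nominal rate (exons cover ~36% of the default gene
  structure) and "rate recovery" would be systematically confounded by a
  deterministic bookkeeping factor rather than measuring inference error.
- **Alignments are gapless**; indel evolution and alignment error are out
  of scope (real alignments arrive from external aligners). Heterozygosity
  exists only at the contig level — two overlapping contigs carry the two
  alleles — because per-individual consensus sequences are what the
  alignment stage consumes.
- **No read-level simulation**: no sequencing error, coverage variation
  or capture-efficiency model. Passing tests therefore demonstrate the
  correctness of the selection/merging/inference/calibration machinery
  under the generative model, not robustness to assembly artifacts or
  alignment error in real data.
- The annotation simulator writes valid GFF3 plus a similarity-hit table
  consistent with the planted copy numbers (self-hits at E = 0, planted
  duplicates at a configurable E-value on either side of the 1e-12
  threshold), with a truth table derived arithmetically from the planted
  parameters — an oracle independent of the selection code.

## Validation design and problem sizes

The end-to-end check simulates 20 panels of 50 loci at 2.5 kb (the
panel's mean locus length) under the default gamma rate distribution,
runs the full inference path (per-locus HKY with estimated kappa,
exhaustive search, cross-root calibration), and compares the ML gamma fit
of the recovered rates with the fit of the planted rates of the same
dataset. Truth is the realized per-dataset rate sample, not the
generating distribution: with n = 50 the sampling error of a gamma(14)
mean is itself ≈ 3.8%, so comparing against the distribution would
conflate sampling noise with inference error — the pipeline's measurement
error is what is being validated. Observed performance: dataset mean
recovered within ~1%, shape within ~8%, single-locus rates within ~3%
(median) at 2.5 kb.

Unit tests exercise the statistically expensive example checks at reduced
replication (10 seeds for topology recovery, 5 for model selection,
30–100 bootstrap replicates) — sizes chosen so each property is tested at
meaningful power while the suite stays fast; the acceptance test runs the
recovery study at its full 20 × 50 size.

## Known limitations

- Exhaustive search caps at 8 taxa by design; no heuristic search is
  provided for larger panels.
- Branch supports assume the exhaustive search per replicate; for very
  low-signal loci the coarse ranking can mis-order near-tied topologies,
  which deflates (never inflates) supports.
- The copy-number assessor consumes an externally produced similarity
  table; it does not run the similarity search itself.
- PPCC shape estimates at panel size n ≈ 50 are diagnostic only (see
  above); prefer the likelihood fit for point estimates.
- The calibration propagates no uncertainty from the root age; rates
  inherit its error linearly.
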