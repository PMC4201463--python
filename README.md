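# lcnpipe

Development and characterization of low-copy nuclear (LCN) phylogenetic
markers from targeted sequence capture, as a tested, reusable Python
library.

## The problem

Resolving species relationships in recently diverged plant groups (the
motivating system is *Medicago* and its sister genus *Melilotus*, tribe
Trifoliae) requires many unlinked nuclear loci: organellar markers share a
single history, and gene-tree discordance — from incomplete lineage
sorting, introgression or paralogy — can only be diagnosed by comparing
well-supported trees from independent loci. The workflow this package
implements turns an annotated reference genome into a characterized marker
panel:

1. **Marker selection** — scan a GFF3/FASTA annotation for genes that are
   ≥ 2 kb long, have introns ≤ 500 bp (so capture fragments span them),
   are single-copy (no second similarity hit at E ≤ 1e-12), and cluster
   into tightly linked groups of 3–4 genes < 30 kb apart (linked genes
   share one history; separate groups sample independent ones).
2. **Probe design** — 90-mer baits tiled every 30 bp (3× density) across
   the whole gene, introns included.
3. **Contig processing** — bin assembled contigs to loci at E ≤ 1e-100,
   orient them, and merge each individual's contigs into one consensus,
   coding allelic conflicts with IUPAC ambiguity codes
   (A + G → R; set-union semantics, no voting).
4. **Gene-tree inference** — per-locus statistics (GC%,
   parsimony-informative sites, Fitch CI/RI), model selection by AIC over
   {JC69, K80, F81, HKY85, GTR} × {+Γ₄}, exhaustive ML search over all
   (2n−5)!! unrooted topologies (105 for six taxa) with bootstrap
   supports.
5. **Rate calibration** — for each gene tree, the mean patristic distance
   d̄ over all ingroup × outgroup pairs spans two root-to-tip lineages, so
   with a dated root split (15.9 Ma) the per-locus substitution rate is

   r = d̄ / (2 T_root)   [substitutions · site⁻¹ · year⁻¹]

6. **Rate priors** — maximum-likelihood normal and gamma fits to the
   per-locus rates (the gamma shape k solves
   ln k − ψ(k) = ln x̄ − mean(ln x)), plus a probability-plot correlation
   coefficient (PPCC) scan over the gamma shape and simulated 95% QQ
   envelopes. The fitted distributions serve as informative rate priors
   for Bayesian phylogenetics and molecular dating.

A first-class synthetic-data generator (`lcnpipe.simulate`) reproduces the
statistical structure of every input — annotated genomes with genes planted
to pass or fail each criterion, ultrametric six-taxon gene trees under a
small topology set with gamma-distributed rates, HKY sequences with a
reduced exon rate, and fragmented heterozygous contigs — so the entire
pipeline is testable end to end without any downloads.

The package ships with the characterized 50-locus *Medicago*/*Melilotus*
reference panel (`lcnpipe.published`): per-locus alignment lengths
(1806–3168 bp), GC%, PI sites, CI/RI and calibrated rates
(1.9–6.1 × 10⁻⁹ subs/site/year).

## Worked example

Fitting rate priors to the reference panel
(`python examples/06_reference_panel_priors.py`):

```
Rate panel: n = 50
  range  : 1.900e-09 .. 6.100e-09 subs/site/year
  mean   : 3.6112e-09
Suggested rate priors:
  normal : mean = 3.6112e-09, sd = 9.5908e-10 (se of mean = 1.3563e-10)
  gamma  : shape = 14.09, scale = 2.5630e-10  [likelihood fit]
  gamma  : shape = 12.93, scale = 2.7591e-10  [PPCC fit, r = 0.9945]

QQ check: 100% of order statistics inside the 95% gamma envelope
```

The normal fit says rates of expressed LCN genes concentrate around
3.6 × 10⁻⁹ subs/site/year; the gamma fit (shape ≈ 14) captures the mild
right skew — about a three-fold spread between the slowest and fastest
locus. Either parameterization can be passed to a Bayesian dating analysis
as the rate prior for markers with similar properties.

Characterizing a single simulated locus
(`python examples/04_infer_gene_tree.py`):

```
locus length : 2500 bp, GC 33.9%
PI sites     : 150 (6.00%)
CI / RI      : 0.98 / 0.95
model        : HKY85, kappa = 2.12
lnL          : -5423.96
topology recovered: True
```

The other examples cover dataset simulation (`01`), marker selection and
probe design (`02`), IUPAC contig merging (`03`), and end-to-end rate
recovery (`05`); each prints what it computes and what the numbers mean.

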