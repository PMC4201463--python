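"""Synthetic data with the statistical structure the marker pipeline
assumes.

The generator emulates the study design end to end: an annotated reference
genome containing linked clusters of genes that pass or fail each selection
criterion; six-taxon gene trees (four ingroup, two outgroup taxa) drawn
from a small topology set, ultrametric in time with a fixed root age, and
scaled by per-locus substitution rates drawn from a gamma or normal
distribution; gapless alignments evolved along those trees under an
HKY-type model with a reduced exon rate; and fragmented, partially
overlapping contigs with injected heterozygous sites to exercise IUPAC
consensus merging.

Everything is deterministic under a fixed seed, and the generative
quantities are exact by construction: with jitter off, the mean cross-root
patristic distance of a simulated tree equals 2 x root_age x rate, which is
what the calibration stage estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .models import BASES, ModelMatrices, SubstitutionModel
from .phylo import Alignment

DEFAULT_INGROUP = ("M_truncatula", "M_italica", "M_sativa", "M_medicaginoides")
DEFAULT_OUTGROUP = ("Mel_sulcatus", "Mel_neapolitanus")

#: Relative node ages (fractions of the root age) for the three built-in
#: 6-taxon topologies.  The ingroup crown is placed at 0.63 of the root age
#: (a 15.9 Ma root puts it near 10 Ma), the outgroup crown at 0.3.
_AGE = {"root": 1.0, "crown": 0.63, "mid": 0.4, "cherry": 0.2, "out": 0.3}

TOPOLOGY_IDS = (1, 2, 3)


@dataclass(frozen=True)
class RateDistribution:
    """Distribution of per-locus substitution rates (subs/site/year)."""

    kind: str = "gamma"        # "gamma" or "normal"
    shape: float = 14.076      # gamma shape
    scale: float = 3.098e-10   # gamma scale
    mean: float = 3.611e-9     # normal mean
    sd: float = 9.6e-10        # normal sd

    def __post_init__(self) -> None:
        if self.kind not in ("gamma", "normal"):
            raise ValueError("rate distribution kind must be gamma or normal")
        if self.kind == "gamma" and (self.shape <= 0 or self.scale <= 0):
            raise ValueError("gamma parameters must be positive")
        if self.kind == "normal" and self.sd < 0:
            raise ValueError("normal sd must be >= 0")


@dataclass(frozen=True)
class ContigScheme:
    """Fragmentation scheme: contig length, junction overlap, and optional
    uncovered gap between consecutive contigs (overlap and gap are mutually
    exclusive per junction)."""

    length: int = 400
    overlap: int = 100
    gap: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.overlap < 0 or self.gap < 0:
            raise ValueError("contig scheme values must be non-negative, length positive")
        if self.length < self.overlap:
            raise ValueError("fragment length must be >= overlap")
        if self.overlap and self.gap:
            raise ValueError("choose either overlap or gap, not both")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_loci: int = 50
    ingroup: tuple[str, ...] = DEFAULT_INGROUP
    outgroup: tuple[str, ...] = DEFAULT_OUTGROUP
    root_age_years: float = 1.59e7
    rate_distribution: RateDistribution = field(default_factory=RateDistribution)
    #: probability of each built-in topology, keyed 1/2/3; defaults follow
    #: the 34:2:1 supported-topology census.
    topology_weights: dict[int, float] = field(
        default_factory=lambda: {1: 34 / 37, 2: 2 / 37, 3: 1 / 37})
    model: SubstitutionModel = field(default_factory=lambda: SubstitutionModel(
        family="HKY85", freqs=(0.335, 0.165, 0.165, 0.335), kappa=2.0))
    exon_rate_multiplier: float = 0.5
    locus_length_range: tuple[int, int] = (1806, 3168)
    heterozygosity: float = 0.002
    contig_scheme: ContigScheme = field(default_factory=ContigScheme)
    branch_jitter_sd: float = 0.0  # lognormal sigma; 0 disables jitter

    def __post_init__(self) -> None:
        w = sum(self.topology_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError("topology weights must sum to 1")
        lo, hi = self.locus_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("locus_length_range must be positive and ordered")
        if not 0 < self.exon_rate_multiplier <= 1:
            raise ValueError("exon_rate_multiplier must be in (0, 1]")
        if not 0 <= self.heterozygosity < 1:
            raise ValueError("heterozygosity must be in [0, 1)")

    @property
    def taxa(self) -> tuple[str, ...]:
        return self.ingroup + self.outgroup


@dataclass
class Contig:
    contig_id: str
    start: int  # position on the source sequence, 0-based half-open
    end: int
    sequence: str


@dataclass
class ContigTruth:
    layout: list[tuple[str, int, int]]
    het_sites: dict[int, tuple[str, str]]


@dataclass
class SimulatedLocus:
    locus_id: str
    true_rate: float
    true_topology_id: int
    gene_tree: dendropy.Tree
    alignment: Alignment
    exon_intervals: list[tuple[int, int]]
    contig_sets: dict[str, list[Contig]]
    contig_truth: dict[str, ContigTruth]


# ---------------------------------------------------------------------------
# rates

def simulate_rates(n: int, dist: RateDistribution, seed: int) -> np.ndarray:
    """Draw n positive per-locus rates; normal draws <= 0 are redrawn."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if dist.kind == "gamma":
        return rng.gamma(dist.shape, dist.scale, size=n)
    rates = rng.normal(dist.mean, dist.sd, size=n)
    while np.any(rates <= 0):
        bad = rates <= 0
        rates[bad] = rng.normal(dist.mean, dist.sd, size=int(bad.sum()))
    return rates


# ---------------------------------------------------------------------------
# gene trees

def _topology_ages(topology_id: int, taxa: Sequence[str]):
    """Nested (children, age) structure for one of the built-in topologies.
    taxa[0..3] are ingroup, taxa[4..5] outgroup; the three topologies
    permute the placement of taxa[2] and taxa[3] relative to the
    (taxa[0], taxa[1]) cherry."""
    t = list(taxa)
    cherry = ((t[0], t[1]), _AGE["cherry"])
    if topology_id == 1:
        ing = (((cherry, t[2]), _AGE["mid"]), t[3])
    elif topology_id == 2:
        ing = (((cherry, t[3]), _AGE["mid"]), t[2])
    elif topology_id == 3:
        ing = (cherry, ((t[2], t[3]), _AGE["mid"]))
    else:
        raise ValueError(f"unknown topology id {topology_id}")
    ingroup = (ing, _AGE["crown"])
    outgroup = ((t[4], t[5]), _AGE["out"])
    return ((ingroup, outgroup), _AGE["root"])


def simulate_gene_tree(topology_id: int, rate: float, root_age_years: float,
                       taxa: Sequence[str] = DEFAULT_INGROUP + DEFAULT_OUTGROUP,
                       seed: int = 0, jitter_sd: float = 0.0) -> dendropy.Tree:
    """Ultrametric 6-taxon gene tree with branch lengths in subs/site.

    Node times are fixed fractions of ``root_age_years``; every branch
    length is (time span) x rate, optionally multiplied by a lognormal
    jitter factor (mean-one on the log scale, default off), so without
    jitter every root-to-tip path equals root_age x rate.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if root_age_years <= 0:
        raise ValueError("root age must be positive")
    rng = np.random.default_rng(seed)
    struct = _topology_ages(topology_id, taxa)

    def render(node, parent_age: float) -> str:
        if isinstance(node, str):
            age = 0.0
            inner = node
        else:
            children, age_frac = node
            age = age_frac
            inner = "(" + ",".join(render(c, age) for c in children) + ")"
        bl = (parent_age - age) * root_age_years * rate
        if jitter_sd > 0:
            bl *= float(rng.lognormal(0.0, jitter_sd))
        return f"{inner}:{bl:.12g}"

    children, root_age_frac = struct
    newick = "(" + ",".join(render(c, root_age_frac) for c in children) + ");"
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


# ---------------------------------------------------------------------------
# sequence evolution

def simulate_alignment(tree: dendropy.Tree, model: SubstitutionModel,
                       length: int, exon_mask: Optional[np.ndarray] = None,
                       exon_rate_multiplier: float = 1.0,
                       seed: int = 0, normalize_rates: bool = False) -> Alignment:
    """Evolve a gapless alignment along the tree.

    Root states are drawn from the model's equilibrium frequencies; each
    branch applies P(t x m) where m is the per-site rate multiplier
    (``exon_rate_multiplier`` under the exon mask, 1 elsewhere; crossed
    with discrete-gamma category rates when the model requests them).

    With ``normalize_rates`` the exon/intron multipliers are rescaled to
    average 1 over the locus, so the tree's nominal rate is the
    alignment-average substitution rate — the quantity the calibration
    stage estimates from whole-locus alignments — and the exon/intron
    contrast only redistributes it.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if exon_mask is not None and len(exon_mask) != length:
        raise ValueError("exon mask length must equal alignment length")
    rng = np.random.default_rng(seed)
    base_model = model.with_(gamma_categories=0, alpha=None)
    mm = ModelMatrices(base_model)
    pi = np.asarray(model.freqs)

    mult = np.ones(length)
    if exon_mask is not None:
        mult[np.asarray(exon_mask, dtype=bool)] = exon_rate_multiplier
    if normalize_rates:
        mult = mult / mult.mean()
    if model.gamma_categories:
        cats = model.category_rates()
        mult = mult * cats[rng.integers(0, len(cats), size=length)]

    classes, class_idx = np.unique(mult, return_inverse=True)
    root_states = rng.choice(4, size=length, p=pi)
    seqs: dict[str, str] = {}

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node._sim_states = root_states
            continue
        t = float(node.edge.length or 0.0)
        parent_states = node.parent_node._sim_states
        child = np.empty(length, dtype=int)
        for ci, m in enumerate(classes):
            idx = np.where(class_idx == ci)[0]
            if idx.size == 0:
                continue
            P = mm.transition(t * m)[0]
            cum = P.cumsum(axis=1)
            u = rng.random(idx.size)
            child[idx] = (u[:, None] > cum[parent_states[idx]]).sum(axis=1)
        node._sim_states = child
        if node.is_leaf():
            label = node.taxon.label
            seqs[label] = "".join(BASES[s] for s in child)

    order = [t.label for t in tree.taxon_namespace]
    return Alignment(order, [seqs[t] for t in order])


def make_exon_mask(length: int, exon_len: int = 250,
                   intron_len: int = 450) -> np.ndarray:
    """Alternating exon/intron structure starting with an exon; with the
    defaults exons cover ~36% of the locus."""
    mask = np.zeros(length, dtype=bool)
    pos = 0
    while pos < length:
        mask[pos: pos + exon_len] = True
        pos += exon_len + intron_len
    return mask


def mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """0-based half-open intervals of True runs."""
    intervals = []
    in_run = False
    for i, v in enumerate(mask):
        if v and not in_run:
            start, in_run = i, True
        elif not v and in_run:
            intervals.append((start, i))
            in_run = False
    if in_run:
        intervals.append((start, len(mask)))
    return intervals


# ---------------------------------------------------------------------------
# contig fragmentation

def fragment_to_contigs(sequence: str, scheme: ContigScheme,
                        heterozygosity: float = 0.0, seed: int = 0,
                        prefix: str = "contig") -> tuple[list[Contig], ContigTruth]:
    """Cut a sequence into tiling contigs with configured overlap or gaps,
    injecting heterozygous sites into overlap regions.

    At each injected site, the two overlapping contigs carry the two
    alternative bases (the earlier contig keeps the source base), so a
    union-semantics merge must emit the corresponding IUPAC code there.
    """
    L = len(sequence)
    if L < scheme.length:
        starts = [0]
    else:
        step = (scheme.length - scheme.overlap) if scheme.gap == 0 \
            else (scheme.length + scheme.gap)
        starts = [0]
        while starts[-1] + scheme.length < L:
            starts.append(starts[-1] + step)
    spans = [(s, min(s + scheme.length, L)) for s in starts]

    rng = np.random.default_rng(seed)
    coverage = np.zeros(L, dtype=int)
    for s, e in spans:
        coverage[s:e] += 1
    het_sites: dict[int, tuple[str, str]] = {}
    if heterozygosity > 0:
        candidates = np.where(coverage >= 2)[0]
        chosen = candidates[rng.random(candidates.size) < heterozygosity]
        for pos in chosen:
            ref = sequence[pos]
            alt = rng.choice([b for b in BASES if b != ref])
            het_sites[int(pos)] = (ref, str(alt))

    contigs = []
    for i, (s, e) in enumerate(spans):
        frag = list(sequence[s:e])
        for pos, (_ref, alt) in het_sites.items():
            # the later (second) covering contig carries the alternate base
            if s <= pos < e and s > 0 and any(
                    s0 <= pos < e0 for s0, e0 in spans[:i]):
                frag[pos - s] = alt
        contigs.append(Contig(f"{prefix}_c{i}", s, e, "".join(frag)))
    truth = ContigTruth(layout=[(c.contig_id, c.start, c.end) for c in contigs],
                        het_sites=het_sites)
    return contigs, truth


# ---------------------------------------------------------------------------
# annotated genome

@dataclass(frozen=True)
class PlantedGene:
    """Specification of one gene planted in the synthetic genome."""

    gene_id: str
    length: int = 2500
    intron_lengths: tuple[int, ...] = (450, 450)
    spacing_after: int = 10_000        # gap to the next planted gene
    n_copies: int = 1                  # >1 plants near-identical duplicates
    copy_evalue: float = 1e-50         # similarity-hit E-value of each copy
    region: str = "chr1"


@dataclass
class SimulatedAnnotation:
    genome: dict[str, str]
    gff3: str
    hit_table: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir) -> None:
        import os
        os.makedirs(outdir, exist_ok=True)
        with open(f"{outdir}/genome.fasta", "w") as fh:
            for region, seq in self.genome.items():
                fh.write(f">{region}\n{seq}\n")
        with open(f"{outdir}/annotation.gff3", "w") as fh:
            fh.write(self.gff3)
        self.hit_table.to_csv(f"{outdir}/hits.tsv", sep="\t",
                              header=False, index=False)
        self.truth.to_csv(f"{outdir}/truth.tsv", sep="\t", index=False)


_HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def simulate_annotation(planted: Sequence[PlantedGene], seed: int = 0,
                        flank: int = 2000,
                        criteria=None) -> SimulatedAnnotation:
    """Build a genome FASTA + GFF3 with the planted genes, a synthetic
    similarity-hit table consistent with the planted copy numbers, and a
    truth table saying which genes must survive each selection criterion
    and how survivors group into linked clusters.
    """
    from .markers import SelectionCriteria  # local import, no cycle at runtime
    crit = criteria or SelectionCriteria()
    rng = np.random.default_rng(seed)

    regions: dict[str, list[str]] = {}
    cursor: dict[str, int] = {}
    layout = []  # (gene, start, end) 0-based half-open on its region
    for pg in planted:
        if sum(pg.intron_lengths) >= pg.length:
            raise ValueError(f"{pg.gene_id}: introns exceed gene length")
        if pg.spacing_after < 0:
            raise ValueError(f"{pg.gene_id}: negative spacing would overlap genes")
        if pg.region not in regions:
            regions[pg.region] = []
            cursor[pg.region] = 0
            pad = "".join(rng.choice(list(BASES), size=flank))
            regions[pg.region].append(pad)
            cursor[pg.region] = flank
        start = cursor[pg.region]
        seq = "".join(rng.choice(list(BASES), size=pg.length))
        regions[pg.region].append(seq)
        layout.append((pg, start, start + pg.length, seq))
        spacer = "".join(rng.choice(list(BASES), size=pg.spacing_after))
        regions[pg.region].append(spacer)
        cursor[pg.region] = start + pg.length + pg.spacing_after

    # plant duplicate copies on a separate region
    dup_region = "chr_dup"
    dup_parts: list[str] = []
    dup_cursor = 0
    dup_layout = []
    for pg, start, end, seq in layout:
        for k in range(pg.n_copies - 1):
            mutated = list(seq)
            n_mut = max(1, int(0.02 * len(seq)))
            pos = rng.choice(len(seq), size=n_mut, replace=False)
            for p in pos:
                mutated[p] = rng.choice([b for b in BASES if b != seq[p]])
            dup_parts.append("".join(rng.choice(list(BASES), size=3000)))
            dup_cursor += 3000
            dup_parts.append("".join(mutated))
            dup_layout.append((pg, dup_cursor, dup_cursor + len(seq)))
            dup_cursor += len(seq)
    if dup_parts:
        regions[dup_region] = dup_parts

    genome = {r: "".join(parts) for r, parts in regions.items()}

    # GFF3 (1-based, inclusive)
    lines = ["##gff-version 3"]
    for region, seq in genome.items():
        lines.append(f"##sequence-region {region} 1 {len(seq)}")
    for pg, start, end, _seq in layout:
        lines.append("\t".join([
            pg.region, "lcnpipe_sim", "gene", str(start + 1), str(end),
            ".", "+", ".", f"ID={pg.gene_id}"]))
        exon_start = start
        exon_lens = _exon_lengths(pg)
        for i, el in enumerate(exon_lens):
            lines.append("\t".join([
                pg.region, "lcnpipe_sim", "exon",
                str(exon_start + 1), str(exon_start + el), ".", "+", ".",
                f"ID={pg.gene_id}.exon{i + 1};Parent={pg.gene_id}"]))
            exon_start += el
            if i < len(pg.intron_lengths):
                exon_start += pg.intron_lengths[i]
    gff3 = "\n".join(lines) + "\n"

    # similarity-hit table (12-column tabular)
    rows = []
    for pg, start, end, _seq in layout:
        rows.append([pg.gene_id, pg.region, 100.0, pg.length, 0, 0,
                     1, pg.length, start + 1, end, 0.0, 2 * pg.length])
    for pg, dstart, dend in dup_layout:
        rows.append([pg.gene_id, dup_region, 98.0, pg.length,
                     int(0.02 * pg.length), 0, 1, pg.length,
                     dstart + 1, dend, pg.copy_evalue,
                     int(1.8 * pg.length)])
    hit_table = pd.DataFrame(rows, columns=_HIT_COLUMNS)

    # truth: per-gene criterion outcomes from the planted parameters alone
    recs = []
    for pg, start, end, _seq in layout:
        max_intron = max(pg.intron_lengths) if pg.intron_lengths else 0
        copies = 1 + sum(1 for q, _, _ in dup_layout
                         if q.gene_id == pg.gene_id
                         and q.copy_evalue <= crit.copy_evalue_threshold)
        ok_len = pg.length >= crit.min_gene_length
        ok_intron = max_intron <= crit.max_intron_length
        ok_copy = copies <= crit.max_copies
        recs.append({"gene_id": pg.gene_id, "region": pg.region,
                     "start": start, "end": end, "length": pg.length,
                     "max_intron": max_intron, "copies": copies,
                     "passes_length": ok_len, "passes_intron": ok_intron,
                     "passes_copies": ok_copy,
                     "passes": ok_len and ok_intron and ok_copy})
    truth = pd.DataFrame(recs)
    truth["group_id"] = _expected_groups(truth, crit)
    return SimulatedAnnotation(genome=genome, gff3=gff3,
                               hit_table=hit_table, truth=truth)


def _exon_lengths(pg: PlantedGene) -> list[int]:
    n_exons = len(pg.intron_lengths) + 1
    coding = pg.length - sum(pg.intron_lengths)
    base = coding // n_exons
    lens = [base] * n_exons
    lens[-1] += coding - base * n_exons
    return lens


def _expected_groups(truth: pd.DataFrame, crit) -> list[Optional[str]]:
    """Direct application of the linkage rule to the planted layout: chain
    passing genes whose gap is under the linkage distance, split long runs
    greedily into groups of 4 then 3, drop runs under the minimum size."""
    out: dict[str, Optional[str]] = {g: None for g in truth.gene_id}
    gid = 0
    for region, sub in truth[truth.passes].groupby("region"):
        sub = sub.sort_values("start")
        run: list[tuple[str, int, int]] = []

        def flush(run):
            nonlocal gid
            i = 0
            while len(run) - i >= crit.group_size[0]:
                take = 4 if len(run) - i >= 4 else 3
                if take > crit.group_size[1]:
                    take = crit.group_size[1]
                gid += 1
                for g, _, _ in run[i:i + take]:
                    out[g] = f"group{gid}"
                i += take

        for _, row in sub.iterrows():
            if run and row.start - run[-1][2] >= crit.max_linked_distance:
                flush(run)
                run = []
            run.append((row.gene_id, row.start, row.end))
        flush(run)
    return [out[g] for g in truth.gene_id]


# ---------------------------------------------------------------------------
# full datasets

def simulate_loci(config: SimulationConfig) -> list[SimulatedLocus]:
    """Generate a full set of loci: rates, trees, alignments and contigs."""
    root = np.random.SeedSequence(config.seed)
    rate_seed, topo_seed, *locus_seeds = root.spawn(2 + config.n_loci)
    rates = simulate_rates(config.n_loci, config.rate_distribution,
                           seed=int(rate_seed.generate_state(1)[0] % (2 ** 31)))
    rng = np.random.default_rng(topo_seed.generate_state(1)[0])
    ids = sorted(config.topology_weights)
    weights = [config.topology_weights[i] for i in ids]
    topo_choices = rng.choice(ids, size=config.n_loci, p=weights)
    lo, hi = config.locus_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_loci)

    loci = []
    for i in range(config.n_loci):
        ss = locus_seeds[i].generate_state(3)
        tree = simulate_gene_tree(int(topo_choices[i]), float(rates[i]),
                                  config.root_age_years, taxa=config.taxa,
                                  seed=int(ss[0] % (2 ** 31)),
                                  jitter_sd=config.branch_jitter_sd)
        mask = make_exon_mask(int(lengths[i]))
        aln = simulate_alignment(tree, config.model, int(lengths[i]),
                                 exon_mask=mask,
                                 exon_rate_multiplier=config.exon_rate_multiplier,
                                 seed=int(ss[1] % (2 ** 31)),
                                 normalize_rates=True)
        aln.locus_id = f"locus{i + 1}"
        contig_sets: dict[str, list[Contig]] = {}
        truths: dict[str, ContigTruth] = {}
        frag_rng = np.random.default_rng(int(ss[2] % (2 ** 31)))
        for taxon in config.taxa:
            cseed = int(frag_rng.integers(0, 2 ** 31))
            contigs, truth = fragment_to_contigs(
                aln.sequence(taxon), config.contig_scheme,
                heterozygosity=config.heterozygosity, seed=cseed,
                prefix=f"{taxon}_locus{i + 1}")
            contig_sets[taxon] = contigs
            truths[taxon] = truth
        loci.append(SimulatedLocus(
            locus_id=f"locus{i + 1}", true_rate=float(rates[i]),
            true_topology_id=int(topo_choices[i]), gene_tree=tree,
            alignment=aln, exon_intervals=mask_to_intervals(mask),
            contig_sets=contig_sets, contig_truth=truths))
    return loci
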