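"""Candidate low-copy nuclear gene selection from an annotated genome.

A gene qualifies as a phylogenetic marker candidate when it is long enough
to yield an informative alignment (>= 2 kb), its introns are short enough
to be spanned by captured fragments (<= 500 bp each), and it is
single-copy in the reference genome as judged from a similarity-hit table
at a strict E-value threshold (1E-12).  Qualifying genes are then chained
into tightly linked groups of three to four genes less than 30 kb apart —
linked genes share one evolutionary history, so each group behaves as one
extended locus while distinct groups sample independent histories.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


@dataclass
class GeneModel:
    """An annotated gene; coordinates are 0-based half-open on the genome,
    exon intervals are expressed on the extracted (strand-corrected) gene
    sequence."""

    gene_id: str
    seq_region: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        prev_end = -1
        for s, e in self.exons:
            if s < 0 or e > len(self.sequence) or e <= s:
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside gene")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, on the gene sequence."""
        return [(self.exons[i][1], self.exons[i + 1][0])
                for i in range(len(self.exons) - 1)]

    @property
    def max_intron_length(self) -> int:
        return max((e - s for s, e in self.introns), default=0)


@dataclass(frozen=True)
class SelectionCriteria:
    min_gene_length: int = 2000
    max_intron_length: int = 500        # inclusive bound
    max_linked_distance: int = 30_000   # strict bound on inter-gene gap
    group_size: tuple[int, int] = (3, 4)
    copy_evalue_threshold: float = 1e-12
    max_copies: int = 1

    def __post_init__(self) -> None:
        if min(self.min_gene_length, self.max_intron_length,
               self.max_linked_distance, self.max_copies) <= 0:
            raise ValueError("criteria thresholds must be positive")
        if self.group_size[0] > self.group_size[1] or self.group_size[0] < 1:
            raise ValueError("group_size must be an ordered positive interval")


@dataclass
class LinkedGroup:
    group_id: str
    seq_region: str
    gene_ids: list[str]   # ordered by start coordinate
    span: int


# ---------------------------------------------------------------------------
# annotation parsing

def parse_annotation(gff3_path, fasta_path) -> list[GeneModel]:
    """Read gene/exon features (GFF3) plus genome sequences (FASTA) into
    GeneModel objects.

    GFF3 1-based inclusive coordinates become 0-based half-open; minus
    strand genes are reverse-complemented and their exon intervals flipped
    onto the extracted sequence.
    """
    genome = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(str(gff3_path), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    genes = []
    for g in db.features_of_type("gene"):
        if g.seqid not in genome:
            raise KeyError(f"region {g.seqid!r} missing from FASTA")
        gstart, gend = g.start - 1, g.end  # to 0-based half-open
        seq = genome[g.seqid][gstart:gend]
        exons = []
        for ex in db.children(g, featuretype="exon", order_by="start"):
            es, ee = ex.start - 1, ex.end
            if es < gstart or ee > gend:
                raise ValueError(
                    f"exon [{es},{ee}) outside gene {g.id} [{gstart},{gend})")
            exons.append((es - gstart, ee - gstart))
        if g.strand == "-":
            seq = str(Seq(seq).reverse_complement())
            L = gend - gstart
            exons = sorted((L - e, L - s) for s, e in exons)
        genes.append(GeneModel(gene_id=g.id, seq_region=g.seqid,
                               start=gstart, end=gend, strand=g.strand,
                               exons=exons, sequence=seq))
    return genes


def read_hit_table(path_or_df) -> pd.DataFrame:
    """Load a 12-column tabular similarity-hit table (headerless TSV)."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
        df.columns = HIT_COLUMNS[: len(df.columns)]
    else:
        try:
            df = pd.read_csv(path_or_df, sep="\t", header=None,
                             names=HIT_COLUMNS)
        except Exception as exc:
            raise ValueError(f"malformed hit table: {exc}") from exc
    if df.shape[1] != 12:
        raise ValueError("hit table must have 12 columns")
    for i, ev in enumerate(df["evalue"]):
        if not (float(ev) >= 0):
            raise ValueError(f"malformed hit row {i + 1}: negative E-value")
    return df


# ---------------------------------------------------------------------------
# selection

def assess_copy_number(gene: GeneModel, hit_table: pd.DataFrame,
                       evalue_threshold: float = 1e-12,
                       cluster_radius: int = 1000) -> int:
    """Number of distinct genomic loci the gene hits at E <= threshold.

    Hits overlapping the gene's own annotated location merge into one
    (self) locus; remaining hits are clustered by subject sequence and
    coordinate proximity (hits within ``cluster_radius`` merge).
    """
    hits = hit_table[hit_table["qseqid"] == gene.gene_id]
    if hits.empty:
        raise ValueError(f"no similarity evidence for gene {gene.gene_id}")
    hits = hits[hits["evalue"] <= evalue_threshold]
    if hits.empty:
        return 0
    loci = 0
    self_found = False
    others: dict[str, list[list[int]]] = {}
    for _, row in hits.iterrows():
        s, e = sorted((int(row["sstart"]), int(row["send"])))
        s -= 1  # to 0-based half-open
        if (row["sseqid"] == gene.seq_region
                and s < gene.end and e > gene.start):
            self_found = True
            continue
        others.setdefault(row["sseqid"], []).append([s, e])
    if self_found:
        loci += 1
    for subject, intervals in others.items():
        intervals.sort()
        prev_end = None
        for s, e in intervals:
            if prev_end is None or s > prev_end + cluster_radius:
                loci += 1
            prev_end = e if prev_end is None else max(prev_end, e)
    return loci


@dataclass
class FilterReport:
    passed: list[GeneModel]
    rejections: pd.DataFrame  # gene_id -> semicolon-joined reasons


def filter_genes(genes: Sequence[GeneModel], criteria: SelectionCriteria,
                 copy_numbers: dict[str, int]) -> FilterReport:
    """Apply the length / intron / copy-number criteria; every violated
    criterion is recorded per rejected gene."""
    passed, rows = [], []
    for g in sorted(genes, key=lambda g: (g.seq_region, g.start, g.gene_id)):
        if g.gene_id not in copy_numbers:
            raise KeyError(f"no copy-number evidence for {g.gene_id}")
        reasons = []
        if g.length < criteria.min_gene_length:
            reasons.append(f"length {g.length} < {criteria.min_gene_length}")
        if g.max_intron_length > criteria.max_intron_length:
            reasons.append(f"intron {g.max_intron_length} > "
                           f"{criteria.max_intron_length}")
        if copy_numbers[g.gene_id] > criteria.max_copies:
            reasons.append(f"copies {copy_numbers[g.gene_id]} > "
                           f"{criteria.max_copies}")
        if reasons:
            rows.append({"gene_id": g.gene_id, "reasons": "; ".join(reasons)})
        else:
            passed.append(g)
    return FilterReport(passed=passed,
                        rejections=pd.DataFrame(rows, columns=["gene_id", "reasons"]))


def build_linked_groups(genes: Sequence[GeneModel],
                        criteria: SelectionCriteria
                        ) -> tuple[list[LinkedGroup], list[list[str]]]:
    """Chain genes into linked groups.

    Per region, genes sorted by start form maximal runs where each
    consecutive gap (next.start - prev.end) is strictly below the linkage
    distance.  Runs longer than the maximum group size are split greedily
    left-to-right into groups of four, then three; runs below the minimum
    size are discarded and returned for reporting.
    """
    lo, hi = criteria.group_size
    groups: list[LinkedGroup] = []
    discarded: list[list[str]] = []
    counter = 0
    by_region: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_region.setdefault(g.seq_region, []).append(g)

    def emit(run: list[GeneModel]) -> None:
        nonlocal counter
        i = 0
        while len(run) - i >= lo:
            take = min(hi, len(run) - i)
            if take > 4:
                take = 4
            counter += 1
            chunk = run[i:i + take]
            groups.append(LinkedGroup(
                group_id=f"group{counter}",
                seq_region=chunk[0].seq_region,
                gene_ids=[g.gene_id for g in chunk],
                span=chunk[-1].end - chunk[0].start))
            i += take
        if len(run) - i > 0:
            discarded.append([g.gene_id for g in run[i:]])

    for region in sorted(by_region):
        ordered = sorted(by_region[region], key=lambda g: g.start)
        run = [ordered[0]]
        for g in ordered[1:]:
            if g.start - run[-1].end < criteria.max_linked_distance:
                run.append(g)
            else:
                emit(run)
                run = [g]
        emit(run)
    return groups, discarded


def select_markers(gff3_path, fasta_path, hit_table,
                   criteria: Optional[SelectionCriteria] = None):
    """End-to-end selection: parse, assess copies, filter, group.

    Returns (groups, filter_report, genes).
    """
    crit = criteria or SelectionCriteria()
    genes = parse_annotation(gff3_path, fasta_path)
    hits = read_hit_table(hit_table)
    copies = {g.gene_id: assess_copy_number(g, hits,
                                            crit.copy_evalue_threshold)
              for g in genes}
    report = filter_genes(genes, crit, copies)
    groups, discarded = build_linked_groups(report.passed, crit)
    return groups, report, genes
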