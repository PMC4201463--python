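"""On-target contig binning and IUPAC consensus merging.

Assembled contigs are assigned to target loci by similarity evidence at a
strict threshold (E <= 1E-100), oriented onto the locus by their best hit,
and each individual's contigs are merged into a single consensus: where
overlapping contigs disagree, the minimal IUPAC code containing the union
of the observed base sets is emitted (both alleles retained, no voting);
stretches between non-overlapping contigs are N-filled for the
reference-implied length so one record per individual per locus results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .iupac import code_for, expand, reverse_complement

DEFAULT_EVALUE_THRESHOLD = 1e-100


@dataclass(frozen=True)
class HitRecord:
    """One similarity hit of a contig against a target locus.

    Intervals are 0-based half-open on the respective sequences; a minus
    strand match means the contig aligns to the reverse complement of the
    locus."""

    contig_id: str
    locus_id: str
    evalue: float
    qstart: int
    qend: int
    sstart: int
    send: int
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if self.qend <= self.qstart:
            raise ValueError("empty contig interval")

    @property
    def minus_strand(self) -> bool:
        return self.send < self.sstart

    @property
    def locus_interval(self) -> tuple[int, int]:
        s, e = self.sstart, self.send
        return (s, e) if s <= e else (e, s)


def hits_from_table(df: pd.DataFrame) -> list[HitRecord]:
    """Convert a 12-column tabular hit table (1-based inclusive BLAST
    coordinates) into HitRecords."""
    records = []
    for i, row in df.iterrows():
        try:
            ss, se = int(row["sstart"]), int(row["send"])
            if ss <= se:
                sstart, send = ss - 1, se
            else:  # minus strand: store reversed to preserve orientation flag
                sstart, send = ss, se - 1
            records.append(HitRecord(
                contig_id=str(row["qseqid"]), locus_id=str(row["sseqid"]),
                evalue=float(row["evalue"]),
                qstart=int(row["qstart"]) - 1, qend=int(row["qend"]),
                sstart=sstart, send=send,
                bitscore=float(row["bitscore"])))
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"malformed hit row {i + 1}: {exc}") from exc
    return records


@dataclass
class BinResult:
    bins: dict[str, list[str]]            # locus_id -> contig ids
    paralog_flags: list[str]              # contigs hitting multiple loci
    off_target: list[str]                 # contigs with no qualifying hit


def bin_contigs(contig_ids: Iterable[str], hits: Sequence[HitRecord],
                evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD) -> BinResult:
    """Assign each contig to every locus it hits at E <= threshold.

    Contigs qualifying for multiple loci are flagged as potentially
    paralogous (they stay in all their bins — removal is a curation
    decision, not an automatic one); contigs with no qualifying hit are
    reported off-target.
    """
    contig_ids = list(contig_ids)
    bins: dict[str, list[str]] = {}
    hit_loci: dict[str, set[str]] = {c: set() for c in contig_ids}
    for h in hits:
        if h.contig_id not in hit_loci:
            raise KeyError(f"hit references unknown contig {h.contig_id!r}")
        if h.evalue <= evalue_threshold:
            if h.contig_id not in hit_loci or h.locus_id not in hit_loci[h.contig_id]:
                bins.setdefault(h.locus_id, []).append(h.contig_id)
                hit_loci[h.contig_id].add(h.locus_id)
    paralogs = sorted(c for c, ls in hit_loci.items() if len(ls) > 1)
    off = sorted(c for c, ls in hit_loci.items() if not ls)
    return BinResult(bins=bins, paralog_flags=paralogs, off_target=off)


@dataclass
class OrientedContig:
    contig_id: str
    locus_id: str
    start: int      # placement on the locus, 0-based half-open
    end: int
    sequence: str   # reference orientation


def orient_contigs(locus_id: str, contig_seqs: Mapping[str, str],
                   hits: Sequence[HitRecord]) -> list[OrientedContig]:
    """Place each binned contig on its locus using its best hit (lowest
    E-value, ties by highest bitscore then contig id); minus-strand matches
    are reverse-complemented so all contigs share reference orientation."""
    by_contig: dict[str, list[HitRecord]] = {}
    for h in hits:
        if h.locus_id == locus_id and h.contig_id in contig_seqs:
            by_contig.setdefault(h.contig_id, []).append(h)
    oriented = []
    for cid in sorted(by_contig):
        best = min(by_contig[cid],
                   key=lambda h: (h.evalue, -h.bitscore, h.contig_id))
        seq = contig_seqs[cid]
        lo, hi = best.locus_interval
        if best.minus_strand:
            seq = reverse_complement(seq)
            qstart = len(seq) - best.qend
        else:
            qstart = best.qstart
        start = lo - qstart  # extend the aligned block to the full contig
        oriented.append(OrientedContig(contig_id=cid, locus_id=locus_id,
                                       start=start, end=start + len(seq),
                                       sequence=seq))
    return oriented


@dataclass
class ConsensusSequence:
    individual_id: str
    locus_id: str
    start: int               # consensus span on the locus
    end: int
    sequence: str            # IUPAC alphabet; N fills uncovered gaps
    source_contigs: list[tuple[str, int, int]]
    flags: list[str] = field(default_factory=list)


def merge_contigs(oriented: Sequence[OrientedContig],
                  individual_id: str = "", locus_id: str = "",
                  low_identity_threshold: float = 0.70,
                  low_identity_min_overlap: int = 100) -> ConsensusSequence:
    """Merge one individual's oriented contigs into an IUPAC consensus.

    Per position: a single covering contig contributes its base; multiple
    covering contigs contribute the union of their base sets, coded by the
    minimal IUPAC symbol (so the merge is commutative, associative and
    idempotent, and adding a contig can only widen a position's base set).
    Uncovered positions inside the span become N.  Contig pairs whose
    overlap identity is under ``low_identity_threshold`` across at least
    ``low_identity_min_overlap`` bp are flagged (possible misassembly or
    paralogy) but still merged — removal is left to curation.
    """
    if not oriented:
        raise ValueError("no contigs to merge")
    locus_id = locus_id or oriented[0].locus_id
    start = min(c.start for c in oriented)
    end = max(c.end for c in oriented)
    sets: list[Optional[frozenset]] = [None] * (end - start)
    for c in oriented:
        for i, ch in enumerate(c.sequence):
            pos = c.start - start + i
            s = expand(ch)
            sets[pos] = s if sets[pos] is None else (sets[pos] | s)
    seq = "".join("N" if s is None else code_for(s) for s in sets)

    flags = []
    for i, a in enumerate(oriented):
        for b in oriented[i + 1:]:
            lo = max(a.start, b.start)
            hi = min(a.end, b.end)
            if hi - lo < low_identity_min_overlap:
                continue
            same = sum(
                1 for p in range(lo, hi)
                if expand(a.sequence[p - a.start]) & expand(b.sequence[p - b.start]))
            if same / (hi - lo) < low_identity_threshold:
                flags.append(f"low-identity overlap {a.contig_id}/{b.contig_id} "
                             f"({same / (hi - lo):.2f} over {hi - lo} bp)")
    return ConsensusSequence(
        individual_id=individual_id, locus_id=locus_id, start=start, end=end,
        sequence=seq,
        source_contigs=[(c.contig_id, c.start, c.end) for c in oriented],
        flags=flags)
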