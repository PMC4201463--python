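"""Tiled capture-probe design.

Baits are 90-mers stepped every 30 bp (3x tiling density) across the whole
gene sequence — introns included, because small introns are captured by
fragments hybridizing to adjacent exonic probes and intronic variation is
what makes the markers informative at shallow depths.  When the last full
step would leave a 3' remainder uncovered, one extra probe is anchored at
the sequence end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .iupac import UNAMBIGUOUS


@dataclass(frozen=True)
class ProbeDesignParams:
    probe_length: int = 90
    step: int = 30
    max_ambiguous: int = 0  # probes with more non-ACGT characters are dropped

    def __post_init__(self) -> None:
        if self.probe_length <= 0 or self.step <= 0:
            raise ValueError("probe length and step must be positive")
        if self.step > self.probe_length:
            raise ValueError("step must not exceed probe length")


@dataclass(frozen=True)
class Probe:
    probe_id: str
    locus_id: str
    offset: int       # 0-based start on the locus sequence
    sequence: str


@dataclass
class ProbeSet:
    probes: list[Probe]
    dropped: list[Probe]          # ambiguous probes excluded from the set
    coverage: pd.DataFrame        # per-locus, per-base probe depth

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for p in self.probes:
                fh.write(f">{p.probe_id}\n{p.sequence}\n")


def tile_offsets(length: int, params: ProbeDesignParams) -> list[int]:
    """Probe start offsets: 0, step, 2*step, ... plus a tail-anchored probe
    at length - probe_length when the last step does not land there."""
    if length < params.probe_length:
        raise ValueError("sequence shorter than probe length")
    last = length - params.probe_length
    offsets = list(range(0, last + 1, params.step))
    if offsets[-1] != last:
        offsets.append(last)
    return offsets


def tile_probes(sequence: str, params: ProbeDesignParams | None = None,
                locus_id: str = "locus") -> tuple[list[Probe], list[Probe]]:
    """Tile one sequence; returns (kept probes, dropped ambiguous probes)."""
    params = params or ProbeDesignParams()
    sequence = sequence.upper()
    kept, dropped = [], []
    width = len(str(len(sequence)))
    for off in tile_offsets(len(sequence), params):
        sub = sequence[off: off + params.probe_length]
        probe = Probe(probe_id=f"{locus_id}_{off:0{width}d}",
                      locus_id=locus_id, offset=off, sequence=sub)
        n_amb = sum(1 for c in sub if c not in UNAMBIGUOUS)
        (kept if n_amb <= params.max_ambiguous else dropped).append(probe)
    return kept, dropped


def design_probe_set(targets: dict[str, str],
                     params: ProbeDesignParams | None = None) -> ProbeSet:
    """Tile every target sequence and report per-base probe coverage.

    Coverage depth at interior bases equals probe_length / step (3 with the
    defaults); every non-ambiguous base is covered at least once.
    """
    params = params or ProbeDesignParams()
    probes: list[Probe] = []
    dropped: list[Probe] = []
    rows = []
    for locus_id, seq in targets.items():
        kept, drop = tile_probes(seq, params, locus_id=locus_id)
        probes.extend(kept)
        dropped.extend(drop)
        depth = np.zeros(len(seq), dtype=int)
        for p in kept:
            depth[p.offset: p.offset + params.probe_length] += 1
        rows.append(pd.DataFrame({"locus_id": locus_id,
                                  "position": np.arange(len(seq)),
                                  "depth": depth}))
    coverage = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["locus_id", "position", "depth"])
    return ProbeSet(probes=probes, dropped=dropped, coverage=coverage)
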