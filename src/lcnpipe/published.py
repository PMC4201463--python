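"""The 50-locus Medicago/Melilotus reference marker panel.

A characterized panel of 50 low-copy nuclear loci (per-locus alignment
length, GC content, parsimony-informative sites, exon fraction, CI/RI and
calibrated substitution rate) ships with the package as the worked
reference dataset: its rate column is the sample from which the suggested
normal/gamma rate priors are derived, and its summary statistics anchor
the synthetic generator's defaults (locus length range, GC level, rate
distribution).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd


def load_locus_stats() -> pd.DataFrame:
    """Per-locus characterization table of the reference panel.

    Columns: locus, linkage_group, gene_id, portion_start, portion_end,
    alignment_length, rate_e9 (substitutions/site/year x 1e9), gc_percent,
    pi_sites, pi_percent, exon_percent, ci, ri.
    """
    with resources.files("lcnpipe.data").joinpath("locus_stats.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def reference_rates() -> np.ndarray:
    """The panel's 50 calibrated substitution rates in subs/site/year."""
    return load_locus_stats()["rate_e9"].to_numpy() * 1e-9
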