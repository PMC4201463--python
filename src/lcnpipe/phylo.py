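"""Per-locus alignment statistics and maximum-likelihood gene-tree
inference for small taxon sets.

This module re-implements, in reduced form, the classic per-locus toolbox
used when characterizing phylogenetic markers: parsimony-informative site
counts, GC content, model selection by AIC over a nested candidate set,
exhaustive ML topology search with per-topology branch-length optimization,
nonparametric bootstrap supports, and the Fitch parsimony indices CI and RI.
Exhaustive search is feasible because marker panels are assessed on few
representative individuals (six here), where all 105 unrooted topologies
can be scored exactly.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from itertools import product as _iterproduct
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from scipy.optimize import minimize, minimize_scalar

from . import mlcore
from .iupac import CODE_TO_SET, UNAMBIGUOUS
from .mlcore import (MIN_BRANCH, PatternData, TreeLikelihood, canonical_key,
                     canonical_newick, compress_patterns, edge_bipartitions,
                     enumerate_topologies, jc_distance_matrix, n_topologies,
                     neighbor_joining, resample_patterns, rooted_structure)
from .models import (SubstitutionModel, empirical_frequencies)

_GAPS = {"-", "?", "."}


# ---------------------------------------------------------------------------
# alignment container

@dataclass
class Alignment:
    """A multiple sequence alignment over the IUPAC alphabet plus gaps."""

    taxa: list[str]
    seqs: list[str]
    locus_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.seqs):
            raise ValueError("taxa and seqs must have equal length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        if self.seqs and len({len(s) for s in self.seqs}) != 1:
            raise ValueError("aligned sequences must have equal length")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def __len__(self) -> int:
        return len(self.taxa)

    def column(self, i: int) -> list[str]:
        return [s[i] for s in self.seqs]

    def sequence(self, taxon: str) -> str:
        return self.seqs[self.taxa.index(taxon)]

    @classmethod
    def from_fasta(cls, path, locus_id: Optional[str] = None) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records],
                   locus_id=locus_id)

    @classmethod
    def from_phylip(cls, path, locus_id: Optional[str] = None) -> "Alignment":
        aln = AlignIO.read(str(path), "phylip-relaxed")
        return cls([r.id for r in aln], [str(r.seq) for r in aln],
                   locus_id=locus_id)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, s in zip(self.taxa, self.seqs):
                fh.write(f">{t}\n{s}\n")


@dataclass
class LocusStats:
    """Per-locus summary mirroring a marker characterization table."""

    locus_id: Optional[str]
    alignment_length: int
    gc_percent: float
    pi_sites: int
    pi_percent: float
    ci: float
    ri: float
    exon_percent: Optional[float] = None


# ---------------------------------------------------------------------------
# simple column statistics

def count_pi_sites(alignment: Alignment) -> int:
    """Parsimony-informative sites: columns where at least two distinct
    unambiguous bases each occur in at least two sequences.  Gaps and
    ambiguity codes never contribute to a state's count."""
    if alignment.length == 0:
        raise ValueError("empty alignment")
    count = 0
    for i in range(alignment.length):
        tally: dict[str, int] = {}
        for c in alignment.column(i):
            if c in UNAMBIGUOUS:
                tally[c] = tally.get(c, 0) + 1
        if sum(1 for v in tally.values() if v >= 2) >= 2:
            count += 1
    return count


def gc_content(alignment: Alignment) -> float:
    """GC percentage over unambiguously AT/GC-classifiable characters:
    G, C and S count as GC; A, T and W as AT; everything else (gaps, N,
    other ambiguities) is excluded from both numerator and denominator."""
    gc = at = 0
    for s in alignment.seqs:
        for c in s:
            if c in "GCS":
                gc += 1
            elif c in "ATW":
                at += 1
    if gc + at == 0:
        raise ValueError("no countable characters in alignment")
    return 100.0 * gc / (gc + at)


# ---------------------------------------------------------------------------
# dendropy bridging

def tree_to_edges(tree: dendropy.Tree, taxa: Sequence[str]):
    """Convert a dendropy tree to the engine's (edges, branch length) form,
    treating the tree as unrooted (a bifurcating seed node is collapsed and
    its two branch lengths summed)."""
    taxa = list(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    t = tree.clone(depth=1)
    if n == 2:
        leaves = list(t.leaf_node_iter())
        if len(leaves) != 2:
            raise ValueError("tree does not match the two-taxon alignment")
        total = sum(float(l.edge.length or 0.0) for l in leaves)
        a, b = sorted(index[l.taxon.label] for l in leaves)
        return ((b, a),), {a: total}
    seed = t.seed_node
    if len(seed.child_nodes()) == 2:
        # unrooted convention: merge the basal bifurcation into one edge
        a, b = seed.child_nodes()
        keep, drop = (a, b) if a.is_internal() else (b, a)
        length = (a.edge.length or 0.0) + (b.edge.length or 0.0)
        seed.remove_child(drop)
        keep.add_child(drop)
        drop.edge.length = length
        keep.edge.length = None
        keep.parent_node = None
        t.seed_node = keep
    ids: dict[dendropy.Node, int] = {}
    next_internal = n
    edges = []
    lengths = {}

    def node_id(nd):
        nonlocal next_internal
        if nd in ids:
            return ids[nd]
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon else nd.label
            if label not in index:
                raise ValueError(f"tree taxon {label!r} not in taxon list")
            ids[nd] = index[label]
        else:
            ids[nd] = next_internal
            next_internal += 1
        return ids[nd]

    for nd in t.preorder_node_iter():
        if nd.parent_node is None:
            node_id(nd)
            continue
        v, u = node_id(nd), node_id(nd.parent_node)
        edges.append((u, v))
        if nd.edge.length is None:
            raise ValueError("tree has a missing branch length")
        lengths[v] = float(nd.edge.length)
    return tuple(edges), lengths


def edges_to_tree(edges, branch_lengths, taxa: Sequence[str],
                  support: Optional[dict[frozenset, float]] = None) -> dendropy.Tree:
    """Build a dendropy tree (basal trifurcation, i.e. unrooted) from the
    engine representation; optional per-bipartition supports become internal
    node labels."""
    taxa = list(taxa)
    n = len(taxa)
    root, parent, children, _ = rooted_structure(edges, n)
    bip = edge_bipartitions(edges, taxa) if support is not None else {}

    def render(v: int) -> str:
        if v < n and not children[v]:
            s = taxa[v]
        else:
            s = "(" + ",".join(render(c) for c in children[v]) + ")"
            if support is not None and parent[v] != -1:
                key = bip.get((parent[v], v)) or bip.get((v, parent[v]))
                if key is not None and key in support:
                    s += f"{support[key]:g}"
        if parent[v] != -1:
            s += f":{branch_lengths[v]:.10g}"
        return s

    newick = render(root) + ";"
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


# ---------------------------------------------------------------------------
# likelihood API

def log_likelihood(tree: dendropy.Tree, model: SubstitutionModel,
                   alignment: Alignment) -> float:
    """Felsenstein pruning log-likelihood of an alignment on a fixed tree.

    Ambiguity codes are treated as partial observations (likelihood mass
    spread over the code's base set) and gaps as fully missing.  Site
    patterns are compressed with multiplicities; discrete-gamma rate
    heterogeneity follows the model specification.
    """
    if alignment.length == 0:
        raise ValueError("empty alignment")
    data = compress_patterns(alignment.taxa, alignment.seqs)
    edges, lengths = tree_to_edges(tree, alignment.taxa)
    tl = TreeLikelihood(edges, data, model, branch_lengths=lengths)
    return tl.log_likelihood()


@dataclass
class MLSearchResult:
    tree: dendropy.Tree
    log_likelihood: float
    n_topologies: int
    edges: tuple = field(repr=False, default=())
    branch_lengths: dict = field(repr=False, default_factory=dict)


def exhaustive_ml_search(alignment: Alignment, model: SubstitutionModel,
                         *, tol: float = 1e-6, coarse_keep: int = 8,
                         data: Optional[PatternData] = None) -> MLSearchResult:
    """Score every unrooted topology (3..8 taxa) and return the ML tree.

    A coarse pass (two optimization sweeps per topology) ranks all
    (2n-5)!! topologies; the ``coarse_keep`` best are then refined to the
    requested tolerance.  Ties within 1e-6 log-likelihood are broken by the
    lexicographically smallest canonical Newick string.
    """
    n = len(alignment)
    if not 3 <= n <= 8:
        raise ValueError("exhaustive search supports 3 to 8 taxa")
    if data is None:
        data = compress_patterns(alignment.taxa, alignment.seqs)
    topologies = enumerate_topologies(n)
    coarse = []
    for edges in topologies:
        tl = TreeLikelihood(edges, data, model)
        lnl = tl.optimize_branches(tol=1e-2, max_sweeps=2, xtol=3e-2)
        coarse.append((lnl, edges, tl))
    coarse.sort(key=lambda x: -x[0])
    refined = []
    for lnl, edges, tl in coarse[: max(1, coarse_keep)]:
        lnl = tl.optimize_branches(tol=tol, max_sweeps=50, xtol=1e-7)
        refined.append((lnl, edges, tl))
    best_lnl = max(r[0] for r in refined)
    contenders = [r for r in refined if best_lnl - r[0] <= 1e-6]
    contenders.sort(key=lambda r: canonical_newick(r[1], alignment.taxa))
    lnl, edges, tl = contenders[0]
    tree = edges_to_tree(edges, tl.bl, alignment.taxa)
    return MLSearchResult(tree=tree, log_likelihood=lnl,
                          n_topologies=len(topologies), edges=edges,
                          branch_lengths=dict(tl.bl))


def ml_branch_lengths(edges, data: PatternData, model: SubstitutionModel,
                      tol: float = 1e-6) -> tuple[float, dict[int, float]]:
    """Optimize branch lengths on a fixed topology; returns (lnL, lengths)."""
    tl = TreeLikelihood(edges, data, model)
    lnl = tl.optimize_branches(tol=tol)
    return lnl, dict(tl.bl)


# ---------------------------------------------------------------------------
# model selection

_CANDIDATE_FAMILIES = ("JC69", "K80", "F81", "HKY85", "GTR")


@dataclass
class ModelSelectionResult:
    best: SubstitutionModel
    table: pd.DataFrame
    criterion: str


def _fit_model_params(data: PatternData, edges, model: SubstitutionModel,
                      init_lengths=None) -> tuple[float, SubstitutionModel, dict]:
    """Alternate branch-length and model-parameter optimization on a fixed
    topology.  Parameters are introduced at their nested-model values, so a
    richer model never scores below the model it contains."""

    def branch_opt(m, lengths):
        tl = TreeLikelihood(edges, data, m, branch_lengths=lengths)
        lnl = tl.optimize_branches(tol=1e-4, max_sweeps=20, xtol=1e-6)
        return lnl, dict(tl.bl)

    lengths = init_lengths
    lnl, lengths = branch_opt(model, lengths)

    for _ in range(2):
        if model.family in ("K80", "HKY85"):
            def f(logk):
                m = model.with_(kappa=math.exp(logk))
                tl = TreeLikelihood(edges, data, m, branch_lengths=lengths)
                return -tl.log_likelihood()
            res = minimize_scalar(f, bounds=(math.log(0.05), math.log(100.0)),
                                  method="bounded", options={"xatol": 1e-4})
            if -res.fun > lnl:
                model = model.with_(kappa=math.exp(res.x))
        elif model.family == "GTR":
            x0 = np.log(np.asarray(model.exchangeabilities[:5]))

            def g(x):
                ex = tuple(np.exp(x)) + (1.0,)
                m = model.with_(exchangeabilities=ex)
                tl = TreeLikelihood(edges, data, m, branch_lengths=lengths)
                return -tl.log_likelihood()
            res = minimize(g, x0, method="Nelder-Mead",
                           options={"maxiter": 200, "fatol": 1e-4})
            if -res.fun > lnl:
                model = model.with_(
                    exchangeabilities=tuple(np.exp(res.x)) + (1.0,))
        if model.gamma_categories:
            grid = [0.1, 0.25, 0.5, 1.0, 2.0, 5.0, 20.0, 100.0, 1e4]
            best_a = max(grid, key=lambda a: TreeLikelihood(
                edges, data, model.with_(alpha=a),
                branch_lengths=lengths).log_likelihood())

            def h(loga):
                m = model.with_(alpha=math.exp(loga))
                tl = TreeLikelihood(edges, data, m, branch_lengths=lengths)
                return -tl.log_likelihood()
            res = minimize_scalar(
                h, bounds=(math.log(best_a / 4.0), math.log(min(best_a * 4.0, 1e5))),
                method="bounded", options={"xatol": 1e-3})
            model = model.with_(alpha=math.exp(res.x))
        new_lnl, lengths = branch_opt(model, lengths)
        if new_lnl - lnl < 1e-3:
            lnl = max(new_lnl, lnl)
            break
        lnl = new_lnl
    return lnl, model, lengths


def select_model(alignment: Alignment, criterion: str = "AIC",
                 gamma: bool = True) -> ModelSelectionResult:
    """Choose a substitution model by information criterion on a fixed
    neighbor-joining starting topology.

    Candidates are {JC69, K80, F81, HKY85, GTR} optionally crossed with
    +G4 (discrete gamma, four categories).  Each candidate's likelihood is
    maximized (branch lengths plus model parameters); AIC = 2k - 2 lnL with
    k counting free model parameters and branch lengths.  AICc and BIC are
    available via ``criterion``.
    """
    if criterion not in ("AIC", "AICc", "BIC"):
        raise ValueError("criterion must be AIC, AICc or BIC")
    data = compress_patterns(alignment.taxa, alignment.seqs)
    edges = neighbor_joining(jc_distance_matrix(data))
    emp = empirical_frequencies(alignment.seqs)
    n_branches = 2 * len(alignment) - 3
    n_sites = alignment.length

    gammas = (0, 4) if gamma else (0,)
    rows = []
    best = None
    cache: dict[tuple, tuple] = {}
    for family, ncat in _iterproduct(_CANDIDATE_FAMILIES, gammas):
        freqs = (0.25,) * 4 if family in ("JC69", "K80") else emp
        model = SubstitutionModel(
            family=family, freqs=freqs, gamma_categories=ncat,
            alpha=1.0 if ncat else None,
            exchangeabilities=(1.0,) * 6 if family == "GTR" else None)
        # nested warm starts: reuse simpler-family parameters
        parent = cache.get(("K80" if family == "HKY85" else None, ncat))
        if family == "HKY85" and parent:
            model = model.with_(kappa=parent[1].kappa)
        if family == "GTR":
            hk = cache.get(("HKY85", ncat))
            if hk:
                k = hk[1].kappa
                model = model.with_(exchangeabilities=(1.0, k, 1.0, 1.0, k, 1.0))
        init = None
        plain = cache.get((family, 0))
        if ncat and plain:
            init = plain[2]
        lnl, fitted, lengths = _fit_model_params(data, edges, model, init)
        cache[(family, ncat)] = (lnl, fitted, lengths)
        k = fitted.n_free_parameters + n_branches
        aic = 2 * k - 2 * lnl
        aicc = aic + (2 * k * (k + 1)) / max(n_sites - k - 1, 1)
        bic = k * math.log(n_sites) - 2 * lnl
        score = {"AIC": aic, "AICc": aicc, "BIC": bic}[criterion]
        name = family + ("+G4" if ncat else "")
        rows.append({"model": name, "lnL": lnl, "k": k, "AIC": aic,
                     "AICc": aicc, "BIC": bic})
        if best is None or score < best[0]:
            best = (score, fitted)
    table = pd.DataFrame(rows).sort_values(criterion).reset_index(drop=True)
    return ModelSelectionResult(best=best[1], table=table, criterion=criterion)


# ---------------------------------------------------------------------------
# bootstrap

@dataclass
class BootstrapResult:
    tree: dendropy.Tree
    supports: dict[frozenset, float]
    replicates: int


def bootstrap_support(alignment: Alignment, model: SubstitutionModel,
                      replicates: int = 500, seed: int = 0,
                      *, coarse_keep: int = 3) -> BootstrapResult:
    """Nonparametric bootstrap supports for the ML tree.

    Columns are resampled with replacement per replicate (replicate r uses
    seed + r) and the full exhaustive search is repeated; support for each
    bipartition of the best tree is the percentage of replicate ML trees
    containing it.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    data = compress_patterns(alignment.taxa, alignment.seqs)
    best = exhaustive_ml_search(alignment, model, data=data)
    focal = set(edge_bipartitions(best.edges, alignment.taxa).values())
    counts = {b: 0 for b in focal}
    for r in range(replicates):
        rng = np.random.default_rng(seed + r)
        rep = resample_patterns(data, rng)
        res = exhaustive_ml_search(alignment, model, data=rep,
                                   coarse_keep=coarse_keep, tol=1e-4)
        rep_bips = set(edge_bipartitions(res.edges, alignment.taxa).values())
        for b in focal & rep_bips:
            counts[b] += 1
    supports = {b: 100.0 * c / replicates for b, c in counts.items()}
    tree = edges_to_tree(best.edges, best.branch_lengths, alignment.taxa,
                         support=supports)
    return BootstrapResult(tree=tree, supports=supports, replicates=replicates)


# ---------------------------------------------------------------------------
# parsimony

def _site_state_sets(alignment: Alignment, i: int) -> list[Optional[frozenset]]:
    """Per-taxon state sets for one column: unambiguous base -> singleton,
    ambiguity code -> its base set, gap/N -> None (missing)."""
    out = []
    for c in alignment.column(i):
        if c in _GAPS or c == "N":
            out.append(None)
        else:
            s = CODE_TO_SET.get(c)
            if s is None:
                raise ValueError(f"bad alignment character {c!r}")
            out.append(s if s != frozenset("ACGT") else None)
    return out


def _fitch_site(children: dict, postorder: list, root: int,
                n: int, states: list) -> int:
    """Fitch count for one site on a rooted version of the tree; missing
    tips carry the full state set and add no steps."""
    full = frozenset("ACGT")
    sets: dict[int, frozenset] = {}
    steps = 0
    for v in postorder + [root]:
        if v < n and not children[v]:
            sets[v] = states[v] if states[v] is not None else full
            continue
        acc = states[v] if (v < n and states[v] is not None) else None
        for c in children[v]:
            s = sets[c]
            if acc is None:
                acc = s
            else:
                inter = acc & s
                if inter:
                    acc = inter
                else:
                    acc = acc | s
                    steps += 1
        sets[v] = acc
    return steps


def fitch_steps(tree: dendropy.Tree | tuple, alignment: Alignment) -> int:
    """Total Fitch parsimony length of the alignment on the tree."""
    edges = tree if isinstance(tree, tuple) else tree_to_edges(tree, alignment.taxa)[0]
    n = len(alignment)
    root, _, children, postorder = rooted_structure(edges, n)
    total = 0
    for i in range(alignment.length):
        states = _site_state_sets(alignment, i)
        total += _fitch_site(children, postorder, root, n, states)
    return total


def ci_ri(tree: dendropy.Tree | tuple, alignment: Alignment) -> tuple[float, float]:
    """Consistency and retention indices of the alignment on the tree.

    Per varying site i: s_i = Fitch steps; m_i = (distinct observed
    unambiguous states - 1); g_i = maximum possible steps on any binary
    tree, i.e. the number of tips carrying a non-modal unambiguous state.
    CI = sum(m)/sum(s); RI = (sum(g)-sum(s)) / (sum(g)-sum(m)).  When no
    site can be homoplasious (sum g == sum m), RI is reported as 1 with a
    warning.
    """
    edges = tree if isinstance(tree, tuple) else tree_to_edges(tree, alignment.taxa)[0]
    n = len(alignment)
    root, _, children, postorder = rooted_structure(edges, n)
    S = M = G = 0
    for i in range(alignment.length):
        states = _site_state_sets(alignment, i)
        counts: dict[str, int] = {}
        for s in states:
            if s is not None and len(s) == 1:
                (b,) = s
                counts[b] = counts.get(b, 0) + 1
        if len(counts) < 2:
            continue
        m = len(counts) - 1
        g = sum(counts.values()) - max(counts.values())
        s_steps = _fitch_site(children, postorder, root, n, states)
        S += s_steps
        M += m
        G += g
    if S == 0:
        return 1.0, 1.0
    ci = M / S
    if G == M:
        warnings.warn("no potentially homoplasious site; RI undefined, "
                      "reporting 1", stacklevel=2)
        ri = 1.0
    else:
        ri = (G - S) / (G - M)
    return ci, ri


# ---------------------------------------------------------------------------
# convenience

def locus_stats(alignment: Alignment, tree: dendropy.Tree | tuple,
                exon_percent: Optional[float] = None) -> LocusStats:
    """Assemble the per-locus characterization row."""
    pi = count_pi_sites(alignment)
    ci, ri = ci_ri(tree, alignment)
    return LocusStats(
        locus_id=alignment.locus_id,
        alignment_length=alignment.length,
        gc_percent=gc_content(alignment),
        pi_sites=pi,
        pi_percent=100.0 * pi / alignment.length,
        ci=ci,
        ri=ri,
        exon_percent=exon_percent,
    )
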