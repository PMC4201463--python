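"""Likelihood engine for small unrooted trees.

Felsenstein pruning over compressed site patterns, with inside/outside
partial vectors so that each branch length can be optimized as a cheap
one-dimensional problem while the rest of the tree is held fixed.  Designed
for exhaustive topology search on <= 8 taxa, where all (2n-5)!! unrooted
binary topologies are enumerated by stepwise tip insertion.

Node convention: tips are 0..n-1 (in the order of the taxon list), internal
nodes are n..2n-3; an unrooted binary tree has 2n-3 edges.  The likelihood
is evaluated by rooting at an arbitrary internal node (a valid operation for
reversible models, which makes the likelihood root-invariant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .iupac import CODE_TO_SET
from .models import BASES, ModelMatrices, SubstitutionModel

MIN_BRANCH = 1e-9
MAX_BRANCH = 10.0

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_max(f, lo: float, hi: float, xtol: float) -> float:
    """Golden-section maximization of a unimodal scalar function."""
    a, b = lo, hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    while b - a > xtol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    return (a + b) / 2.0

_GAP_CHARS = {"-", "?", ".", "N"}


# ---------------------------------------------------------------------------
# site patterns

@dataclass
class PatternData:
    """Compressed alignment: per-tip partial likelihood columns.

    ``partials`` has shape (ntaxa, 4, npatterns); an unambiguous base is a
    one-hot column, an ambiguity code puts 1 on every base of its set, and a
    gap (or N) is all-ones, i.e. fully missing.
    """

    taxa: list[str]
    partials: np.ndarray
    weights: np.ndarray

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return int(self.weights.sum())


def _char_partial(c: str) -> np.ndarray:
    c = c.upper()
    if c in _GAP_CHARS:
        return np.ones(4)
    bases = CODE_TO_SET.get(c)
    if bases is None:
        raise ValueError(f"unrecognized alignment character {c!r}")
    return np.array([1.0 if b in bases else 0.0 for b in BASES])


def compress_patterns(taxa: list[str], seqs: list[str]) -> PatternData:
    """Collapse identical alignment columns into weighted patterns."""
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must share one alignment length")
    mat = np.array([list(s.upper()) for s in seqs])
    cols, weights = np.unique(mat, axis=1, return_counts=True)
    lut = {}
    npat = cols.shape[1]
    partials = np.empty((len(taxa), 4, npat))
    for i in range(len(taxa)):
        for p in range(npat):
            c = cols[i, p]
            if c not in lut:
                lut[c] = _char_partial(c)
            partials[i, :, p] = lut[c]
    return PatternData(list(taxa), partials, weights.astype(float))


def resample_patterns(data: PatternData, rng: np.random.Generator) -> PatternData:
    """Bootstrap: resample alignment columns with replacement, expressed as
    new multinomial pattern weights (patterns drawn with probability
    proportional to their original weight)."""
    n = data.n_sites
    probs = data.weights / n
    new_w = rng.multinomial(n, probs).astype(float)
    keep = new_w > 0
    return PatternData(data.taxa, data.partials[:, :, keep], new_w[keep])


# ---------------------------------------------------------------------------
# topologies

def enumerate_topologies(n: int) -> list[tuple[tuple[int, int], ...]]:
    """All unrooted binary topologies on tips 0..n-1, as edge tuples.

    Built by stepwise insertion: tip k subdivides each existing edge with a
    new internal node n + (k - 2).  Yields (2n-5)!! topologies.
    """
    if n < 3:
        raise ValueError("need at least 3 taxa")
    base = [((0, n), (1, n), (2, n))]
    for k in range(3, n):
        new_node = n + (k - 2)
        nxt = []
        for edges in base:
            for idx, (a, b) in enumerate(edges):
                new_edges = list(edges)
                new_edges[idx : idx + 1] = [(a, new_node), (new_node, b), (k, new_node)]
                nxt.append(tuple(new_edges))
        base = nxt
    return base


def n_topologies(n: int) -> int:
    """(2n-5)!! — the number of unrooted binary topologies on n tips."""
    count = 1
    for m in range(3, 2 * n - 4, 2):
        count *= m
    return count


def _adjacency(edges, n_taxa: int):
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    return adj


def rooted_structure(edges, n_taxa: int, root: int | None = None):
    """Orient an unrooted edge list from an internal root node.

    Returns (root, parent, children, postorder) where parent[v] is v's
    parent (-1 for the root) and postorder lists non-root nodes children
    before parents.
    """
    adj = _adjacency(edges, n_taxa)
    if root is None:
        root = next(v for v in adj if v >= n_taxa) if len(adj) > 2 else max(adj)
    parent = {root: -1}
    children: dict[int, list[int]] = {v: [] for v in adj}
    order = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for w in adj[v]:
            if w not in parent:
                parent[w] = v
                children[v].append(w)
                stack.append(w)
    postorder = [v for v in reversed(order) if v != root]
    return root, parent, children, postorder


def edge_bipartitions(edges, taxa: list[str]) -> dict[tuple[int, int], frozenset[str]]:
    """Non-trivial bipartitions, one per internal edge, canonicalized as the
    taxon set on the side *not* containing taxa[0]."""
    n = len(taxa)
    adj = _adjacency(edges, n)
    out = {}
    for a, b in edges:
        if a < n or b < n:
            continue  # pendant edge -> trivial split
        # collect tips on b's side of edge (a, b)
        seen = {a, b}
        stack = [b]
        side = set()
        while stack:
            v = stack.pop()
            if v < n:
                side.add(taxa[v])
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        if taxa[0] in side:
            side = set(taxa) - side
        out[(a, b)] = frozenset(side)
    return out


def canonical_key(edges, taxa: list[str]) -> frozenset[frozenset[str]]:
    """Rotation/reordering-invariant topology key: the set of non-trivial
    bipartitions."""
    return frozenset(edge_bipartitions(edges, taxa).values())


def canonical_newick(edges, taxa: list[str], branch_lengths=None) -> str:
    """Deterministic Newick string: rooted at the internal node adjacent to
    the alphabetically first taxon, children ordered by their smallest
    descendant label."""
    n = len(taxa)
    first = min(range(n), key=lambda i: taxa[i])
    adj = _adjacency(edges, n)
    root = adj[first][0]
    _, parent, children, _ = rooted_structure(edges, n, root=root)

    def min_label(v: int) -> str:
        if v < n:
            return taxa[v]
        return min(min_label(c) for c in children[v])

    def render(v: int) -> str:
        if v < n:
            s = taxa[v]
        else:
            parts = sorted(children[v], key=min_label)
            s = "(" + ",".join(render(c) for c in parts) + ")"
        if branch_lengths is not None and parent[v] != -1:
            s += f":{branch_lengths[v]:.10g}"
        return s

    return render(root) + ";"


# ---------------------------------------------------------------------------
# likelihood

class TreeLikelihood:
    """Pruning likelihood and coordinate-wise branch-length optimization on
    one fixed topology."""

    def __init__(self, edges, data: PatternData, model: SubstitutionModel,
                 branch_lengths: dict[int, float] | None = None,
                 start_length: float = 0.05):
        self.edges = tuple(edges)
        self.data = data
        self.n = data.n_taxa
        self.mm = ModelMatrices(model)
        self.model = model
        (self.root, self.parent, self.children,
         self.postorder) = rooted_structure(edges, self.n)
        self.preorder = list(reversed(self.postorder))
        self.bl: dict[int, float] = {
            v: (branch_lengths[v] if branch_lengths else start_length)
            for v in self.postorder
        }
        self._cl: dict[int, np.ndarray] = {}
        self._msg: dict[int, np.ndarray] = {}
        self._out: dict[int, np.ndarray] = {}

    # -- passes -------------------------------------------------------------

    def _tip_partial(self, v: int) -> np.ndarray:
        return np.broadcast_to(
            self.data.partials[v],
            (self.mm.ncat, 4, self.data.partials.shape[2]),
        )

    def _inside(self) -> None:
        for v in self.postorder + [self.root]:
            if v < self.n and not self.children[v]:
                self._cl[v] = self._tip_partial(v)
                continue
            prod = self._tip_partial(v) if v < self.n else None
            for c in self.children[v]:
                P = self.mm.transition(self.bl[c])
                m = np.einsum("cij,cjp->cip", P, self._cl[c])
                self._msg[c] = m
                prod = m if prod is None else prod * m
            self._cl[v] = prod

    def _outside(self) -> None:
        pi = self.mm.pi[None, :, None]
        for v in self.preorder:
            u = self.parent[v]
            prod = None
            if u < self.n:  # root may be a tip on 2-taxon trees
                prod = self._tip_partial(u)
            for s in self.children[u]:
                if s != v:
                    prod = self._msg[s] if prod is None else prod * self._msg[s]
            if u == self.root:
                base = pi if prod is None else pi * prod
            else:
                Pu = self.mm.transition(self.bl[u])
                transported = np.einsum("cxy,cxp->cyp", Pu, self._out[u])
                base = transported if prod is None else transported * prod
            self._out[v] = base

    def log_likelihood(self) -> float:
        self._inside()
        site = np.einsum("x,cxp->cp", self.mm.pi, self._cl[self.root]).mean(axis=0)
        return float(np.sum(self.data.weights * np.log(site)))

    # -- branch optimization ------------------------------------------------

    def _branch_coefficients(self, v: int) -> np.ndarray:
        """Spectral coefficients for branch v: with P(t) expanded in the
        model's eigenbasis, the per-pattern site likelihood becomes
        sum_j exp(lambda_j r_c t) coef[c, j, p], so trial branch lengths
        cost one small matrix product each."""
        u = np.einsum("xj,cxp->cjp", self.mm._left, self._out[v])
        w = np.einsum("jy,cyp->cjp", self.mm._right, self._cl[v])
        return u * w

    def _branch_loglik(self, v: int, t: float) -> float:
        P = self.mm.transition(t)
        site = np.einsum("cxp,cxy,cyp->p", self._out[v], P,
                         self._cl[v]) / self.mm.ncat
        return float(np.sum(self.data.weights * np.log(np.maximum(site, 1e-300))))

    def _spectral_loglik(self, coef: np.ndarray, t: float) -> float:
        if self.mm.ncat == 1:
            site = np.exp(self.mm.lam * t) @ coef[0]
        else:
            E = np.exp(np.outer(self.mm.rates * t, self.mm.lam))
            site = np.einsum("cj,cjp->p", E, coef) / self.mm.ncat
        return float(self.data.weights @ np.log(np.maximum(site, 1e-300)))

    def optimize_branches(self, tol: float = 1e-6, max_sweeps: int = 50,
                          xtol: float = 1e-7) -> float:
        """Coordinate-wise branch optimization; each sweep refreshes the
        inside/outside partials then optimizes every branch in log-length
        space by golden-section search.  Stops when a sweep improves the
        log-likelihood by less than ``tol``."""
        lo, hi = math.log(MIN_BRANCH), math.log(MAX_BRANCH)
        best = prev = self.log_likelihood()
        best_bl = dict(self.bl)
        for _ in range(max_sweeps):
            self._outside()
            for v in self.preorder:
                coef = self._branch_coefficients(v)
                self.bl[v] = math.exp(_golden_max(
                    lambda u: self._spectral_loglik(coef, math.exp(u)),
                    lo, hi, xtol))
            cur = self.log_likelihood()
            if cur > best:
                best = cur
                best_bl = dict(self.bl)
            if cur - prev < tol:
                break
            prev = cur
        self.bl.update(best_bl)
        return best


# ---------------------------------------------------------------------------
# distance methods (starting topologies)

def jc_distance_matrix(data: PatternData) -> np.ndarray:
    """Pairwise Jukes-Cantor distances over unambiguously called sites."""
    n = data.n_taxa
    # classify each tip/pattern as a concrete base (argmax) or missing
    part = data.partials
    is_obs = part.sum(axis=1) == 1.0  # (ntaxa, P): exactly one base allowed
    state = part.argmax(axis=1)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = is_obs[i] & is_obs[j]
            total = data.weights[ok].sum()
            if total == 0:
                d = 0.0
            else:
                diff = data.weights[ok & (state[i] != state[j])].sum()
                p = diff / total
                p = min(p, 0.749)
                d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    return D


def neighbor_joining(D: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Classic neighbor joining; returns the unrooted topology as an edge
    list in the engine's node convention (branch lengths discarded — NJ is
    used only as a starting/reference topology)."""
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n) if i != j}
    next_internal = n
    edges: list[tuple[int, int]] = []

    def d(a, b):
        return dist[(a, b)] if a != b else 0.0

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                if best is None or q < best[0]:
                    best = (q, a, b)
        _, a, b = best
        u = next_internal
        next_internal += 1
        edges.append((a, u))
        edges.append((b, u))
        for c in active:
            if c in (a, b):
                continue
            nd = 0.5 * (d(a, c) + d(b, c) - d(a, b))
            dist[(u, c)] = dist[(c, u)] = max(nd, 0.0)
        active = [c for c in active if c not in (a, b)] + [u]
    u = next_internal
    for a in active:
        edges.append((a, u))
    return tuple(edges)
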