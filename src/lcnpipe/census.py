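"""Topology census over a set of gene trees.

Gene trees inferred from unlinked loci need not agree; tallying how many
loci support each distinct unrooted topology — and how many do so with
bootstrap support at or above a threshold on every internal branch — is
the standard way to quantify gene-tree discordance before any species-tree
or reticulation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import pandas as pd

TopologyKey = frozenset  # frozenset of frozensets of taxon labels


def _restrict(tree: dendropy.Tree, subset: Optional[Sequence[str]]):
    t = tree.clone(depth=1)
    if subset is not None:
        labels = set(subset)
        t.retain_taxa_with_labels(list(labels))
    seed = t.seed_node
    if len(seed.child_nodes()) == 2:
        # the two basal edges carry one and the same bipartition; make sure
        # its support label survives on whichever child the collapse keeps
        a, b = seed.child_nodes()
        label = a.label if a.label is not None else b.label
        for c in (a, b):
            if c.is_internal() and c.label is None:
                c.label = label
        t.collapse_basal_bifurcation()
    return t


def _support_of(node: dendropy.Node) -> Optional[float]:
    label = node.label
    if label is None:
        return None
    try:
        return float(label)
    except ValueError:
        return None


def _bipartitions(t: dendropy.Tree) -> dict[frozenset, Optional[float]]:
    """Non-trivial bipartitions of an (unrooted) tree, each mapped to the
    support parsed from its internal node label; sides are canonicalized
    as the taxon set not containing the alphabetically first leaf."""
    leaves = sorted(l.taxon.label for l in t.leaf_node_iter())
    anchor = leaves[0]
    all_taxa = frozenset(leaves)
    out: dict[frozenset, Optional[float]] = {}
    for node in t.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(all_taxa - side) < 2:
            continue
        if anchor in side:
            side = all_taxa - side
        support = _support_of(node)
        if side not in out or out[side] is None:
            out[side] = support
    return out


def topology_key(tree: dendropy.Tree,
                 subset: Optional[Sequence[str]] = None) -> TopologyKey:
    """Canonical key of a tree's unrooted topology restricted to a taxon
    subset: the set of its non-trivial bipartitions.  Branch lengths,
    supports, rotation and taxon order do not affect the key."""
    if subset is not None and len(subset) < 4:
        raise ValueError("subset must contain at least 4 taxa")
    t = _restrict(tree, subset)
    return frozenset(_bipartitions(t).keys())


@dataclass
class CensusResult:
    table: pd.DataFrame            # key_id, n_trees, n_supported, exemplar
    keys: dict[str, TopologyKey]
    n_trees: int
    n_supported_all_nodes: int     # trees with every internal branch >= threshold
    threshold: float


def census(trees: Mapping[str, dendropy.Tree], threshold: float = 80.0,
           subset: Optional[Sequence[str]] = None) -> CensusResult:
    """Group gene trees by topology and tally support-filtered counts.

    A tree counts as supported for its topology class iff every non-trivial
    bipartition of the (restricted) tree has bootstrap support >= threshold
    (inclusive).  Trees without parseable supports stay in the totals but
    are excluded from supported counts, with a warning.
    """
    groups: dict[TopologyKey, dict] = {}
    n_supported_total = 0
    for locus_id in sorted(trees):
        t = _restrict(trees[locus_id], subset)
        bips = _bipartitions(t)
        key = frozenset(bips.keys())
        entry = groups.setdefault(key, {"n": 0, "supported": 0,
                                        "exemplar": locus_id,
                                        "newick": t.as_string(schema="newick").strip()})
        entry["n"] += 1
        supports = list(bips.values())
        if any(s is None for s in supports):
            warnings.warn(f"{locus_id}: missing support values; excluded "
                          "from supported counts", stacklevel=2)
            continue
        if supports and all(s >= threshold for s in supports):
            entry["supported"] += 1
            n_supported_total += 1
    ordered = sorted(groups.items(), key=lambda kv: (-kv[1]["n"], kv[1]["exemplar"]))
    rows = []
    keys = {}
    for i, (key, entry) in enumerate(ordered, start=1):
        key_id = f"topology{i}"
        keys[key_id] = key
        rows.append({"key_id": key_id, "n_trees": entry["n"],
                     "n_supported": entry["supported"],
                     "exemplar_locus": entry["exemplar"],
                     "exemplar_newick": entry["newick"]})
    table = pd.DataFrame(rows, columns=["key_id", "n_trees", "n_supported",
                                        "exemplar_locus", "exemplar_newick"])
    return CensusResult(table=table, keys=keys, n_trees=len(trees),
                        n_supported_all_nodes=n_supported_total,
                        threshold=threshold)
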