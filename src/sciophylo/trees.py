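"""Rooted trees with branch lengths: parsing, writing, pruning, congruence.

The in-memory :class:`Tree` is a thin array-based container (postorder node
arrays) tuned for repeated pruning-algorithm passes; dendropy does the
Newick grammar work behind :func:`read_newick` / :func:`write_newick`.
Internal node labels are interpreted as support values, as exported by
Bayesian/ML tree programs, not as node names.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "TreeError",
    "read_newick",
    "write_newick",
    "prune_to_one_per_species",
    "validate_congruence",
]

#: floor applied to zero/missing branch lengths in likelihood work; avoids
#: singular transition matrices while being far below any resolvable length
MIN_BRANCH_LENGTH = 1e-8


class TreeError(ValueError):
    pass


@dataclass
class Node:
    index: int
    parent: int | None
    children: list[int] = field(default_factory=list)
    length: float | None = None
    label: str | None = None  # tip name
    support: str | None = None  # internal label, kept verbatim

    @property
    def is_tip(self) -> bool:
        return not self.children


class Tree:
    """Rooted tree; node 0..n-1 indexed, root has ``parent is None``.

    Polytomies are allowed and preserved.  Tip labels must be unique.
    """

    def __init__(self, nodes: list[Node], root: int):
        self.nodes = nodes
        self.root = root
        labels = [n.label for n in nodes if n.is_tip]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        if any(n.label is None for n in nodes if n.is_tip):
            raise TreeError("unlabeled tip")
        for n in nodes:
            if n.parent is not None and n.length is not None and n.length < 0:
                raise TreeError(f"negative branch length on node {n.index}")

    # ---------------------------------------------------------------- basic
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def tip_indices(self) -> list[int]:
        return [n.index for n in self.nodes if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [self.nodes[i].label for i in self.tip_indices]

    @property
    def internal_indices(self) -> list[int]:
        return [n.index for n in self.nodes if not n.is_tip]

    def postorder(self) -> list[int]:
        """Indices in postorder (children before parents)."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.nodes[i].children)
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def branch_lengths(self, clamp: bool = True) -> np.ndarray:
        """Per-node branch length array (root entry 0).

        Missing/zero lengths are clamped to ``MIN_BRANCH_LENGTH`` when
        ``clamp`` so transition matrices stay nonsingular.
        """
        bl = np.zeros(self.n_nodes)
        for n in self.nodes:
            if n.parent is None:
                continue
            t = n.length if n.length is not None else 0.0
            bl[n.index] = max(t, MIN_BRANCH_LENGTH) if clamp else t
        return bl

    def mrca(self, labels: Iterable[str]) -> int:
        want = set(labels)
        have = {n.label: n.index for n in self.nodes if n.is_tip}
        missing = want - have.keys()
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        # count tips under each node, postorder
        counts = np.zeros(self.n_nodes, dtype=int)
        for i in self.postorder():
            nd = self.nodes[i]
            if nd.is_tip:
                counts[i] = 1 if nd.label in want else 0
            else:
                counts[i] = sum(counts[c] for c in nd.children)
        k = len(want)
        best = self.root
        for i in self.postorder():
            if counts[i] == k:
                return i
        return best

    def clade_nodes(self, clade_root: int) -> set[int]:
        """All node indices in the subtree rooted at ``clade_root``."""
        out: set[int] = set()
        stack = [clade_root]
        while stack:
            i = stack.pop()
            out.add(i)
            stack.extend(self.nodes[i].children)
        return out

    def tip_set(self, clade_root: int) -> set[str]:
        return {
            self.nodes[i].label
            for i in self.clade_nodes(clade_root)
            if self.nodes[i].is_tip
        }

    # ------------------------------------------------------------- topology
    def bipartitions(self) -> set[frozenset[str]]:
        """Set of non-trivial tip bipartitions (as the smaller-side set)."""
        all_tips = frozenset(self.tip_labels)
        out: set[frozenset[str]] = set()
        for i in self.internal_indices:
            if i == self.root:
                continue
            side = frozenset(self.tip_set(i))
            if 1 < len(side) < len(all_tips):
                out.add(min(side, all_tips - side, key=sorted))
        return out

    def patristic_distance(self, a: str, b: str) -> float:
        idx = {n.label: n.index for n in self.nodes if n.is_tip}
        pa = self._path_to_root(idx[a])
        pb = self._path_to_root(idx[b])
        sa = dict(pa)
        # walk b's path until first shared ancestor
        for node, db in pb:
            if node in sa:
                return sa[node] + db
        raise TreeError("disconnected tree")

    def _path_to_root(self, i: int) -> list[tuple[int, float]]:
        out = []
        d = 0.0
        while True:
            out.append((i, d))
            nd = self.nodes[i]
            if nd.parent is None:
                return out
            d += nd.length or 0.0
            i = nd.parent

    def retain_tips(self, keep: Iterable[str]) -> "Tree":
        """Tree restricted to ``keep`` tips; unary nodes suppressed with
        lengths summed."""
        keep = set(keep)
        missing = keep - set(self.tip_labels)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        d = _to_dendropy(self)
        d.retain_taxa_with_labels(sorted(keep))
        # dendropy keeps the root even if unary; suppress
        d.suppress_unifurcations()
        return _from_dendropy(d)

    def copy(self) -> "Tree":
        return read_newick(write_newick(self))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree with {len(self.tip_labels)} tips>"


# ------------------------------------------------------------------ parsing

def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    nodes: list[Node] = []
    index: dict[int, int] = {}
    for dnode in dtree.preorder_node_iter():
        i = len(nodes)
        index[id(dnode)] = i
        parent = index[id(dnode.parent_node)] if dnode.parent_node else None
        label = None
        support = None
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            support = dnode.label
        nodes.append(
            Node(index=i, parent=parent, length=dnode.edge.length,
                 label=label, support=support)
        )
        if parent is not None:
            nodes[parent].children.append(i)
    return Tree(nodes, root=0)


def _to_dendropy(tree: Tree) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)
    dnodes = {tree.root: dtree.seed_node}
    for i in tree.preorder():
        if i == tree.root:
            dn = dtree.seed_node
        else:
            dn = dnodes[tree.nodes[i].parent].new_child()
            dnodes[i] = dn
        nd = tree.nodes[i]
        dn.edge.length = nd.length
        if nd.is_tip:
            dn.taxon = taxa.new_taxon(nd.label)
        elif nd.support is not None:
            dn.label = nd.support
    return dtree


def read_newick(text: str) -> Tree:
    """Parse one Newick tree from a string.

    Lengths kept at full precision, polytomies preserved, internal labels
    stored as supports.  Raises :class:`TreeError` naming the offset on
    malformed input.
    """
    text = text.strip()
    if not text:
        raise TreeError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error classes
        offset = getattr(exc, "col_num", None)
        where = f" near column {offset}" if offset is not None else ""
        raise TreeError(f"malformed Newick{where}: {exc}") from exc
    return _from_dendropy(dtree)


def read_newick_file(path) -> Tree:
    with open(path) as fh:
        return read_newick(fh.read())


def _fmt_len(x: float | None) -> str:
    return "" if x is None else f":{x:.10g}"


def write_newick(tree: Tree) -> str:
    """Serialize to Newick; lengths at 10 significant digits."""

    def rec(i: int) -> str:
        nd = tree.nodes[i]
        if nd.is_tip:
            name = nd.label
            if any(c in name for c in " (),:;[]'"):
                name = "'" + name.replace("'", "''") + "'"
            return name + _fmt_len(nd.length)
        inner = ",".join(rec(c) for c in nd.children)
        sup = nd.support or ""
        return f"({inner}){sup}" + _fmt_len(nd.length)

    return rec(tree.root) + ";"


def write_newick_file(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# ------------------------------------------------- species-level operations

def species_of(label: str) -> str:
    """Species part of a ``Genus_species_specimen`` tip label.

    Labels without a trailing specimen identifier are returned unchanged.
    """
    parts = label.split("_")
    if len(parts) >= 3:
        return "_".join(parts[:2])
    return label


def prune_to_one_per_species(tree, matrix=None, keep_rule="fewest_missing"):
    """Keep one terminal per species; returns ``(tree, matrix_or_None)``.

    keep_rule:
      * ``"fewest_missing"`` (default) — retain the specimen with fewest
        missing characters in ``matrix``, ties broken by lexicographic
        specimen id;
      * ``"first"`` — lexicographically first label.

    Pendant lengths of removed tips are discarded; unary internal nodes are
    suppressed with lengths summed, so patristic distances between retained
    tips are untouched.  Specimens of a non-monophyletic species trigger a
    warning but the rule is still applied.
    """
    import warnings

    groups: dict[str, list[str]] = {}
    for lab in tree.tip_labels:
        groups.setdefault(species_of(lab), []).append(lab)

    def missing_count(label: str) -> int:
        if matrix is None or label not in matrix.taxa:
            return 0
        row = matrix.data.loc[label]
        return int((row == matrix.missing_code).sum())

    keep: list[str] = []
    for sp, labs in groups.items():
        if len(labs) > 1:
            clade = tree.mrca(labs)
            if tree.tip_set(clade) != set(labs):
                warnings.warn(f"specimens of {sp} are not monophyletic")
        if keep_rule == "first":
            keep.append(min(labs))
        else:
            keep.append(min(labs, key=lambda l: (missing_count(l), l)))
    pruned = tree.retain_tips(keep)
    # collapse labels to species names
    for nd in pruned.nodes:
        if nd.is_tip:
            nd.label = species_of(nd.label)
    out_matrix = None
    if matrix is not None:
        kept_rows = [l for l in keep if l in matrix.taxa]
        out_matrix = (
            matrix.subset(kept_rows)
            .rename_taxa(species_of)
            .subset(pruned.tip_labels)
        )
    return pruned, out_matrix


def validate_congruence(tree: Tree, matrix) -> dict:
    """Report taxa present in only one of tree / character matrix.

    The pipeline requires ``tip set ⊆ matrix taxa``; matrix rows without a
    tip are ignored (report-only).
    """
    tips = set(tree.tip_labels)
    taxa = set(matrix.taxa)
    report = {
        "tree_only": sorted(tips - taxa),
        "matrix_only": sorted(taxa - tips),
        "ok": tips <= taxa,
    }
    return report
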