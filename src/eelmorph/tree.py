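"""Rooted phylogenies with node ages and tip occurrence ranges.

:class:`Phylogeny` wraps a :class:`dendropy.Tree`. Ages are Ma before
present (larger = older) and live on ``node.age``; tip stratigraphic
ranges (first/last occurrence) live in side dictionaries keyed by tip
label. Polytomies are first-class — the composite eel tree has extensive
polytomies and is used unresolved.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Tuple

import dendropy

from .errors import TreeError


class Phylogeny:
    """A rooted tree, optionally dated.

    Parameters
    ----------
    tree:
        A rooted ``dendropy.Tree``; tip labels must be unique.
    first_occurrence, last_occurrence:
        Tip label -> age (Ma). ``first >= last``; both 0 for extant tips.
        Tips not listed are treated as extant (0, 0).
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        first_occurrence: Optional[Dict[str, float]] = None,
        last_occurrence: Optional[Dict[str, float]] = None,
    ) -> None:
        self.tree = tree
        self.tree.is_rooted = True
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        self.first_occurrence: Dict[str, float] = dict(first_occurrence or {})
        self.last_occurrence: Dict[str, float] = dict(last_occurrence or {})
        for lab in labels:
            fo = self.first_occurrence.get(lab, 0.0)
            lo = self.last_occurrence.get(lab, 0.0)
            if fo < lo:
                raise TreeError(
                    f"tip {lab!r}: first occurrence {fo} Ma younger than last {lo} Ma"
                )
            self.first_occurrence[lab] = fo
            self.last_occurrence[lab] = lo

    # -- structure ---------------------------------------------------

    @property
    def tip_labels(self) -> List[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def mrca(self, labels: Iterable[str]) -> dendropy.Node:
        labels = list(labels)
        missing = set(labels) - set(self.tip_labels)
        if missing:
            raise TreeError(f"unknown tip labels in MRCA query: {sorted(missing)}")
        node = self.tree.mrca(taxon_labels=labels)
        if node is None:
            raise TreeError(f"unresolvable MRCA for {sorted(labels)}")
        return node

    # -- ages ---------------------------------------------------------

    @property
    def is_calibrated(self) -> bool:
        return all(getattr(n, "age", None) is not None for n in self.tree)

    def node_age(self, node: dendropy.Node) -> float:
        age = getattr(node, "age", None)
        if age is None:
            raise TreeError("node has no age; calibrate the tree first")
        return age

    def branch_durations(self) -> List[Tuple[str, float]]:
        """(child description, parent age - child age) for every edge."""
        out = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            name = node.taxon.label if node.is_leaf() else f"node:{id(node) & 0xffff:04x}"
            out.append((name, self.node_age(node.parent_node) - self.node_age(node)))
        return out

    def set_ages_from_branch_lengths(self, tip_age: float = 0.0) -> None:
        """Date an ultrametric tree from its edge lengths (tips at ``tip_age``)."""
        depths = {self.root: 0.0}
        maxdepth = 0.0
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                el = node.edge.length or 0.0
                depths[node] = depths[node.parent_node] + el
                maxdepth = max(maxdepth, depths[node])
        for node, d in depths.items():
            node.age = maxdepth - d + tip_age

    # -- serialization ------------------------------------------------

    def as_newick(self, include_ages: bool = False) -> str:
        if include_ages:
            for node in self.tree:
                age = getattr(node, "age", None)
                node.annotations.drop(name="age")
                if age is not None:
                    node.annotations.add_new("age", round(age, 6))
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_annotations=not include_ages,
        ).strip()
        return s

    def clone(self) -> "Phylogeny":
        t = dendropy.Tree(self.tree)
        for src, dst in zip(self.tree, t):
            if getattr(src, "age", None) is not None:
                dst.age = src.age
        return Phylogeny(t, dict(self.first_occurrence), dict(self.last_occurrence))


def from_newick(newick: str, **kw) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Unbalanced parentheses raise :class:`TreeError` with the character
    offset of the imbalance.
    """
    depth = 0
    for i, ch in enumerate(newick):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise TreeError(f"unbalanced ')' at character {i}")
    if depth != 0:
        raise TreeError(f"unbalanced '(' — {depth} unclosed at end of input")
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"newick parse error: {exc}") from exc
    return Phylogeny(tree, **kw)


def star_tree(tip_labels: Iterable[str], depth: float) -> Phylogeny:
    """A star (single polytomy) phylogeny with all tips at equal depth.

    Useful as a no-structure null: its Brownian covariance is diagonal.
    """
    labels = list(tip_labels)
    if len(labels) < 2:
        raise TreeError("a star tree needs >= 2 tips")
    phy = from_newick("(" + ",".join(labels) + ");")
    phy.root.age = depth
    for lf in phy.tree.leaf_node_iter():
        lf.age = 0.0
    return phy
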