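"""Cell-type differentiation hierarchy.

The signature-derivation procedure compares cell types *within* categories
along a differentiation hierarchy of at most three levels: the children of
the root are level-1 nodes (broad compartments such as epithelial or
immune), their children are level-2 nodes (e.g. T cells vs NK cells), and
level-3 nodes are terminal activation states. Leaves — the deconvolution
targets — may sit at any level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["CellHierarchy", "DEFAULT_HIERARCHY_PATH", "load_default_hierarchy"]

DEFAULT_HIERARCHY_PATH = Path(__file__).parent / "data" / "default_hierarchy.yaml"

MAX_DEPTH = 3


@dataclass
class CellHierarchy:
    """Rooted tree of named cell-type categories, depth at most three.

    Parameters
    ----------
    children
        Mapping node name -> list of child names. The root is named
        ``root`` and is not itself a cell type.
    """

    children: dict[str, list[str]]
    root: str = "root"
    _parent: dict[str, str] = field(init=False, repr=False)
    _level: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.root not in self.children:
            raise ValueError(f"root node {self.root!r} missing from children map")
        self._parent = {}
        self._level = {self.root: 0}
        seen = {self.root}
        frontier = [self.root]
        while frontier:
            node = frontier.pop()
            for child in self.children.get(node, []):
                if child in seen:
                    raise ValueError(f"node {child!r} has more than one parent")
                seen.add(child)
                self._parent[child] = node
                self._level[child] = self._level[node] + 1
                if self._level[child] > MAX_DEPTH:
                    raise ValueError(f"hierarchy deeper than {MAX_DEPTH} levels at {child!r}")
                frontier.append(child)
        orphans = set(self.children) - seen
        if orphans:
            raise ValueError(f"nodes unreachable from root: {sorted(orphans)}")

    # -- structure queries -------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        """All cell-type nodes (root excluded), in deterministic order."""
        out: list[str] = []
        stack = list(reversed(self.children[self.root]))
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(self.children.get(node, [])))
        return out

    @property
    def leaves(self) -> list[str]:
        return [n for n in self.nodes if not self.children.get(n)]

    def level_of(self, node: str) -> int:
        return self._level[node]

    def parent_of(self, node: str) -> str:
        return self._parent[node]

    def children_of(self, node: str) -> list[str]:
        return list(self.children.get(node, []))

    def is_leaf(self, node: str) -> bool:
        return not self.children.get(node)

    def leaf_descendants(self, node: str) -> list[str]:
        """Terminal cell types below (or equal to) ``node``."""
        if self.is_leaf(node):
            return [node]
        out: list[str] = []
        for child in self.children[node]:
            out.extend(self.leaf_descendants(child))
        return out

    def sibling_groups(self, level: int) -> list[list[str]]:
        """Groups of nodes compared against each other at ``level``.

        Each group is the set of children of one node at ``level - 1``
        (the root for level 1); only groups of size >= 2 are returned.
        """
        parents = [self.root] if level == 1 else [
            n for n in self.nodes if self._level[n] == level - 1 and not self.is_leaf(n)
        ]
        groups = [self.children_of(p) for p in parents]
        return [g for g in groups if len(g) >= 2]

    @property
    def levels(self) -> list[int]:
        return sorted({self._level[n] for n in self.nodes})

    # -- (de)serialization -------------------------------------------------
    @classmethod
    def from_mapping(cls, tree: dict) -> "CellHierarchy":
        """Build from a nested mapping ``{root: {child: {...}, leaf: {}}}``."""
        if len(tree) != 1:
            raise ValueError("nested mapping must have a single root key")
        root = next(iter(tree))
        children: dict[str, list[str]] = {}

        def walk(name: str, sub: dict | None) -> None:
            sub = sub or {}
            children[name] = list(sub)
            for child, node in sub.items():
                walk(child, node)

        walk(root, tree[root])
        return cls(children=children, root=root)

    def to_mapping(self) -> dict:
        def build(name: str) -> dict:
            return {c: build(c) for c in self.children.get(name, [])}

        return {self.root: build(self.root)}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CellHierarchy":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=False)

    def validate_leaf_names(self) -> None:
        leaves = self.leaves
        if len(leaves) != len(set(leaves)):
            raise ValueError("leaf names are not unique")


def load_default_hierarchy() -> CellHierarchy:
    """Packaged three-level hierarchy: four broad compartments, with the
    immune compartment resolved into T-cell and NK-cell lineages and their
    terminal states (eight leaves in total)."""
    return CellHierarchy.from_yaml(DEFAULT_HIERARCHY_PATH)
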