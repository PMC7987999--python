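"""Rooted, dated tree structure used across the pipeline.

The haplotree is rooted and (for dated trees) ultrametric: every tip sits at
age 0 and internal nodes carry ages in years before present.  Branch lengths
in Newick serialisations are age differences (years).  Newick parsing is
delegated to dendropy; only the conversion into this light structure is done
here.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import dendropy

__all__ = ["Node", "Tree", "min_state_changes", "state_change_edges",
           "resolve_polytomies"]


class Node:
    """One node of a rooted tree.

    Attributes
    ----------
    name : str | None
        Tip label or branch name (e.g. ``"J1a1a1-P58"``).
    age : float
        Years before present (tips are 0 in ultrametric trees).
    sites : list
        Positions of the SNPs assigned to the branch above this node.
    location : tuple[float, float] | None
        (lat, lon) in degrees, when geography is attached.
    population : str | None
    """

    __slots__ = ("name", "age", "parent", "children", "sites", "location", "population")

    def __init__(self, name=None, age=0.0, children=None):
        self.name = name
        self.age = float(age)
        self.parent = None
        self.children = []
        self.sites = []
        self.location = None
        self.population = None
        if children:
            for c in children:
                self.add_child(c)

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def remove_child(self, node: "Node") -> None:
        self.children.remove(node)
        node.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def branch_length(self) -> float:
        """Duration of the branch above this node, years."""
        if self.parent is None:
            return 0.0
        return self.parent.age - self.age

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "tip" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.name!r} {kind} age={self.age:.1f}>"


class Tree:
    """Rooted tree with named tips and aged nodes."""

    def __init__(self, root: Node):
        self.root = root

    # ---------------------------------------------------------------- traversal
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def branches(self) -> list[Node]:
        """Every node except the root, i.e. one per branch."""
        return [n for n in self.postorder() if n.parent is not None]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Node:
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(f"no node named {name!r}")

    def has_node(self, name: str) -> bool:
        return any(n.name == name for n in self.postorder())

    def leaf_sets(self) -> dict[int, frozenset]:
        """Map id(node) -> frozenset of descendant tip names."""
        out: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[id(node)] = frozenset([node.name])
            else:
                s: set = set()
                for c in node.children:
                    s |= out[id(c)]
                out[id(node)] = frozenset(s)
        return out

    def mrca(self, names: Iterable[str]) -> Node:
        targets = set(names)
        sets = self.leaf_sets()
        best = None
        for node in self.postorder():
            if targets <= sets[id(node)]:
                if best is None or len(sets[id(node)]) < len(sets[id(best)]):
                    best = node
        if best is None:
            raise KeyError(f"tips not all present: {sorted(targets)}")
        return best

    def total_branch_time(self) -> float:
        return sum(n.branch_length for n in self.branches())

    # ---------------------------------------------------------------- editing
    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(name=node.name, age=node.age)
            new.sites = list(node.sites)
            new.location = node.location
            new.population = node.population
            for c in node.children:
                new.add_child(clone(c))
            return new

        return Tree(clone(self.root))

    def prune_leaves(self, names: Iterable[str]) -> "Tree":
        """Return a copy with the given tips removed and unifurcations collapsed."""
        drop = set(names)
        tree = self.copy()
        for name in drop:
            leaf = tree.find(name)
            parent = leaf.parent
            if parent is None:
                raise ValueError("cannot prune the only node of a tree")
            parent.remove_child(leaf)
            # collapse chains of single-child nodes upward
            node = parent
            while node is not None and len(node.children) == 1 and node.parent is not None:
                child = node.children[0]
                gp = node.parent
                gp.remove_child(node)
                child.sites = node.sites + child.sites
                gp.add_child(child)
                node = gp
        # root left with a single child: promote the child
        while not tree.root.is_leaf and len(tree.root.children) == 1:
            child = tree.root.children[0]
            child.parent = None
            child.sites = tree.root.sites + child.sites
            tree.root = child
        return tree

    def collapse_unifurcations(self) -> None:
        """In place: merge single-child internal nodes into their child."""
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if not node.is_leaf and len(node.children) == 1 and node.parent is not None:
                    child = node.children[0]
                    child.sites = node.sites + child.sites
                    gp = node.parent
                    gp.remove_child(node)
                    gp.add_child(child)
                    changed = True
        if not self.root.is_leaf and len(self.root.children) == 1:
            child = self.root.children[0]
            child.sites = self.root.sites + child.sites
            child.parent = None
            self.root = child

    # ---------------------------------------------------------------- newick IO
    def to_newick(self, include_internal_names: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                suffix = (node.name or "") if include_internal_names else ""
                label = f"({inner})" + suffix
            if node.parent is None:
                return label
            return f"{label}:{node.branch_length:.12g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dtree = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=True)
        droot = dtree.seed_node

        # depth of every node from the root, then convert to ages
        depth: dict = {droot: 0.0}
        for edge in dtree.preorder_edge_iter():
            if edge.tail_node is not None:
                depth[edge.head_node] = depth[edge.tail_node] + (edge.length or 0.0)
        max_depth = max(depth.values()) if depth else 0.0

        def convert(dnode) -> Node:
            if dnode.taxon is not None:
                name = dnode.taxon.label
            else:
                name = dnode.label
            node = Node(name=name, age=max(0.0, max_depth - depth[dnode]))
            for c in dnode.child_nodes():
                node.add_child(convert(c))
            return node

        return cls(convert(droot))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def read(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def __repr__(self):  # pragma: no cover
        return f"<Tree {self.n_leaves} tips root_age={self.root.age:.1f}>"


def resolve_polytomies(tree: Tree, epsilon: float = 1e-6) -> Tree:
    """Binary-resolve every polytomy by a deterministic ladder.

    A node with children c1..ck (sorted by name) becomes a chain of k-1
    binary merges; the inserted nodes are named ``<node>|r1``, ``|r2`` ...
    and get ages just below the original node's age (separated by a
    relative ``epsilon``), so downstream age sampling starts from a valid
    strictly-ordered state.  Branches created by the resolution carry no
    sites.  Returns a resolved copy; the input is untouched.
    """
    tree = tree.copy()
    for node in list(tree.postorder()):
        if len(node.children) <= 2:
            continue
        kids = sorted(node.children, key=lambda c: (c.name or ""))
        for c in kids:
            node.remove_child(c)
        current = kids[0]
        for i, nxt in enumerate(kids[1:-1], start=1):
            floor = max(current.age, nxt.age)
            merged = Node(
                name=f"{node.name}|r{i}",
                age=floor + (node.age - floor) * 0.5 if node.age > 0 else 0.0,
            )
            merged.add_child(current)
            merged.add_child(nxt)
            current = merged
        node.add_child(current)
        node.add_child(kids[-1])
    return tree


# -------------------------------------------------------------------- parsimony
_INF = 1e18


def _sankoff_costs(tree: Tree, tip_states: Mapping[str, np.ndarray]) -> np.ndarray:
    """Bottom-up Sankoff DP for binary characters, vectorised over sites.

    tip_states maps tip name -> int array of 0 (ancestral), 1 (derived) or
    -1 (missing).  Returns root cost array of shape (n_sites, 2): the minimum
    number of state changes given each root state.
    """
    first = next(iter(tip_states.values()))
    m = len(np.atleast_1d(first))
    costs: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            states = np.atleast_1d(np.asarray(tip_states[node.name]))
            c = np.zeros((m, 2))
            c[states == 0, 1] = _INF
            c[states == 1, 0] = _INF
            costs[id(node)] = c
        else:
            total = np.zeros((m, 2))
            for child in node.children:
                cc = costs.pop(id(child))
                # transition cost 1 between states
                total[:, 0] += np.minimum(cc[:, 0], cc[:, 1] + 1.0)
                total[:, 1] += np.minimum(cc[:, 1], cc[:, 0] + 1.0)
            costs[id(node)] = total
    return costs[id(tree.root)]


def min_state_changes(
    tree: Tree, tip_states: Mapping[str, np.ndarray], root_state: int | None = 0
) -> np.ndarray:
    """Minimum number of state changes for each site on the tree.

    With ``root_state=0`` the root is constrained to the ancestral allele
    (the matrix is polarised); pass ``None`` to minimise over root states.
    """
    root_cost = _sankoff_costs(tree, tip_states)
    if root_state is None:
        out = root_cost.min(axis=1)
    else:
        out = root_cost[:, root_state]
    out = np.where(out >= _INF / 2, np.inf, out)
    return out


def state_change_edges(tree: Tree, tip_states: Mapping[str, int]) -> list[Node]:
    """One minimal-change labelling of a single binary character.

    Returns the child nodes of edges on which the state changes (origins and
    losses), with the root constrained to the ancestral state.  Ties during
    the top-down pass are broken toward the parent's state, which favours
    fewer, deeper changes.
    """
    states = {k: np.asarray([v]) for k, v in tip_states.items()}
    costs: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = states[node.name][0]
            c = np.zeros(2)
            if s == 0:
                c[1] = _INF
            elif s == 1:
                c[0] = _INF
            costs[id(node)] = c
        else:
            total = np.zeros(2)
            for child in node.children:
                cc = costs[id(child)]
                total[0] += min(cc[0], cc[1] + 1.0)
                total[1] += min(cc[1], cc[0] + 1.0)
            costs[id(node)] = total

    changed: list[Node] = []
    assign: dict[int, int] = {id(tree.root): 0}
    for node in tree.preorder():
        s = assign[id(node)]
        for child in node.children:
            cc = costs[id(child)]
            keep = cc[s]
            switch = cc[1 - s] + 1.0
            cs = s if keep <= switch else 1 - s
            assign[id(child)] = cs
            if cs != s:
                changed.append(child)
    return changed
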