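"""Haplotree construction from the QC'd binary matrix.

On polarised, nearly homoplasy-free Y-chromosome data the tree topology is
determined by site compatibility, so the haplotree is built directly as the
perfect phylogeny of the carrier sets; sites incompatible with it are
resolved by small parsimony and flagged recurrent.  Branch names follow the
hierarchical haplogroup convention: children ranked major-first by
descendant count, suffixes alternating letters and numbers with depth, and
a defining-marker label appended (e.g. ``J1a1a1-P58``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .trees import Node, Tree, state_change_edges

__all__ = [
    "SiteAssignment",
    "build_parsimony_tree",
    "map_sites_to_branches",
    "annotate_branch_names",
    "parse_branch_name",
]


@dataclass
class SiteAssignment:
    """Site -> branch map with recurrence bookkeeping.

    ``branches[pos]`` is a tuple of branch (child-node) names: length 1 for
    single-origin sites, longer for recurrent sites (all state-change
    branches of a minimal labelling), empty for unassignable sites.
    """

    branches: dict[int, tuple[str, ...]] = field(default_factory=dict)
    recurrent: set[int] = field(default_factory=set)

    @property
    def n_sites(self) -> int:
        return len(self.branches)

    @property
    def n_recurrent(self) -> int:
        return len(self.recurrent)

    @property
    def recurrence_fraction(self) -> float:
        return self.n_recurrent / self.n_sites if self.n_sites else 0.0

    def branch_snp_counts(self) -> dict[str, int]:
        """Single-origin SNPs per branch, keyed by child-node name."""
        counts: dict[str, int] = {}
        for pos, brs in self.branches.items():
            if pos not in self.recurrent and len(brs) == 1:
                counts[brs[0]] = counts.get(brs[0], 0) + 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"position": pos, "branch": ",".join(brs),
             "recurrent": pos in self.recurrent}
            for pos, brs in sorted(self.branches.items())
        ]
        return pd.DataFrame(rows, columns=["position", "branch", "recurrent"])


def _polarize(matrix: GenotypeMatrix, outgroup: str) -> GenotypeMatrix:
    og = matrix.column(outgroup)
    flip = og == 1
    out = matrix.drop_samples([outgroup])
    calls = out.calls.copy()
    sub = calls[:, flip]
    swapped = sub.copy()
    swapped[sub == 0] = 1
    swapped[sub == 1] = 0
    calls[:, flip] = swapped
    return GenotypeMatrix(samples=out.samples, positions=out.positions,
                          calls=calls, platforms=out.platforms)


def build_parsimony_tree(
    matrix: GenotypeMatrix,
    outgroup_sample: str | None = None,
) -> Tree:
    """Perfect-phylogeny haplotree of the binary matrix.

    If ``outgroup_sample`` is given, sites are re-polarised so the outgroup
    carries the ancestral state everywhere, and the outgroup column is
    dropped from the returned tree.  Compatible sites become the tree's
    branches (sites attached to ``node.sites``); incompatible sites are left
    for :func:`map_sites_to_branches` to flag recurrent.  Missing calls are
    treated as non-carriers during construction (the smaller-carrier-set
    resolution).  Polytomies are allowed; identical samples become sister
    tips under their shared defining branch.
    """
    if outgroup_sample is not None:
        matrix = _polarize(matrix, outgroup_sample)
    all_missing = [
        s for i, s in enumerate(matrix.samples)
        if matrix.n_sites and np.all(matrix.calls[i] == MISSING)
    ]
    if all_missing:
        raise ValueError(f"samples with no calls at all: {all_missing}")

    samples = list(matrix.samples)
    root_set = frozenset(samples)
    # only complete-call sites define clades: a site with missing calls has
    # an ambiguous carrier set and must not create novel structure (it is
    # attached afterwards by wildcard matching in map_sites_to_branches)
    groups: dict[frozenset, list[int]] = {}
    complete = (matrix.calls != MISSING).all(axis=0)
    for j in np.nonzero(complete)[0]:
        carriers = matrix.carriers(j)
        groups.setdefault(carriers, []).append(int(matrix.positions[j]))

    root = Node(name="root", age=0.0)
    node_set: dict[int, frozenset] = {id(root): root_set}
    # best-supported carrier sets claim the topology first, so a lone
    # homoplasic site (e.g. a retained two-origin SNP whose carriers span
    # two clades) cannot displace clades backed by many sites
    sets_sorted = sorted(
        (s for s in groups if 0 < len(s) < len(samples)),
        key=lambda s: (-len(groups[s]), -len(s), min(groups[s])),
    )
    tip_parent_sites: dict[str, list[int]] = {s: [] for s in samples}
    for S in sets_sorted:
        if len(S) == 1:
            (only,) = S
            tip_parent_sites[only].extend(groups[S])
            continue
        node = root
        conflict = False
        while True:
            nxt = None
            for child in node.children:
                cs = node_set[id(child)]
                if S <= cs:
                    nxt = child
                    break
                if S & cs and not cs < S:
                    conflict = True  # partial overlap: incompatible site
                    break
            if conflict or nxt is None:
                break
            node = nxt
        if conflict:
            continue  # flagged later by map_sites_to_branches
        child = Node(name=None, age=0.0)
        child.sites = list(groups[S])
        node_set[id(child)] = S
        # re-parent smaller already-placed clades contained in S
        for sub in [c for c in node.children if node_set[id(c)] < S]:
            node.remove_child(sub)
            child.add_child(sub)
        node.add_child(child)

    if root_set in groups:
        root.sites = list(groups[root_set])

    # attach tips under the smallest containing clade
    for s in samples:
        node = root
        while True:
            nxt = None
            for child in node.children:
                if id(child) in node_set and s in node_set[id(child)]:
                    nxt = child
                    break
            if nxt is None:
                break
            node = nxt
        tip = Node(name=s, age=0.0)
        tip.sites = tip_parent_sites[s]
        node.add_child(tip)

    # deterministic internal names (overwritten by annotate_branch_names)
    counter = 0
    tree = Tree(root)
    for node in tree.preorder():
        if not node.is_leaf and node.parent is not None:
            counter += 1
            node.name = f"node{counter}"
    return tree


def map_sites_to_branches(
    tree: Tree,
    matrix: GenotypeMatrix,
    attach: bool = True,
) -> SiteAssignment:
    """Assign every site to the branch(es) explaining its carrier set.

    A site whose non-missing carriers match exactly one clade (missing calls
    are wildcards; ties resolved toward the smaller clade) is single-origin
    on that branch.  Other sites receive a minimal state-change labelling by
    small parsimony and are counted recurrent.  With ``attach=True`` the
    single-origin sites are written onto ``node.sites``.
    """
    tips = set(tree.leaf_names())
    extra = [s for s in matrix.samples if s not in tips]
    if extra:
        raise ValueError(f"matrix samples missing from tree: {extra}")

    leaf_sets = tree.leaf_sets()
    nodes = [n for n in tree.postorder()]
    by_set: dict[frozenset, Node] = {}
    for n in nodes:
        by_set.setdefault(leaf_sets[id(n)], n)
    nodes_by_size = sorted(nodes, key=lambda n: len(leaf_sets[id(n)]))

    assignment = SiteAssignment()
    if attach:
        for n in nodes:
            n.sites = []
    states = matrix.tip_states()
    for j in range(matrix.n_sites):
        pos = int(matrix.positions[j])
        carriers = matrix.carriers(j)
        wild = matrix.missing_samples(j)
        if not carriers:
            assignment.branches[pos] = ()
            continue
        target = None
        exact = by_set.get(carriers)
        if exact is not None and not wild:
            target = exact
        else:
            upper = carriers | wild
            for n in nodes_by_size:
                ds = leaf_sets[id(n)]
                if carriers <= ds <= upper:
                    target = n
                    break
        if target is not None and target.parent is not None:
            assignment.branches[pos] = (target.name,)
            if attach:
                target.sites.append(pos)
        elif target is not None:
            # carriers fill the whole tree: the root/stem "branch"
            assignment.branches[pos] = (target.name,)
            if attach:
                target.sites.append(pos)
        else:
            tip_states = {s: int(states[s][j]) for s in matrix.samples}
            for s in tips - set(matrix.samples):
                tip_states[s] = MISSING
            changed = state_change_edges(tree, tip_states)
            assignment.branches[pos] = tuple(n.name for n in changed)
            assignment.recurrent.add(pos)
    return assignment


_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _letter_suffix(i: int) -> str:
    out = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out = _LETTERS[r] + out
    return out


def annotate_branch_names(
    tree: Tree,
    haplogroup_label: str = "J1",
    marker_names: dict[int, str] | None = None,
    genotyped_markers: set[str] | None = None,
) -> Tree:
    """Apply hierarchical haplogroup nomenclature to the tree (in place).

    At every split the children are ranked by descendant-tip count (major
    first, ties by marker name, then by smallest tip label); suffixes
    alternate letters and numbers with depth ("a"/"1" always going to the
    major child).  Each branch with a named defining SNP gets a
    "-<marker>" label, preferring markers genotyped in-study, otherwise the
    lexicographically smallest.  Unifurcations are collapsed, their sites
    joining the child branch.
    """
    if marker_names:
        values = list(marker_names.values())
        if len(values) != len(set(values)):
            dupes = sorted({v for v in values if values.count(v) > 1})
            raise ValueError(f"duplicate marker names: {dupes}")
    marker_names = marker_names or {}
    genotyped_markers = genotyped_markers or set()

    tree.collapse_unifurcations()
    leaf_sets = tree.leaf_sets()

    def best_marker(node: Node) -> str | None:
        named = sorted(marker_names[p] for p in node.sites if p in marker_names)
        if not named:
            return None
        geno = [m for m in named if m in genotyped_markers]
        return geno[0] if geno else named[0]

    def full_name(base: str, node: Node) -> str:
        m = best_marker(node)
        return f"{base}-{m}" if m else base

    tree.root.name = full_name(haplogroup_label, tree.root)
    base_of: dict[int, str] = {id(tree.root): haplogroup_label}
    depth_of: dict[int, int] = {id(tree.root): 0}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        depth = depth_of[id(node)]
        internal_children = [c for c in node.children if not c.is_leaf]
        ranked = sorted(
            internal_children,
            key=lambda c: (
                -len(leaf_sets[id(c)]),
                best_marker(c) or "￿",
                min(leaf_sets[id(c)]),
            ),
        )
        for rank, child in enumerate(ranked):
            suffix = _letter_suffix(rank) if depth % 2 == 0 else str(rank + 1)
            base = base_of[id(node)] + suffix
            base_of[id(child)] = base
            depth_of[id(child)] = depth + 1
            child.name = full_name(base, child)
    return tree


def parse_branch_name(name: str, haplogroup_label: str = "J1") -> list[str]:
    """Split a branch name back into its per-depth suffixes.

    ``"J1a1a-P58" -> ["a", "1", "a"]``; the marker suffix and haplogroup
    label are stripped.  The suffix at even depths is a letter run, at odd
    depths a digit run, so the alternation makes the parse unambiguous.
    """
    core = name.split("-", 1)[0]
    if not core.startswith(haplogroup_label):
        raise ValueError(f"{name!r} does not start with {haplogroup_label!r}")
    rest = core[len(haplogroup_label):]
    return re.findall(r"[a-z]+|[0-9]+", rest)
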