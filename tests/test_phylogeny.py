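"""Haplotree construction, site mapping, and nomenclature."""

import numpy as np
import pytest

from ychron.genotypes import MISSING, GenotypeMatrix
from ychron.phylogeny import (
    annotate_branch_names,
    build_parsimony_tree,
    map_sites_to_branches,
    parse_branch_name,
)
from ychron.trees import Tree

from conftest import true_clades


def matrix_of(samples, sites):
    positions = np.array(sorted(sites), dtype=np.int64)
    calls = np.zeros((len(samples), len(positions)), dtype=np.int8)
    for j, pos in enumerate(positions):
        for s, v in sites[pos].items():
            calls[samples.index(s), j] = v
    return GenotypeMatrix(samples=list(samples), positions=positions, calls=calls)


class TestBuildTree:
    def test_textbook_caterpillar(self):
        """Nested sites {A,B,C},{A,B},{A} give ((A,B),C) rooted by outgroup."""
        m = matrix_of(
            ["A", "B", "C", "OUT"],
            {10: {"A": 1, "B": 1, "C": 1}, 20: {"A": 1, "B": 1}, 30: {"A": 1}},
        )
        tree = build_parsimony_tree(m, outgroup_sample="OUT")
        sets = tree.leaf_sets()
        clades = {sets[id(n)] for n in tree.postorder() if not n.is_leaf}
        assert frozenset({"A", "B"}) in clades
        assert sets[id(tree.root)] == frozenset({"A", "B", "C"})
        # root branch carries the {A,B,C} site, the cherry carries site 20
        assert tree.root.sites == [10]
        ab = tree.mrca(["A", "B"])
        assert ab.sites == [20]
        assert tree.find("A").sites == [30]

    def test_outgroup_polarises_flipped_sites(self):
        # outgroup derived at POS 10: polarity flips, carriers become {B}
        m = matrix_of(["A", "B", "OUT"], {10: {"A": 1, "OUT": 1}})
        tree = build_parsimony_tree(m, outgroup_sample="OUT")
        assert tree.find("B").sites == [10]

    def test_identical_samples_are_sisters_under_shared_branch(self):
        m = matrix_of(
            ["A", "B", "C"],
            {10: {"A": 1, "B": 1}, 20: {"A": 1, "B": 1}, 30: {"C": 1}},
        )
        tree = build_parsimony_tree(m)
        ab = tree.mrca(["A", "B"])
        assert sorted(ab.sites) == [10, 20]
        assert {c.name for c in ab.children} == {"A", "B"}

    def test_all_missing_sample_rejected(self):
        m = matrix_of(["A", "B"], {10: {"A": 1, "B": MISSING}, 20: {"B": MISSING}})
        with pytest.raises(ValueError, match="B"):
            build_parsimony_tree(m)

    def test_recovers_simulated_topology(self, clean50):
        """All resolvable truth clades recovered, no false clades (RF = 0
        after collapsing branches without mutations)."""
        tree, matrix = clean50["tree"], clean50["matrix"]
        built = build_parsimony_tree(matrix)
        with_sites = set(clean50["truth_map"].values())
        want = true_clades(tree, with_sites_only=with_sites)
        got = true_clades(built)
        assert got == want


class TestSiteAssignment:
    def test_assignments_match_simulation_truth(self, clean50):
        tree, matrix, truth = clean50["tree"], clean50["matrix"], clean50["truth_map"]
        built = build_parsimony_tree(matrix)
        sa = map_sites_to_branches(built, matrix)
        assert sa.recurrence_fraction == 0.0
        sets = {n.name: s for n, s in
                ((n, built.leaf_sets()[id(n)]) for n in built.postorder())}
        truth_sets = tree.leaf_sets()
        truth_clade = {n.name: truth_sets[id(n)] for n in tree.postorder()}
        rng = np.random.default_rng(1)
        for j in rng.choice(matrix.n_sites, size=300, replace=False):
            pos = int(matrix.positions[j])
            (assigned,) = sa.branches[pos]
            assert sets[assigned] == truth_clade[truth[pos]]

    def test_injected_two_origin_site_counted_recurrent(self):
        m = matrix_of(
            ["A", "B", "C", "D"],
            {10: {"A": 1, "B": 1}, 20: {"C": 1, "D": 1}, 30: {"A": 1, "C": 1}},
        )
        tree = build_parsimony_tree(m)
        sa = map_sites_to_branches(tree, m)
        assert sa.recurrent == {30}
        assert len(sa.branches[30]) == 2
        assert sa.recurrence_fraction == pytest.approx(1 / 3)

    def test_recurrence_fraction_arithmetic(self, clean50):
        """k injected recurrent among m sites -> fraction exactly k/m."""
        take = clean50["matrix"]
        # append 3 two-origin sites at fresh positions
        tips = take.samples
        extra_pos = [9_400_001, 9_400_002, 9_400_003]
        cols = np.zeros((take.n_samples, 3), dtype=np.int8)
        for k in range(3):
            cols[k, k] = 1
            cols[take.n_samples - 1 - k, k] = 1
        m2 = GenotypeMatrix(
            samples=tips,
            positions=np.concatenate([take.positions, extra_pos]),
            calls=np.concatenate([take.calls, cols], axis=1),
        )
        built = build_parsimony_tree(m2)
        sa = map_sites_to_branches(built, m2)
        assert sa.n_recurrent == 3
        assert sa.recurrence_fraction == pytest.approx(3 / m2.n_sites)

    def test_wildcard_matching_prefers_smaller_clade(self):
        m = matrix_of(
            ["A", "B", "C"],
            {10: {"A": 1, "B": 1}, 20: {"C": 1}, 30: {"A": 1, "B": MISSING}},
        )
        tree = build_parsimony_tree(m)
        sa = map_sites_to_branches(tree, m)
        # site 30: carriers {A}, wildcard {B} -> smaller matching clade is tip A
        assert sa.branches[30] == ("A",)
        assert 30 not in sa.recurrent


class TestAnnotation:
    @staticmethod
    def build_annotated(sizes=(3, 1)):
        """Root with two clades of given tip counts, plus marker names."""
        n = sum(sizes)
        samples = [f"S{i}" for i in range(n)]
        sites = {}
        pos = 100
        # haplogroup-defining site on the root
        sites[50] = {s: 1 for s in samples}
        start = 0
        for size in sizes:
            group = samples[start:start + size]
            if size > 1:
                sites[pos] = {s: 1 for s in group}
            pos += 100
            start += size
        m = matrix_of(samples, sites)
        return build_parsimony_tree(m)

    def test_major_minor_letter_ranking(self):
        tree = self.build_annotated(sizes=(3, 2))
        annotate_branch_names(tree, "J1")
        sets = tree.leaf_sets()
        names = {len(sets[id(c)]): c.name for c in tree.root.children if not c.is_leaf}
        assert names[3].startswith("J1a")
        assert names[2].startswith("J1b")

    def test_suffixes_alternate_letter_number(self, clean50):
        built = build_parsimony_tree(clean50["matrix"])
        annotate_branch_names(built, "J1")
        for node in built.preorder():
            if node.is_leaf or node.parent is None:
                continue
            suffixes = parse_branch_name(node.name, "J1")
            for depth, s in enumerate(suffixes):
                if depth % 2 == 0:
                    assert s.isalpha()
                else:
                    assert s.isdigit()

    def test_marker_suffix_prefers_genotyped(self):
        tree = self.build_annotated(sizes=(3, 2))
        markers = {50: "M267", 100: "Z99", 200: "P58"}
        annotate_branch_names(tree, "J1", marker_names=markers,
                              genotyped_markers={"P58"})
        assert tree.root.name == "J1-M267"
        by_name = {n.name for n in tree.preorder()}
        assert "J1b-P58" in by_name  # genotyped marker wins on its branch
        assert "J1a-Z99" in by_name

    def test_duplicate_markers_rejected(self):
        tree = self.build_annotated()
        with pytest.raises(ValueError):
            annotate_branch_names(tree, "J1", marker_names={50: "X", 100: "X"})

    def test_names_parse_back_to_paths(self, clean50):
        """Following the parsed major/minor choices from the root reaches the
        named node."""
        built = build_parsimony_tree(clean50["matrix"])
        annotate_branch_names(built, "J1")
        sets = built.leaf_sets()

        def ranked_children(node):
            kids = [c for c in node.children if not c.is_leaf]
            return sorted(kids, key=lambda c: (-len(sets[id(c)]), min(sets[id(c)])))

        for node in built.preorder():
            if node.is_leaf or node.parent is None:
                continue
            path = parse_branch_name(node.name, "J1")
            cur = built.root
            for s in path:
                rank = (ord(s) - ord("a")) if s.isalpha() else int(s) - 1
                cur = ranked_children(cur)[rank]
            assert cur is node

    def test_unifurcation_collapse_convention(self):
        # chain root -> u -> (A, B): u has one child after a tip is pruned
        m = matrix_of(
            ["A", "B", "C"],
            {10: {"A": 1, "B": 1}, 20: {"A": 1, "B": 1}, 30: {"A": 1}},
        )
        tree = build_parsimony_tree(m)
        pruned = tree.prune_leaves(["C"])
        annotate_branch_names(pruned, "J1")
        # the sites of the collapsed chain end up on one branch
        assert sorted(pruned.root.sites) == [10, 20]


def test_lone_homoplasic_site_cannot_displace_supported_clades():
    """A single two-origin site spanning two clades loses to the clades'
    multi-site support: the clades stay, the site is flagged recurrent."""
    samples = ["A", "B", "C", "D", "E"]
    sites = {}
    for p in (10, 20, 30):            # clade {A,B}: 3 supporting sites
        sites[p] = {"A": 1, "B": 1}
    for p in (40, 50):                # clade {C,D}: 2 supporting sites
        sites[p] = {"C": 1, "D": 1}
    sites[60] = {"A": 1, "B": 1, "C": 1}  # homoplasy across both clades
    m = matrix_of(samples, sites)
    tree = build_parsimony_tree(m)
    clades = {tree.leaf_sets()[id(n)] for n in tree.postorder() if not n.is_leaf}
    assert frozenset({"A", "B"}) in clades
    assert frozenset({"C", "D"}) in clades
    assert frozenset({"A", "B", "C"}) not in clades
    sa = map_sites_to_branches(tree, m)
    assert sa.recurrent == {60}


def test_branch_counts_keyed_by_final_names(clean50):
    """Annotation renames internal nodes, so assignments computed after it
    carry the final names and their counts account for every site."""
    built = build_parsimony_tree(clean50["matrix"])
    annotate_branch_names(built, "J1")
    sa = map_sites_to_branches(built, clean50["matrix"])
    counts = sa.branch_snp_counts()
    names = {n.name for n in built.postorder()}
    assert set(counts) <= names
    assert sum(counts.values()) == clean50["matrix"].n_sites
    internal_snps = sum(v for k, v in counts.items()
                        if not built.find(k).is_leaf)
    assert internal_snps > 0


class TestRoundTrip:
    def test_newick_preserves_names_and_site_counts(self, clean50):
        built = build_parsimony_tree(clean50["matrix"])
        sa = map_sites_to_branches(built, clean50["matrix"])
        annotate_branch_names(built, "J1")
        counts = {n.name: len(n.sites) for n in built.postorder() if not n.is_leaf}
        back = Tree.from_newick(built.to_newick())
        back_names = {n.name for n in back.postorder() if not n.is_leaf}
        assert back_names == set(counts)
        assert true_clades(back) == true_clades(built)
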