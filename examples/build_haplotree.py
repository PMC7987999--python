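"""Build and annotate the haplotree from a binary genotype matrix.

On polarised Y-chromosome data the topology is determined by site
compatibility: the perfect phylogeny of the carrier sets.  Branches get
hierarchical haplogroup names (major child 'a'/'1' first) and every SNP is
assigned to the branch whose descendant tips carry it.
"""

from ychron.phylogeny import (
    annotate_branch_names,
    build_parsimony_tree,
    map_sites_to_branches,
)
from ychron.simulate import DemographyModel, drop_mutations, simulate_genealogy

tree = simulate_genealogy(40, DemographyModel.study_like(), seed=31)
matrix, site_truth = drop_mutations(tree, 6.95e-10, 9_429_728, seed=32)

built = build_parsimony_tree(matrix)
annotate_branch_names(built, haplogroup_label="J1")
assignment = map_sites_to_branches(built, matrix)

print(f"{matrix.n_sites} SNPs -> {len(built.internal_nodes())} branches")
print(f"recurrent SNPs: {assignment.n_recurrent} "
      f"({100 * assignment.recurrence_fraction:.2f}% of sites)")

sets = built.leaf_sets()
named = sorted(
    (n for n in built.postorder() if not n.is_leaf),
    key=lambda n: -len(sets[id(n)]),
)
print("\nlargest branches (name, tips, defining SNPs):")
for node in named[:8]:
    print(f"  {node.name:<12} {len(sets[id(node)]):>3} tips  {len(node.sites):>3} SNPs")
# A clean simulated matrix reproduces the generating genealogy exactly:
# zero recurrence and one defining-SNP set per true branch.
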