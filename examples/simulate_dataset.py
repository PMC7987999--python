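"""Generate a synthetic haplogroup study dataset with known ground truth.

Simulates a coalescent genealogy under the study-like demography, drops
infinite-sites SNP mutations over the callable region, walks Brownian
geography down the tree, and evolves 8-locus Y-STR haplotypes.  Writes the
standard formats (haploid VCF, BED mask, Newick tree, TSV tables) into
./scratch_example/.
"""

from pathlib import Path

from ychron.simulate import (
    DemographyModel,
    drop_mutations,
    simulate_brownian_locations,
    simulate_genealogy,
    simulate_str_haplotypes,
    tiled_mask,
)

out = Path("scratch_example")
out.mkdir(exist_ok=True)

dem = DemographyModel.study_like()
tree = simulate_genealogy(60, dem, seed=11)
span = 11_787_160  # tiled mask over this span holds 9,429,728 callable bases
mask = tiled_mask(span)
matrix, site_truth = drop_mutations(tree, mu=6.95e-10, L=span, seed=12)
locations = simulate_brownian_locations(tree, (39.0, 44.0), sigma=11.0, seed=13)
strs = simulate_str_haplotypes(tree, n_loci=8, seed=14)

matrix.to_vcf(out / "genotypes.vcf")
mask.to_bed(out / "callable.bed")
tree.write(out / "genealogy.nwk")
strs.to_csv(out / "str_haplotypes.tsv", sep="\t")
with open(out / "tip_locations.tsv", "w") as fh:
    fh.write("sample\tlat\tlon\n")
    for tip in tree.leaves():
        lat, lon = locations[tip.name]
        fh.write(f"{tip.name}\t{lat:.4f}\t{lon:.4f}\n")

print(f"tips: {tree.n_leaves}, TMRCA: {tree.root.age / 1000:.1f} kyr BP")
print(f"SNPs: {matrix.n_sites} over {mask.length:,} callable bases "
      f"({matrix.n_sites / (tree.total_branch_time() * 6.95e-10 * span):.2f}x "
      "the Poisson expectation)")
print(f"wrote VCF/BED/Newick/TSV to {out}/")
# Every SNP's carrier set equals one true branch's descendant tips, so the
# downstream tree builder can be scored against site_truth exactly.
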