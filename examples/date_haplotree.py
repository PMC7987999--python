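"""Calibrated-clock dating and skyline demography on a fixed haplotree.

Samples node ages, the clock rate and skyline Ne by MCMC: branch SNP
counts are Poisson with mean mu*L*t, the tree prior is a 5-group Bayesian
skyline, and one node carries a normal age calibration.  Prints the TMRCA
table and the Ne trajectory, and checks the growth criterion (a recent
lower HPD bound exceeding an ancient upper bound).
"""

import numpy as np

from ychron.chronology import (
    CalibrationPrior,
    clock_summary,
    combine_chains,
    detect_expansion,
    ess,
    run_dating_mcmc,
    skyline_from_trace,
    summarize_node_ages,
)
from ychron.phylogeny import annotate_branch_names, build_parsimony_tree, map_sites_to_branches
from ychron.simulate import DemographyModel, drop_mutations, simulate_genealogy

L = 9_429_728
tree = simulate_genealogy(40, DemographyModel.study_like(), seed=41)
true_tmrca = tree.root.age
matrix, _ = drop_mutations(tree, 6.95e-10, L, seed=42)

built = build_parsimony_tree(matrix)
annotate_branch_names(built, "J1")
counts = map_sites_to_branches(built, matrix).branch_snp_counts()

calibration = CalibrationPrior(built.root.name, true_tmrca, 0.10 * true_tmrca)
traces = run_dating_mcmc(built, counts, L, calibration, skyline_groups=5,
                         chains=2, iterations=150_000, thin=25, seed=43)
trace = combine_chains(traces)

ages = trace.node_ages(built.root.name)
print(f"true TMRCA {true_tmrca / 1e3:.1f} kyr; posterior median "
      f"{np.median(ages) / 1e3:.1f} kyr (ESS {ess(ages):.0f})")
print(f"clock rate: {clock_summary(trace)['mu_median']:.3g} mutations/bp/year "
      "(simulated at 6.95e-10)")

table = summarize_node_ages(trace, built)
print("\noldest branches (kyr BP):")
print((table.head(6).set_index("node") / 1e3).round(2))

traj = skyline_from_trace(trace)
print(f"\nskyline Ne: {traj.median[0]:,.0f} recent -> {traj.median[-1]:,.0f} "
      f"near the root; growth detected: {detect_expansion(traj)}")
# The study-like demography expands >10-fold after the mid-Holocene, which
# the skyline flags via the HPD-crossing criterion.
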