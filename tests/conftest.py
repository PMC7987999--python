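"""Shared fixtures: simulated datasets with known ground truth.

Everything is generated at test time from explicit seeds; nothing is read
from disk.  Session scope keeps the heavier simulations to one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from ychron.simulate import (
    ArtifactSpec,
    DemographyModel,
    drop_mutations,
    inject_qc_artifacts,
    simulate_genealogy,
    tiled_mask,
)
from ychron.qc import filter_singleton_clusters


def scaled_tree(n, ne, seed, tmrca=None):
    """Constant-Ne coalescent tree, optionally conditioned on an exact TMRCA
    by linear time rescaling."""
    tree = simulate_genealogy(n, DemographyModel.constant(ne), seed=seed)
    if tmrca is not None:
        f = tmrca / tree.root.age
        for node in tree.postorder():
            node.age *= f
    return tree


def clean_qc_inputs(n_samples, L, mu, base_seed, mask):
    """Simulated matrix free of natural rule triggers (no chance same-carrier
    singleton pairs within 50 bp), so injected artifacts are the only truth.

    Scans seeds deterministically from ``base_seed``.
    """
    for k in range(50):
        seed = base_seed + 101 * k
        tree = simulate_genealogy(n_samples, DemographyModel.constant(4000), seed=seed)
        matrix, truth_map = drop_mutations(tree, mu, L, seed=seed + 1)
        _, _, excluded = filter_singleton_clusters(matrix, mask, window=50)
        if excluded.length == 0:
            return tree, matrix, truth_map
    raise RuntimeError("no artifact-free simulation found in 50 seeds")


@pytest.fixture(scope="session")
def qc_fixture():
    """60-sample, ~5,000-site matrix with every artifact class injected."""
    L = 8_000_000
    mask = tiled_mask(L, interval=8000, gap=2000)
    tree, matrix, truth_map = clean_qc_inputs(60, L, 7e-10, base_seed=21, mask=mask)
    spec = ArtifactSpec(
        singleton_clusters=5,
        replicate_pairs=1,
        discordant_sites_per_pair=3,
        recurrent_sites=3,
        missing_blocks=2,
    )
    injected, truth = inject_qc_artifacts(matrix, spec, seed=77, tree=tree, mask=mask)
    groups = [[s, f"{s}_rep"] for s in matrix.samples if f"{s}_rep" in injected.samples]
    return {
        "tree": tree,
        "clean": matrix,
        "matrix": injected,
        "truth": truth,
        "truth_map": truth_map,
        "mask": mask,
        "L": L,
        "groups": groups,
    }


@pytest.fixture(scope="session")
def clean50():
    """Clean 50-tip dataset at study-like mutation pressure."""
    tree = scaled_tree(50, 2000, seed=7, tmrca=20_000.0)
    matrix, truth_map = drop_mutations(tree, 7e-10, 9_400_000, seed=8)
    return {"tree": tree, "matrix": matrix, "truth_map": truth_map}


@pytest.fixture(scope="session")
def study172():
    """Study-scale dataset: 172 tips under the expansion demography,
    ~4,300 SNPs — the conditions of the ancient-placement experiment."""
    dem = DemographyModel.study_like()
    tree = simulate_genealogy(172, dem, seed=1)
    matrix, truth_map = drop_mutations(tree, 6.95e-10, 9_429_728, seed=51)
    return {"tree": tree, "matrix": matrix, "truth_map": truth_map}


def branch_counts_from_truth(truth_map):
    counts = {}
    for _pos, branch in truth_map.items():
        counts[branch] = counts.get(branch, 0) + 1
    return counts


def true_clades(tree, with_sites_only=None):
    """Set of non-trivial descendant-tip sets; optionally restricted to
    branches carrying at least one mutation (the resolvable ones)."""
    sets = tree.leaf_sets()
    out = set()
    for node in tree.postorder():
        if node.is_leaf or node.parent is None:
            continue
        if with_sites_only is not None and node.name not in with_sites_only:
            continue
        out.add(sets[id(node)])
    return out
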