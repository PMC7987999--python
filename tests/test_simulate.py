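"""Generator correctness against coalescent, Poisson and Brownian oracles."""

import math

import numpy as np
import pytest

from ychron.geo import LocalProjection, haversine_km
from ychron.simulate import (
    ArtifactSpec,
    DemographyModel,
    DemographyError,
    SimulationConfig,
    degrade_sample,
    drop_mutations,
    inject_qc_artifacts,
    simulate_brownian_locations,
    simulate_genealogy,
    simulate_str_haplotypes,
    tiled_mask,
)
from ychron.trees import min_state_changes

from conftest import true_clades


class TestDemographyValidation:
    def test_rejects_nonpositive_ne(self):
        with pytest.raises(DemographyError):
            DemographyModel(epochs=[(0.0, -5.0)])

    def test_rejects_unsorted_epochs(self):
        with pytest.raises(DemographyError):
            DemographyModel(epochs=[(0.0, 100.0), (0.0, 200.0)])
        with pytest.raises(DemographyError):
            DemographyModel(epochs=[(10.0, 100.0)])

    def test_ne_lookup_backwards_in_time(self):
        dem = DemographyModel(epochs=[(0.0, 100.0), (50.0, 900.0)])
        assert dem.ne_at(0.0) == 100.0
        assert dem.ne_at(49.9) == 100.0
        assert dem.ne_at(50.0) == 900.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_samples=0)
        with pytest.raises(ValueError):
            SimulationConfig(mu=-1e-10)
        with pytest.raises(ValueError):
            SimulationConfig(root_location=(95.0, 0.0))


class TestGenealogy:
    def test_single_tip_has_no_internal_nodes(self):
        tree = simulate_genealogy(1, DemographyModel.constant(1000), seed=0)
        assert tree.n_leaves == 1
        assert tree.root.is_leaf

    def test_deterministic_given_seed(self):
        dem = DemographyModel.constant(2000)
        a = simulate_genealogy(12, dem, seed=42)
        b = simulate_genealogy(12, dem, seed=42)
        assert a.to_newick() == b.to_newick()
        assert a.to_newick() != simulate_genealogy(12, dem, seed=43).to_newick()

    def test_two_tip_tmrca_matches_analytic_mean(self):
        """E[T2] = 2*Ne generations = 2*Ne*g years."""
        ne, g, reps = 1000.0, 31.0, 10_000
        dem = DemographyModel.constant(ne, generation_time=g)
        ages = np.array(
            [simulate_genealogy(2, dem, seed=s).root.age for s in range(reps)]
        )
        expect = 2 * ne * g
        se = expect / math.sqrt(reps)  # exponential: sd = mean
        assert abs(ages.mean() - expect) < 3 * se

    def test_total_length_matches_closed_form(self):
        """E[total length] = 2*Ne*g * sum_{k=1}^{n-1} 2/k (pairs coalesce
        after 2*Ne generations on average)."""
        ne, g, n, reps = 800.0, 31.0, 10, 2000
        dem = DemographyModel.constant(ne, generation_time=g)
        totals = np.array(
            [simulate_genealogy(n, dem, seed=s).total_branch_time() for s in range(reps)]
        )
        expect = 2 * ne * g * sum(2.0 / k for k in range(1, n))
        assert abs(totals.mean() - expect) < 3 * totals.std(ddof=1) / math.sqrt(reps)

    def test_piecewise_ne_slows_ancient_coalescence(self):
        """A huge ancient Ne pushes two-tip TMRCAs past the epoch boundary."""
        dem = DemographyModel(epochs=[(0.0, 100.0), (3000.0, 1e9)])
        ages = np.array(
            [simulate_genealogy(2, dem, seed=s).root.age for s in range(400)]
        )
        recent = ages[ages < 3000.0]
        # within the first epoch the process is Exp(mean 2*100*31=6200):
        # P(T < 3000) = 38%; all others are flung deep into the huge epoch
        assert 0.25 < len(recent) / len(ages) < 0.55
        assert ages[ages >= 3000.0].min() > 3000.0


class TestMutations:
    def test_zero_rate_gives_empty_matrix(self, clean50):
        matrix, truth = drop_mutations(clean50["tree"], 0.0, 1_000_000, seed=1)
        assert matrix.n_sites == 0
        assert truth == {}

    def test_negative_rate_rejected(self, clean50):
        with pytest.raises(ValueError):
            drop_mutations(clean50["tree"], -1e-9, 1000, seed=1)

    def test_total_count_matches_poisson_mean(self):
        tree = simulate_genealogy(6, DemographyModel.constant(1500), seed=5)
        mu, L, reps = 5e-9, 1_000_000, 1000
        lam = mu * L * tree.total_branch_time()
        counts = np.array(
            [drop_mutations(tree, mu, L, seed=s)[0].n_sites for s in range(reps)]
        )
        assert abs(counts.mean() - lam) < 3 * math.sqrt(lam / reps)

    def test_infinite_sites_perfect_phylogeny(self, clean50):
        """Every site's carrier set is exactly one branch's tip set."""
        tree, matrix, truth = clean50["tree"], clean50["matrix"], clean50["truth_map"]
        sets = tree.leaf_sets()
        clade_of = {n.name: sets[id(n)] for n in tree.postorder()}
        rng = np.random.default_rng(0)
        for j in rng.choice(matrix.n_sites, size=200, replace=False):
            pos = int(matrix.positions[j])
            assert matrix.carriers(j) == clade_of[truth[pos]]

    def test_positions_unique_and_in_range(self, clean50):
        pos = clean50["matrix"].positions
        assert len(np.unique(pos)) == len(pos)
        assert pos.min() >= 1 and pos.max() <= 9_400_000


class TestBrownianGeography:
    def test_zero_sigma_pins_everyone_to_root(self):
        tree = simulate_genealogy(5, DemographyModel.constant(1000), seed=2)
        truth = simulate_brownian_locations(tree, (40.0, 45.0), 0.0, seed=3)
        for loc in truth.values():
            assert loc == pytest.approx((40.0, 45.0), abs=1e-9)

    def test_msd_matches_2_sigma2_t(self):
        """Mean squared displacement of a single branch is 2*sigma^2*t."""
        from ychron.trees import Node, Tree

        sigma, t, reps = 5.0, 400.0, 3000
        proj = LocalProjection(39.0, 44.0)
        sq = []
        for s in range(reps):
            root = Node(name="r", age=t)
            root.add_child(Node(name="tip", age=0.0))
            truth = simulate_brownian_locations(Tree(root), (39.0, 44.0), sigma, seed=s)
            x, y = proj.to_plane(*truth["tip"])
            sq.append(float(x) ** 2 + float(y) ** 2)
        sq = np.array(sq)
        expect = 2 * sigma**2 * t
        assert abs(sq.mean() - expect) < 3 * sq.std(ddof=1) / math.sqrt(reps)

    def test_two_tip_midpoint_unbiased_for_root(self):
        from ychron.trees import Node, Tree

        proj = LocalProjection(39.0, 44.0)
        mids = []
        for s in range(2000):
            root = Node(name="r", age=500.0)
            root.add_child(Node(name="A", age=0.0))
            root.add_child(Node(name="B", age=0.0))
            truth = simulate_brownian_locations(Tree(root), (39.0, 44.0), 4.0, seed=s)
            ax, ay = proj.to_plane(*truth["A"])
            bx, by = proj.to_plane(*truth["B"])
            mids.append([(float(ax) + float(bx)) / 2, (float(ay) + float(by)) / 2])
        mids = np.array(mids)
        se = mids.std(axis=0, ddof=1) / math.sqrt(len(mids))
        assert np.all(np.abs(mids.mean(axis=0)) < 3 * se)

    def test_deterministic(self):
        tree = simulate_genealogy(6, DemographyModel.constant(1000), seed=4)
        a = simulate_brownian_locations(tree, (39.0, 44.0), 8.0, seed=9)
        b = simulate_brownian_locations(tree, (39.0, 44.0), 8.0, seed=9)
        assert a == b


class TestSTR:
    def test_zero_rate_keeps_root_haplotype(self):
        tree = simulate_genealogy(6, DemographyModel.constant(1000), seed=6)
        table = simulate_str_haplotypes(tree, n_loci=8, str_rate=0.0, seed=7)
        assert (table.nunique(axis=0) == 1).all()

    def test_mutation_count_oracle(self):
        """Expected net events per locus = rate * total_time / g (Poisson)."""
        from ychron.trees import Node, Tree

        rate, g, t, reps = 0.02, 31.0, 50_000.0, 800
        # single branch, single locus: displacement variance equals the
        # expected number of mutations (steps are +-1 with equal odds)
        disps = []
        for s in range(reps):
            root = Node(name="r", age=t)
            root.add_child(Node(name="tip", age=0.0))
            table = simulate_str_haplotypes(
                Tree(root), n_loci=1, str_rate=rate, generation_time=g, seed=s,
                root_repeats={"DYS19": 30},
            )
            disps.append(table.iloc[0, 0] - 30)
        lam = rate * t / g
        var = np.var(disps, ddof=1)
        # Var(net step) = E[N] for a symmetric +-1 walk stopped at Poisson N
        assert abs(var - lam) < 4 * lam / math.sqrt(reps) * math.sqrt(2)

    def test_reflecting_floor_keeps_repeats_positive(self):
        tree = simulate_genealogy(10, DemographyModel.constant(50_000), seed=8)
        table = simulate_str_haplotypes(
            tree, n_loci=4, str_rate=0.05, seed=9,
            root_repeats={"A": 2, "B": 2, "C": 2, "D": 2},
        )
        assert (table.to_numpy() >= 1).all()
        assert table.to_numpy().dtype.kind == "i"


class TestDegrade:
    def test_all_missing_at_rate_one(self):
        geno = np.array([0, 1, 0, 1], dtype=np.int8)
        obs = degrade_sample(geno, np.arange(1, 5), 1.0, 0.0, seed=0)
        assert (obs.states == -1).all()

    def test_identity_at_zero_rates(self):
        geno = np.array([0, 1, 0, 1], dtype=np.int8)
        obs = degrade_sample(geno, np.arange(1, 5), 0.0, 0.0, seed=0)
        assert np.array_equal(obs.states, geno)

    def test_missing_fraction_binomial(self):
        n, rate = 4292, 0.8
        geno = np.zeros(n, dtype=np.int8)
        obs = degrade_sample(geno, np.arange(1, n + 1), rate, 0.0, seed=3)
        se = math.sqrt(rate * (1 - rate) / n)
        assert abs(obs.fraction_missing - rate) < 3 * se

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            degrade_sample(np.zeros(3, dtype=np.int8), np.arange(1, 4), 1.5, 0.0, seed=0)


class TestArtifacts:
    def test_empty_spec_is_identity(self, qc_fixture):
        matrix = qc_fixture["clean"]
        out, truth = inject_qc_artifacts(matrix, ArtifactSpec(), seed=1)
        assert out == matrix
        assert truth.artifacts == []

    def test_singleton_cluster_construction(self, qc_fixture):
        mask = qc_fixture["mask"]
        out, truth = inject_qc_artifacts(
            qc_fixture["clean"], ArtifactSpec(singleton_clusters=5), seed=5, mask=mask
        )
        clusters = [a for a in truth.artifacts if a.kind == "singleton_cluster"]
        assert len(clusters) == 5
        for art in clusters:
            gaps = np.diff(sorted(art.positions))
            assert (gaps <= 50).all()
            carrier = art.samples[0]
            for pos in art.positions:
                j = int(np.nonzero(out.positions == pos)[0][0])
                assert out.carriers(j) == frozenset({carrier})

    def test_recurrent_site_needs_three_origins_by_fitch(self, qc_fixture):
        tree, mask = qc_fixture["tree"], qc_fixture["mask"]
        out, truth = inject_qc_artifacts(
            qc_fixture["clean"],
            ArtifactSpec(recurrent_sites=2, recurrent_origins=3),
            seed=6, tree=tree, mask=mask,
        )
        for art in truth.artifacts:
            assert art.kind == "recurrent_site"
            j = int(np.nonzero(out.positions == art.positions[0])[0][0])
            states = {s: out.calls[i, j:j + 1] for i, s in enumerate(out.samples)}
            changes = min_state_changes(tree, states, root_state=0)[0]
            assert changes >= 3

    def test_two_origin_sites_are_labelled_without_regions(self, qc_fixture):
        tree, mask = qc_fixture["tree"], qc_fixture["mask"]
        out, truth = inject_qc_artifacts(
            qc_fixture["clean"],
            ArtifactSpec(recurrent_sites_2origin=3),
            seed=8, tree=tree, mask=mask,
        )
        arts = [a for a in truth.artifacts if a.kind == "recurrent_site_2origin"]
        assert len(arts) == 3
        for art in arts:
            assert art.region is None  # nothing for QC to excise
            j = int(np.nonzero(out.positions == art.positions[0])[0][0])
            states = {s: out.calls[i, j:j + 1] for i, s in enumerate(out.samples)}
            assert min_state_changes(tree, states, root_state=0)[0] == 2

    def test_overlap_exhaustion_raises(self, qc_fixture):
        tiny_mask = tiled_mask(40_000, interval=8000, gap=2000)
        with pytest.raises(ValueError):
            inject_qc_artifacts(
                qc_fixture["clean"], ArtifactSpec(singleton_clusters=50),
                seed=7, mask=tiny_mask,
            )

    def test_deterministic(self, qc_fixture):
        spec = ArtifactSpec(singleton_clusters=2, missing_blocks=1)
        a, _ = inject_qc_artifacts(qc_fixture["clean"], spec, seed=9,
                                   tree=qc_fixture["tree"], mask=qc_fixture["mask"])
        b, _ = inject_qc_artifacts(qc_fixture["clean"], spec, seed=9,
                                   tree=qc_fixture["tree"], mask=qc_fixture["mask"])
        assert a == b
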