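"""Region-exclusion rules: worked examples, fixtures, and pipeline laws."""

import numpy as np
import pytest

from ychron.genotypes import MISSING, GenotypeMatrix, RegionMask
from ychron.qc import (
    apply_region_mask,
    callable_length,
    filter_missingness,
    filter_recurrent_site_regions,
    filter_replicate_discordance,
    filter_singleton_clusters,
    run_qc_pipeline,
)
from ychron.trees import Node, Tree


def matrix_of(samples, sites):
    """sites: {pos: {sample: call}} with default ancestral."""
    positions = np.array(sorted(sites), dtype=np.int64)
    calls = np.zeros((len(samples), len(positions)), dtype=np.int8)
    for j, pos in enumerate(positions):
        for s, v in sites[pos].items():
            calls[samples.index(s), j] = v
    return GenotypeMatrix(samples=list(samples), positions=positions, calls=calls)


BIG = RegionMask.from_intervals([(0, 100_000)])


class TestRegionMaskFilter:
    def test_empty_mask_drops_everything(self):
        m = matrix_of(["a", "b"], {100: {"a": 1}, 200: {"b": 1}})
        out = apply_region_mask(m, RegionMask.empty())
        assert out.n_sites == 0
        assert callable_length(RegionMask.empty()) == 0

    def test_boundary_positions(self):
        # mask [(0,100)]: POS 100 inside, POS 101 outside
        m = matrix_of(["a"], {100: {"a": 1}, 101: {"a": 1}})
        out = apply_region_mask(m, RegionMask.from_intervals([(0, 100)]))
        assert out.positions.tolist() == [100]

    def test_random_sites_match_per_base_membership(self):
        rng = np.random.default_rng(3)
        pos = np.unique(rng.integers(1, 3000, size=200))
        m = GenotypeMatrix(
            samples=["a"], positions=pos,
            calls=np.ones((1, len(pos)), dtype=np.int8),
        )
        mask = RegionMask.from_intervals([(50, 400), (800, 801), (1500, 2999)])
        base = np.zeros(3001, dtype=bool)
        for s, e in mask.intervals:
            base[s:e] = True
        out = apply_region_mask(m, mask)
        expect = [int(p) for p in pos if base[p - 1]]
        assert out.positions.tolist() == expect


class TestSingletonClusters:
    def test_same_sample_run_within_window_excised(self):
        m = matrix_of(["a", "b", "c"], {100: {"a": 1}, 140: {"a": 1}, 5000: {"b": 1}})
        out, mask, excluded = filter_singleton_clusters(m, BIG)
        assert excluded.intervals.tolist() == [[49, 190]]
        assert out.positions.tolist() == [5000]
        assert mask.length == BIG.length - (190 - 49)

    def test_gap_beyond_window_kept(self):
        m = matrix_of(["a", "b"], {100: {"a": 1}, 200: {"a": 1}})
        out, _, excluded = filter_singleton_clusters(m, BIG)
        assert excluded.length == 0
        assert out.n_sites == 2

    def test_different_carriers_kept(self):
        m = matrix_of(["a", "b"], {100: {"a": 1}, 140: {"b": 1}})
        out, _, excluded = filter_singleton_clusters(m, BIG)
        assert excluded.length == 0
        assert out.n_sites == 2

    def test_any_carrier_mode_excises_mixed_run(self):
        m = matrix_of(["a", "b"], {100: {"a": 1}, 140: {"b": 1}})
        out, _, excluded = filter_singleton_clusters(m, BIG, same_carrier=False)
        assert excluded.intervals.tolist() == [[49, 190]]
        assert out.n_sites == 0

    def test_non_singletons_ignored(self):
        m = matrix_of(["a", "b", "c"], {100: {"a": 1, "b": 1}, 140: {"a": 1, "b": 1}})
        _, _, excluded = filter_singleton_clusters(m, BIG)
        assert excluded.length == 0

    def test_innocent_bystander_sites_inside_run_are_dropped(self):
        m = matrix_of(
            ["a", "b", "c"],
            {100: {"a": 1}, 120: {"b": 1, "c": 1}, 140: {"a": 1}},
        )
        out, _, excluded = filter_singleton_clusters(m, BIG)
        assert excluded.intervals.tolist() == [[49, 190]]
        assert out.n_sites == 0


class TestReplicateDiscordance:
    def test_concordant_pair_keeps_fewest_nocalls(self):
        m = matrix_of(
            ["s1", "s1b", "x"],
            {
                100: {"s1": 1, "s1b": 1},
                200: {"s1": MISSING, "s1b": 1, "x": 1},
                300: {"s1": MISSING, "s1b": 1},
            },
        )
        out, mask, excluded, kept = filter_replicate_discordance(m, BIG, [["s1", "s1b"]])
        assert kept == {"s1+s1b": "s1b"}
        assert out.samples == ["s1b", "x"]
        assert excluded.length == 0

    def test_tie_broken_by_sample_id(self):
        m = matrix_of(["b2", "a2"], {100: {"b2": 1, "a2": 1}})
        _, _, _, kept = filter_replicate_discordance(m, BIG, [["b2", "a2"]])
        assert kept == {"a2+b2": "a2"}

    def test_discordant_site_excises_containing_interval(self):
        mask = RegionMask.from_intervals([(0, 1000), (1000, 2000), (5000, 6000)])
        m = matrix_of(
            ["s1", "s1b", "x"],
            {1500: {"s1": 1, "s1b": 0, "x": 1}, 5500: {"s1": 1, "s1b": 1}},
        )
        out, new_mask, excluded, _ = filter_replicate_discordance(m, mask, [["s1", "s1b"]])
        assert excluded.intervals.tolist() == [[1000, 2000]]
        assert new_mask.length == 2000
        assert out.positions.tolist() == [5500]

    def test_three_discordances_in_distinct_intervals(self, qc_fixture):
        mask = qc_fixture["mask"]
        m = apply_region_mask(qc_fixture["matrix"], mask)
        out, _, excluded, _ = filter_replicate_discordance(m, mask, qc_fixture["groups"])
        want = qc_fixture["truth"].artifact_regions("replicate_discordance")
        assert excluded == want
        assert len(excluded) == 3
        # brute-force pairwise scan agrees
        src, rep = qc_fixture["groups"][0]
        a, b = m.column(src), m.column(rep)
        disc = (a != b) & (a != MISSING) & (b != MISSING)
        assert {int(p) for p in m.positions[disc]} == {
            p for art in qc_fixture["truth"].artifacts
            if art.kind == "replicate_discordance" for p in art.positions
        }

    def test_unknown_sample_raises(self):
        m = matrix_of(["a"], {100: {"a": 1}})
        with pytest.raises(KeyError):
            filter_replicate_discordance(m, BIG, [["a", "ghost"]])


class TestRecurrentSites:
    @staticmethod
    def tree_abcd():
        root = Node(name="root", age=3.0)
        ab = Node(name="ab", age=1.0)
        ab.add_child(Node(name="a", age=0.0))
        ab.add_child(Node(name="b", age=0.0))
        cd = Node(name="cd", age=1.0)
        cd.add_child(Node(name="c", age=0.0))
        cd.add_child(Node(name="d", age=0.0))
        root.add_child(ab)
        root.add_child(cd)
        return Tree(root)

    def test_compatible_site_retained_unflagged(self):
        m = matrix_of(["a", "b", "c", "d"], {100: {"a": 1, "b": 1}})
        out, _, excluded, flagged = filter_recurrent_site_regions(m, BIG, self.tree_abcd())
        assert out.n_sites == 1 and excluded.length == 0 and flagged == []

    def test_two_origin_site_retained_but_flagged(self):
        m = matrix_of(["a", "b", "c", "d"], {100: {"a": 1, "c": 1}})
        out, _, excluded, flagged = filter_recurrent_site_regions(m, BIG, self.tree_abcd())
        assert out.n_sites == 1 and excluded.length == 0
        assert flagged == [100]

    def test_three_origin_site_excises_interval(self):
        mask = RegionMask.from_intervals([(0, 500), (500, 99_000)])
        m = matrix_of(
            ["a", "b", "c", "d", "e"],
            {100: {"a": 1, "c": 1, "e": 1}, 700: {"a": 1, "b": 1}},
        )
        root = self.tree_abcd().root
        root.add_child(Node(name="e", age=0.0))
        out, _, excluded, _ = filter_recurrent_site_regions(m, mask, Tree(root))
        assert excluded.intervals.tolist() == [[0, 500]]
        assert out.positions.tolist() == [700]

    def test_platform_partition_limits_detection(self):
        """A 3-origin pattern split across platforms never reaches 3 changes
        within one platform, so the site survives."""
        m = matrix_of(
            ["a", "b", "c", "d", "e"],
            {100: {"a": 1, "c": 1, "e": 1}},
        )
        root = self.tree_abcd().root
        root.add_child(Node(name="e", age=0.0))
        tree = Tree(root)
        platforms = {"a": "p1", "b": "p1", "c": "p1", "d": "p2", "e": "p2"}
        out, _, excluded, _ = filter_recurrent_site_regions(
            m, BIG, tree, platform_labels=platforms
        )
        assert excluded.length == 0 and out.n_sites == 1

    def test_sample_mismatch_raises(self):
        m = matrix_of(["a", "z"], {100: {"a": 1}})
        with pytest.raises(ValueError):
            filter_recurrent_site_regions(m, BIG, self.tree_abcd())


class TestMissingness:
    def test_strict_ten_percent_rule(self):
        samples = [f"s{i}" for i in range(100)]
        sites = {
            1000: {f"s{i}": MISSING for i in range(11)},   # 11% -> dropped
            5000: {f"s{i}": MISSING for i in range(10)},   # 10% -> kept
        }
        sites[1000]["s99"] = 1
        sites[5000]["s99"] = 1
        m = matrix_of(samples, sites)
        out, _, excluded = filter_missingness(m, BIG, max_missing=0.10)
        assert out.positions.tolist() == [5000]
        assert excluded.intervals.tolist() == [[999, 1000]]

    def test_clean_matrix_untouched(self):
        m = matrix_of(["a", "b"], {100: {"a": 1}, 200: {"b": 1}})
        out, mask, excluded = filter_missingness(m, BIG)
        assert out.n_sites == 2 and excluded.length == 0 and mask == BIG

    def test_variant_free_gap_between_nearby_sites_excised(self):
        samples = [f"s{i}" for i in range(10)]
        bad = {f"s{i}": MISSING for i in range(2)}  # 20% missing
        m = matrix_of(samples, {1000: dict(bad), 1400: dict(bad)})
        out, _, excluded = filter_missingness(m, BIG)
        assert out.n_sites == 0
        assert excluded.intervals.tolist() == [[999, 1400]]

    def test_gap_with_clean_variant_between_is_kept(self):
        samples = [f"s{i}" for i in range(10)]
        bad = {f"s{i}": MISSING for i in range(2)}
        m = matrix_of(samples, {1000: dict(bad), 1200: {"s5": 1}, 1400: dict(bad)})
        out, _, excluded = filter_missingness(m, BIG)
        assert out.positions.tolist() == [1200]
        assert excluded.intervals.tolist() == [[999, 1000], [1399, 1400]]

    def test_distant_sites_not_bridged(self):
        samples = [f"s{i}" for i in range(10)]
        bad = {f"s{i}": MISSING for i in range(2)}
        m = matrix_of(samples, {1000: dict(bad), 9000: dict(bad)})
        _, _, excluded = filter_missingness(m, BIG, proximity=1000)
        assert excluded.intervals.tolist() == [[999, 1000], [8999, 9000]]


class TestPipeline:
    def test_fixture_exactness(self, qc_fixture):
        """Every labelled artifact excluded, nothing else (regions equal the
        labelled truth exactly)."""
        res = run_qc_pipeline(
            qc_fixture["matrix"], qc_fixture["mask"],
            replicate_groups=qc_fixture["groups"],
        )
        expected = qc_fixture["truth"].artifact_regions().intersect(qc_fixture["mask"])
        excluded = qc_fixture["mask"].subtract(res.mask)
        assert excluded == expected
        injected = [p for a in qc_fixture["truth"].artifacts for p in a.positions]
        assert not np.isin(res.matrix.positions, injected).any()

    def test_callable_length_matches_per_base_oracle(self, qc_fixture):
        res = run_qc_pipeline(
            qc_fixture["matrix"], qc_fixture["mask"],
            replicate_groups=qc_fixture["groups"],
        )
        base = np.zeros(qc_fixture["L"], dtype=bool)
        for s, e in qc_fixture["mask"].intervals:
            base[s:e] = True
        for rule_mask in res.report.excluded_regions.values():
            for s, e in rule_mask.intervals:
                base[s:e] = False
        assert res.mask.length == int(base.sum())

    def test_idempotent(self, qc_fixture):
        first = run_qc_pipeline(
            qc_fixture["matrix"], qc_fixture["mask"],
            replicate_groups=qc_fixture["groups"],
        )
        second = run_qc_pipeline(
            first.matrix, first.mask, replicate_groups=qc_fixture["groups"]
        )
        assert second.matrix == first.matrix
        assert second.mask == first.mask

    def test_mask_monotone_and_attribution_sums(self, qc_fixture):
        res = run_qc_pipeline(
            qc_fixture["matrix"], qc_fixture["mask"],
            replicate_groups=qc_fixture["groups"],
        )
        assert res.report.callable_after <= res.report.callable_before
        assert (
            res.report.sites_before - sum(res.report.sites_excluded.values())
            == res.report.sites_after
        )

    def test_report_serialises(self, qc_fixture, tmp_path):
        res = run_qc_pipeline(
            qc_fixture["matrix"], qc_fixture["mask"],
            replicate_groups=qc_fixture["groups"],
        )
        out = tmp_path / "report.json"
        res.report.to_json(out)
        assert out.exists() and "callable_after" in out.read_text()
        assert "sites" in res.report.summary()
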