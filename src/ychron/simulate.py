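"""Synthetic-data generator with known ground truth.

Emulates the data structure of a high-coverage Y-chromosome haplogroup
study: a Kingman coalescent genealogy under piecewise-constant Ne, Poisson
SNP mutations over a callable region (infinite-sites), Brownian tip
geography, stepwise-mutation Y-STR haplotypes, degraded low-coverage
(ancient) samples, and injectable QC artifacts (singleton clusters,
replicate discordances, recurrent sites, missing blocks).

Every stochastic operation takes one explicit integer seed and is
deterministic given it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, RegionMask
from .geo import LocalProjection
from .trees import Node, Tree, min_state_changes

__all__ = [
    "DemographyModel",
    "SimulationConfig",
    "ArtifactSpec",
    "ArtifactRecord",
    "TruthRecord",
    "DemographyError",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_brownian_locations",
    "simulate_str_haplotypes",
    "degrade_sample",
    "inject_qc_artifacts",
    "tiled_mask",
    "STR_LOCI",
    "DEFAULT_ROOT_REPEATS",
]

# the 8 Y-STR loci used for gene-diversity estimates, with typical modal
# repeat counts as the simulated root haplotype
STR_LOCI = ("DYS19", "DYS389I", "DYS389II", "DYS390",
            "DYS391", "DYS392", "DYS393", "DYS439")
DEFAULT_ROOT_REPEATS = {
    "DYS19": 14, "DYS389I": 13, "DYS389II": 29, "DYS390": 23,
    "DYS391": 10, "DYS392": 11, "DYS393": 12, "DYS439": 11,
}


class DemographyError(ValueError):
    pass


@dataclass
class DemographyModel:
    """Piecewise-constant male effective population size.

    ``epochs`` lists (start_time_years_bp, Ne) with start times strictly
    increasing from 0; each Ne applies from its start time backwards until
    the next epoch.  ``generation_time`` converts coalescent generations to
    years (human male default 31 years).
    """

    epochs: list[tuple[float, float]] = field(default_factory=lambda: [(0.0, 5000.0)])
    generation_time: float = 31.0

    def __post_init__(self):
        if not self.epochs:
            raise DemographyError("at least one epoch required")
        starts = [t for t, _ in self.epochs]
        if starts[0] != 0:
            raise DemographyError("first epoch must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise DemographyError("epoch start times must be strictly increasing")
        if any(ne <= 0 for _, ne in self.epochs):
            raise DemographyError("all Ne must be positive")
        if self.generation_time <= 0:
            raise DemographyError("generation_time must be positive")

    def ne_at(self, t: float) -> float:
        ne = self.epochs[0][1]
        for start, n in self.epochs:
            if t >= start:
                ne = n
            else:
                break
        return ne

    @classmethod
    def constant(cls, ne: float, generation_time: float = 31.0) -> "DemographyModel":
        return cls(epochs=[(0.0, float(ne))], generation_time=generation_time)

    @classmethod
    def study_like(cls) -> "DemographyModel":
        """Piecewise stand-in for the inferred haplogroup history: a small
        constant Ne through the Pleistocene and early Holocene, strong
        growth through the Chalcolithic/Bronze/Iron Ages, and a recent
        plateau.  With 172 samples this yields trees with TMRCA ~ 20 kyr,
        ~ 4,500 SNPs at the default mutation rate and callable length, and
        internal nodes spread over the whole depth of the tree (as in the
        dated haplogroup branches)."""
        return cls(epochs=[(0.0, 12_000.0), (1_500.0, 2_500.0),
                           (6_000.0, 500.0), (12_000.0, 120.0)])


@dataclass
class SimulationConfig:
    """Study-scale defaults: 172 sequenced chromosomes, a ~9.4 Mb callable
    region, and a clock of ~7e-10 mutations/bp/year."""

    n_samples: int = 172
    mu: float = 6.95e-10           # mutations / bp / year
    L: int = 9_429_728             # callable bases
    seed: int = 0
    root_location: tuple[float, float] = (39.0, 44.0)  # (lat, lon) degrees
    sigma: float = 11.0            # km / sqrt(year) Brownian dispersal
    str_loci: int = 8
    str_rate: float = 2.0e-3       # mutations / locus / generation

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.L <= 0:
            raise ValueError("L must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        lat, lon = self.root_location
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError("root_location out of range")


@dataclass
class ArtifactRecord:
    """One injected QC artifact with its class label and footprint."""

    kind: str                      # singleton_cluster | replicate_discordance |
                                   # recurrent_site | missing_block
    region: tuple[int, int] | None  # expected excised region, 0-based half-open
    positions: tuple[int, ...] = ()
    samples: tuple[str, ...] = ()
    branches: tuple[str, ...] = ()


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset."""

    node_ages: dict[str, float] = field(default_factory=dict)
    site_to_branch: dict[int, str] = field(default_factory=dict)
    node_locations: dict[str, tuple[float, float]] = field(default_factory=dict)
    artifacts: list[ArtifactRecord] = field(default_factory=list)

    def artifact_regions(self, kind: str | None = None) -> RegionMask:
        regions = [
            a.region for a in self.artifacts
            if a.region is not None and (kind is None or a.kind == kind)
        ]
        return RegionMask.from_intervals(regions, merge=True)

    def to_json(self, path=None) -> str:
        import json

        payload = {
            "node_ages": self.node_ages,
            "site_to_branch": {str(k): v for k, v in self.site_to_branch.items()},
            "node_locations": {k: list(v) for k, v in self.node_locations.items()},
            "artifacts": [
                {"kind": a.kind, "region": list(a.region) if a.region else None,
                 "positions": list(a.positions), "samples": list(a.samples),
                 "branches": list(a.branches)}
                for a in self.artifacts
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# ---------------------------------------------------------------- genealogy
def simulate_genealogy(
    n_samples: int,
    demography: DemographyModel,
    seed: int,
    tip_prefix: str = "S",
) -> Tree:
    """Kingman coalescent genealogy with piecewise-constant Ne, ages in years.

    While k lineages survive at time t, coalescences occur at rate
    C(k,2) / (2 * Ne(t) * g) per year, so a pair coalesces after 2*Ne
    generations on average (the convention under which skyline Ne values
    are reported).  Epoch boundaries are handled by restarting the
    exponential clock (memorylessness).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_samples - 1)))
    lineages = [Node(name=f"{tip_prefix}{i:0{width}d}", age=0.0) for i in range(n_samples)]
    g = demography.generation_time
    starts = [t for t, _ in demography.epochs] + [math.inf]
    nes = [ne for _, ne in demography.epochs]

    t = 0.0
    epoch = 0
    coal_count = 0
    while len(lineages) > 1:
        while epoch + 1 < len(nes) + 0 and starts[epoch + 1] <= t:
            epoch += 1
        k = len(lineages)
        rate = k * (k - 1) / 2.0 / (2.0 * nes[epoch] * g)
        wait = rng.exponential(1.0 / rate)
        boundary = starts[epoch + 1]
        if t + wait >= boundary:
            t = boundary
            epoch += 1
            continue
        t += wait
        i, j = sorted(rng.choice(k, size=2, replace=False))
        coal_count += 1
        parent = Node(name=f"anc{coal_count}", age=t)
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        lineages[j:j + 1] = []
        lineages[i] = parent
    return Tree(lineages[0])


# ---------------------------------------------------------------- mutations
def _sample_unique_positions(rng: np.random.Generator, L: int, k: int) -> np.ndarray:
    """k distinct 1-based positions uniform on [1, L]."""
    if k > L:
        raise ValueError("more mutations than available positions")
    if k > L // 4:
        return rng.permutation(L)[:k] + 1
    seen: set[int] = set()
    out = np.empty(k, dtype=np.int64)
    n = 0
    while n < k:
        draw = rng.integers(1, L + 1, size=2 * (k - n))
        for p in draw:
            p = int(p)
            if p not in seen:
                seen.add(p)
                out[n] = p
                n += 1
                if n == k:
                    break
    return out


def drop_mutations(
    tree: Tree, mu: float, L: int, seed: int
) -> tuple[GenotypeMatrix, dict[int, str]]:
    """Poisson mutations on branches under the infinite-sites model.

    Each branch b of duration t_b receives Poisson(mu * L * t_b) mutations;
    every mutation gets a unique position in [1, L] and its derived allele is
    carried by exactly the tip descendants of the branch.  Returns the
    matrix and the position -> branch (child-node name) truth map.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    rng = np.random.default_rng(seed)
    branches = tree.branches()
    durations = np.array([b.branch_length for b in branches])
    counts = rng.poisson(mu * L * durations) if len(branches) else np.array([], dtype=int)
    total = int(counts.sum())
    positions = _sample_unique_positions(rng, L, total)

    tips = tree.leaf_names()
    tip_idx = {s: i for i, s in enumerate(tips)}
    leaf_sets = tree.leaf_sets()
    calls = np.zeros((len(tips), total), dtype=np.int8)
    truth: dict[int, str] = {}
    cursor = 0
    for b, c in zip(branches, counts):
        if c == 0:
            continue
        rows = [tip_idx[s] for s in leaf_sets[id(b)]]
        for p in positions[cursor:cursor + c]:
            truth[int(p)] = b.name
        calls[np.ix_(rows, np.arange(cursor, cursor + c))] = 1
        cursor += c
    matrix = GenotypeMatrix(samples=tips, positions=positions, calls=calls)
    return matrix, truth


# ---------------------------------------------------------------- geography
def simulate_brownian_locations(
    tree: Tree,
    root_location: tuple[float, float],
    sigma: float,
    seed: int,
) -> dict[str, tuple[float, float]]:
    """Brownian random walk over the tree in a local km plane.

    Child location = parent location + N(0, sigma^2 * t_b) per axis, in an
    azimuthal-equirectangular plane centred on the root location, converted
    back to (lat, lon) degrees.  Locations are attached to the tree nodes
    and returned as a name -> (lat, lon) map for all nodes.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    proj = LocalProjection(*root_location)
    plane: dict[int, np.ndarray] = {id(tree.root): np.zeros(2)}
    truth: dict[str, tuple[float, float]] = {}
    for node in tree.preorder():
        if node.parent is not None:
            step = rng.normal(0.0, sigma * math.sqrt(max(node.branch_length, 0.0)), size=2)
            plane[id(node)] = plane[id(node.parent)] + step
        x, y = plane[id(node)]
        lat, lon = proj.to_latlon(x, y)
        node.location = (float(lat), float(lon))
        truth[node.name] = node.location
    return truth


# ---------------------------------------------------------------- STRs
def simulate_str_haplotypes(
    tree: Tree,
    n_loci: int = 8,
    str_rate: float = 2.0e-3,
    generation_time: float = 31.0,
    seed: int = 0,
    root_repeats: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Stepwise-mutation STR haplotypes for the tree tips.

    Each locus mutates +-1 repeat at ``str_rate`` per generation along each
    branch, reflecting at a floor of 1 repeat.  Returns a tips x loci
    DataFrame of integer repeat counts.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    if root_repeats is None:
        loci = list(STR_LOCI[:n_loci]) + [f"STR{i}" for i in range(len(STR_LOCI), n_loci)]
        root = np.array([DEFAULT_ROOT_REPEATS.get(l, 12) for l in loci], dtype=np.int64)
    else:
        loci = list(root_repeats)[:n_loci]
        root = np.array([root_repeats[l] for l in loci], dtype=np.int64)

    state: dict[int, np.ndarray] = {id(tree.root): root.copy()}
    rows, names = [], []
    for node in tree.preorder():
        if node.parent is not None:
            h = state[id(node.parent)].copy()
            n_mut = rng.poisson(str_rate * node.branch_length / generation_time, size=n_loci)
            for locus in range(n_loci):
                for _ in range(int(n_mut[locus])):
                    step = 1 if rng.random() < 0.5 else -1
                    h[locus] = h[locus] + step
                    if h[locus] < 1:  # reflecting floor: repeat counts stay >= 1
                        h[locus] = 2 - h[locus]
            state[id(node)] = h
        if node.is_leaf:
            names.append(node.name)
            rows.append(state[id(node)])
    return pd.DataFrame(rows, index=names, columns=loci)


# ---------------------------------------------------------------- degradation
def degrade_sample(
    genotypes: np.ndarray,
    positions: np.ndarray,
    missing_rate: float,
    error_rate: float,
    seed: int,
    source_sample: str | None = None,
    truth_branch: str | None = None,
):
    """Degrade one sample's calls into a low-coverage ancient observation.

    Each site independently becomes missing with ``missing_rate``; surviving
    sites flip state (symmetrically) with ``error_rate``.
    """
    from .placement import AncientObservation

    if not (0.0 <= missing_rate <= 1.0 and 0.0 <= error_rate <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    states = np.asarray(genotypes, dtype=np.int8).copy()
    miss = rng.random(states.shape) < missing_rate
    flip = rng.random(states.shape) < error_rate
    states[(~miss) & flip & (states >= 0)] ^= 1
    states[miss] = MISSING
    return AncientObservation(
        positions=np.asarray(positions, dtype=np.int64).copy(),
        states=states,
        source_sample=source_sample,
        truth_branch=truth_branch,
    )


# ---------------------------------------------------------------- QC artifacts
@dataclass
class ArtifactSpec:
    """How many artifacts of each class to inject."""

    singleton_clusters: int = 0
    cluster_size: int = 2
    cluster_gap: int = 30          # bp between consecutive cluster singletons (<= 50)
    replicate_pairs: int = 0
    discordant_sites_per_pair: int = 3
    replicate_extra_missing: int = 5
    recurrent_sites: int = 0
    recurrent_origins: int = 3
    recurrent_sites_2origin: int = 0  # retained + flagged, not excised
    missing_blocks: int = 0
    block_sites: int = 2
    block_gap: int = 400           # bp between consecutive high-missing sites
    block_missing_count: int | None = None  # default: >10% of samples

    @property
    def empty(self) -> bool:
        return not (self.singleton_clusters or self.replicate_pairs
                    or self.recurrent_sites or self.recurrent_sites_2origin
                    or self.missing_blocks)


class _PositionAllocator:
    """Places artifact footprints in mask intervals, one artifact per
    interval, away from existing sites; raises if injections would overlap."""

    def __init__(self, mask: RegionMask, existing_positions: np.ndarray,
                 rng: np.random.Generator, margin: int = 120):
        self.mask = mask
        self.existing = np.sort(np.asarray(existing_positions, dtype=np.int64))
        self.rng = rng
        self.margin = margin
        self.used_intervals: set[int] = set()

    def _sites_in(self, lo: int, hi: int) -> int:
        """Existing 1-based sites with lo <= pos <= hi."""
        a = np.searchsorted(self.existing, lo, side="left")
        b = np.searchsorted(self.existing, hi, side="right")
        return b - a

    def claim_span(self, span: int, clean: bool = True) -> tuple[int, int]:
        """Reserve a span of `span` bp inside an unused mask interval.

        Returns (interval_index, first_position) with the whole footprint +
        margins inside the interval; ``clean`` additionally requires no
        pre-existing site within the margins.
        """
        order = self.rng.permutation(len(self.mask.intervals))
        for ii in order:
            if int(ii) in self.used_intervals:
                continue
            s, e = self.mask.intervals[ii]
            lo = int(s) + 1 + self.margin       # 1-based first usable POS
            hi = int(e) - self.margin - span
            if hi < lo:
                continue
            for _ in range(25):
                p0 = int(self.rng.integers(lo, hi + 1))
                if not clean or self._sites_in(p0 - self.margin, p0 + span + self.margin) == 0:
                    self.used_intervals.add(int(ii))
                    return int(ii), p0
        raise ValueError("could not place artifact without overlap; "
                         "reduce the artifact count or enlarge the mask")

    def claim_interval_with_site(self, positions_ok: np.ndarray) -> tuple[int, int]:
        """Reserve an unused interval that contains one of the given existing
        1-based positions; returns (interval_index, position)."""
        order = self.rng.permutation(len(positions_ok))
        for pi in order:
            pos = int(positions_ok[pi])
            idx = np.searchsorted(self.mask.intervals[:, 0], pos - 1, side="right") - 1
            if idx < 0 or pos - 1 >= self.mask.intervals[idx, 1]:
                continue
            if int(idx) in self.used_intervals:
                continue
            self.used_intervals.add(int(idx))
            return int(idx), pos
        raise ValueError("no free mask interval contains a usable site for injection")


def tiled_mask(L: int, interval: int = 8000, gap: int = 2000) -> RegionMask:
    """A callable mask tiling [0, L) into fixed-size intervals with gaps,
    mimicking the patchy reachable fraction of the Y chromosome."""
    starts = np.arange(0, L, interval + gap, dtype=np.int64)
    ends = np.minimum(starts + interval, L)
    keep = ends > starts
    return RegionMask(np.stack([starts[keep], ends[keep]], axis=1))


def inject_qc_artifacts(
    matrix: GenotypeMatrix,
    artifact_spec: ArtifactSpec,
    seed: int,
    tree: Tree | None = None,
    mask: RegionMask | None = None,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Inject labelled QC artifacts into a clean matrix.

    Each artifact occupies its own callable-mask interval so the truth is
    unambiguous; attempting to place more artifacts than there are free
    intervals raises.  Returns the modified matrix and a TruthRecord whose
    ``artifacts`` list carries one labelled entry (with the region a correct
    QC pipeline should excise) per injection.
    """
    truth = TruthRecord()
    if artifact_spec.empty:
        return matrix, truth
    if mask is None:
        raise ValueError("a callable-region mask is required to place artifacts")
    if (artifact_spec.recurrent_sites or artifact_spec.missing_blocks) and tree is None:
        raise ValueError("recurrent-site and missing-block injection require the truth tree")

    rng = np.random.default_rng(seed)
    alloc = _PositionAllocator(mask, matrix.positions, rng)
    samples = list(matrix.samples)
    n = len(samples)
    calls = matrix.calls.copy()
    new_positions: list[int] = []
    new_cols: list[np.ndarray] = []   # columns over the ORIGINAL samples
    leaf_sets = tree.leaf_sets() if tree is not None else None
    clades: list[tuple[str, frozenset]] = []
    if tree is not None:
        clades = [
            (node.name, leaf_sets[id(node)])
            for node in tree.postorder()
            if node.parent is not None
        ]

    # --- singleton clusters -------------------------------------------------
    window = 50
    cluster_samples = rng.choice(n, size=max(artifact_spec.singleton_clusters, 0),
                                 replace=artifact_spec.singleton_clusters > n)
    for ci in range(artifact_spec.singleton_clusters):
        k = artifact_spec.cluster_size
        span = (k - 1) * artifact_spec.cluster_gap
        _, p0 = alloc.claim_span(span + 2 * window)
        pos = [p0 + window + i * artifact_spec.cluster_gap for i in range(k)]
        si = int(cluster_samples[ci])
        for p in pos:
            col = np.zeros(n, dtype=np.int8)
            col[si] = 1
            new_positions.append(p)
            new_cols.append(col)
        region = (pos[0] - 1 - window, pos[-1] + window)
        truth.artifacts.append(ArtifactRecord(
            kind="singleton_cluster", region=region, positions=tuple(pos),
            samples=(samples[si],),
        ))

    # --- recurrent sites ----------------------------------------------------
    # >= 3 origins: the QC rule must excise the containing interval;
    # exactly 2 origins: retained but flagged, emulating the residual
    # recurrent-SNP fraction of a QC'd call set (region=None: nothing to excise)
    recurrent_plan = (
        [(artifact_spec.recurrent_origins, "recurrent_site", True)]
        * artifact_spec.recurrent_sites
        + [(2, "recurrent_site_2origin", False)]
        * artifact_spec.recurrent_sites_2origin
    )
    for origins, kind, excised in recurrent_plan:
        carriers = None
        chosen: list[tuple[str, frozenset]] = []
        for _attempt in range(200):
            picks = rng.choice(len(clades), size=origins, replace=False)
            cand = [clades[i] for i in picks]
            sets = [c[1] for c in cand]
            union: set = set()
            ok = True
            for s in sets:
                if union & s:
                    ok = False
                    break
                union |= s
            if not ok or len(union) >= n:
                continue
            if any(union == c[1] for c in clades):
                continue  # union coincides with a real clade: not recurrent
            carriers, chosen = union, cand
            break
        if carriers is None:
            raise ValueError("could not find disjoint clades for a recurrent site")
        _, p = alloc.claim_span(1, clean=False)
        col = np.zeros(n, dtype=np.int8)
        col[[matrix.sample_index(s) for s in carriers]] = 1
        new_positions.append(p)
        new_cols.append(col)
        iv = mask.interval_containing(p) if excised else None
        truth.artifacts.append(ArtifactRecord(
            kind=kind, region=iv, positions=(p,),
            branches=tuple(c[0] for c in chosen),
        ))

    # --- missing blocks -----------------------------------------------------
    n_missing = artifact_spec.block_missing_count
    if n_missing is None:
        n_missing = int(math.floor(0.10 * n)) + 1
        if n_missing / n <= 0.10:
            n_missing += 1
    big_clades = [c for c in clades if 3 <= len(c[1]) <= max(3, n // 2)]
    for _ in range(artifact_spec.missing_blocks):
        k = artifact_spec.block_sites
        span = (k - 1) * artifact_spec.block_gap
        _, p0 = alloc.claim_span(span + 2 * alloc.margin)
        pos = [p0 + i * artifact_spec.block_gap for i in range(k)]
        for p in pos:
            name, clade = big_clades[int(rng.integers(len(big_clades)))]
            col = np.zeros(n, dtype=np.int8)
            col[[matrix.sample_index(s) for s in clade]] = 1
            miss_rows = rng.choice(n, size=n_missing, replace=False)
            col[miss_rows] = MISSING
            new_positions.append(p)
            new_cols.append(col)
        region = (pos[0] - 1, pos[-1])
        truth.artifacts.append(ArtifactRecord(
            kind="missing_block", region=region, positions=tuple(pos),
        ))

    # assemble matrix with new sites, original samples
    if new_positions:
        add = np.stack(new_cols, axis=1)
        calls = np.concatenate([calls, add], axis=1)
        positions = np.concatenate([matrix.positions, np.asarray(new_positions, dtype=np.int64)])
    else:
        positions = matrix.positions.copy()
    out = GenotypeMatrix(samples=samples, positions=positions, calls=calls,
                         platforms=dict(matrix.platforms))

    # --- replicate pairs (adds columns) -------------------------------------
    used_as_source = set(s for a in truth.artifacts for s in a.samples)
    candidates = [s for s in samples if s not in used_as_source] or samples
    for _ in range(artifact_spec.replicate_pairs):
        src = candidates[int(rng.integers(len(candidates)))]
        candidates = [s for s in candidates if s != src] or candidates
        rep_name = f"{src}_rep"
        col = out.column(src).copy()
        # discordances at existing sites where the source call is non-missing,
        # each in its own free mask interval
        obs = np.nonzero(col >= 0)[0]
        disc_pos = []
        regions = []
        for _d in range(artifact_spec.discordant_sites_per_pair):
            pool = out.positions[obs]
            ii, p = alloc.claim_interval_with_site(pool)
            j = int(np.nonzero(out.positions == p)[0][0])
            col[j] ^= 1
            disc_pos.append(p)
            regions.append(tuple(int(v) for v in mask.intervals[ii]))
            obs = obs[out.positions[obs] != p]
        # extra no-calls so the original column is the one retained (never at
        # the injected discordances, which must stay visible)
        eligible = np.nonzero(~np.isin(out.positions, disc_pos))[0]
        extra = rng.choice(eligible, size=artifact_spec.replicate_extra_missing,
                           replace=False)
        col[extra] = MISSING
        out = GenotypeMatrix(
            samples=out.samples + [rep_name],
            positions=out.positions,
            calls=np.vstack([out.calls, col[None, :]]),
            platforms={**out.platforms, rep_name: out.platforms.get(src, "")},
        )
        for p, reg in zip(disc_pos, regions):
            truth.artifacts.append(ArtifactRecord(
                kind="replicate_discordance", region=reg, positions=(p,),
                samples=(src, rep_name),
            ))
    return out, truth
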