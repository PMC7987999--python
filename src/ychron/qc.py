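"""Region-exclusion QC for a raw multi-sample haploid call set.

Four exclusion rules turn the raw matrix into the high-quality analysis
matrix, in a fixed pipeline order:

1. callable-region mask (the "re-mapping filter"),
2. replicate / paternal-relative discordance regions (one column kept per
   group, the one with fewest no-calls),
3. same-carrier singleton clusters (>= 2 singletons of one sample within
   50 bp, the run excised with a 50 bp flank),
4. recurrent-SNP regions (sites needing >= 3 independent origins on the
   preliminary tree within a single sequencing platform),
5. high-missingness sites (> 10% no-calls, strict) plus variant-free gaps
   between nearby such sites.

All excisions are mask arithmetic: the callable mask shrinks monotonically
and the surviving matrix contains exactly the sites inside the final mask.
A site excluded by several rules is attributed to the first rule in
pipeline order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, RegionMask
from .trees import Tree, min_state_changes

__all__ = [
    "FilterReport",
    "QCResult",
    "apply_region_mask",
    "filter_singleton_clusters",
    "filter_replicate_discordance",
    "filter_recurrent_site_regions",
    "filter_missingness",
    "callable_length",
    "run_qc_pipeline",
]

RULE_ORDER = ("region_mask", "replicate_discordance", "singleton_cluster",
              "recurrent_site", "missingness")


@dataclass
class FilterReport:
    callable_before: int = 0
    callable_after: int = 0
    sites_before: int = 0
    sites_after: int = 0
    excluded_regions: dict[str, RegionMask] = field(default_factory=dict)
    sites_excluded: dict[str, int] = field(default_factory=dict)
    replicate_kept: dict[str, str] = field(default_factory=dict)  # group label -> kept sample
    recurrent_flagged: list[int] = field(default_factory=list)    # retained 2-origin sites

    def to_json(self, path=None) -> str:
        payload = {
            "callable_before": self.callable_before,
            "callable_after": self.callable_after,
            "sites_before": self.sites_before,
            "sites_after": self.sites_after,
            "sites_excluded": self.sites_excluded,
            "excluded_regions": {
                rule: mask.intervals.tolist() for rule, mask in self.excluded_regions.items()
            },
            "replicate_kept": self.replicate_kept,
            "recurrent_flagged": [int(p) for p in self.recurrent_flagged],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def summary(self) -> str:
        lines = [
            f"callable bases: {self.callable_before:,} -> {self.callable_after:,}",
            f"sites: {self.sites_before:,} -> {self.sites_after:,}",
        ]
        for rule in RULE_ORDER:
            if rule in self.sites_excluded:
                n_reg = len(self.excluded_regions.get(rule, RegionMask.empty()))
                lines.append(
                    f"  {rule}: {self.sites_excluded[rule]} sites, {n_reg} regions excluded"
                )
        if self.replicate_kept:
            for grp, kept in self.replicate_kept.items():
                lines.append(f"  replicate group {grp}: kept {kept}")
        if self.recurrent_flagged:
            lines.append(f"  flagged (2-origin, retained): {len(self.recurrent_flagged)} sites")
        return "\n".join(lines)


@dataclass
class QCResult:
    matrix: GenotypeMatrix
    mask: RegionMask
    report: FilterReport


def callable_length(mask: RegionMask) -> int:
    """Total callable bases of a mask."""
    return mask.length


def apply_region_mask(matrix: GenotypeMatrix, mask: RegionMask) -> GenotypeMatrix:
    """Retain exactly the sites whose 1-based POS lies inside the 0-based
    half-open mask (POS p covers base p-1)."""
    inside = mask.contains_positions(matrix.positions)
    return matrix.take_sites(inside)


def _drop_sites_in_regions(matrix: GenotypeMatrix, regions: RegionMask) -> GenotypeMatrix:
    if not len(regions.intervals):
        return matrix
    inside = regions.contains_positions(matrix.positions)
    return matrix.take_sites(~inside)


def filter_singleton_clusters(
    matrix: GenotypeMatrix,
    mask: RegionMask,
    window: int = 50,
    same_carrier: bool = True,
) -> tuple[GenotypeMatrix, RegionMask, RegionMask]:
    """Excise runs of >= 2 singletons within ``window`` bp of each other.

    A singleton is a site whose derived allele occurs in exactly one sample.
    By default only runs carried by the same sample count (terminal-branch
    artifact signature); ``same_carrier=False`` switches to any-carrier
    mode.  The excised region spans the run extended by ``window`` bp on
    each side.  Returns (matrix, mask, excluded_regions).
    """
    derived = matrix.derived_counts()
    is_singleton = derived == 1
    carrier = np.where(is_singleton, (matrix.calls == 1).argmax(axis=0), -1)

    regions: list[tuple[int, int]] = []
    sing_idx = np.nonzero(is_singleton)[0]
    if same_carrier:
        groups = [sing_idx[carrier[sing_idx] == c] for c in np.unique(carrier[sing_idx])]
    else:
        groups = [sing_idx]
    for idx in groups:
        pos = matrix.positions[idx]
        if len(pos) < 2:
            continue
        run_start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > window:
                if i - run_start >= 2:
                    first, last = int(pos[run_start]), int(pos[i - 1])
                    regions.append((max(0, first - 1 - window), last + window))
                run_start = i
    excluded = RegionMask.from_intervals(regions, merge=True)
    return _drop_sites_in_regions(matrix, excluded), mask.subtract(excluded), excluded


def filter_replicate_discordance(
    matrix: GenotypeMatrix,
    mask: RegionMask,
    replicate_groups,
) -> tuple[GenotypeMatrix, RegionMask, RegionMask, dict[str, str]]:
    """Excise callable intervals containing replicate-discordant calls and
    keep one column per replicate group.

    ``replicate_groups`` lists groups of sample names known to be the same
    individual resequenced, or paternal relatives.  Any site where two group
    members have different non-missing calls marks its containing callable
    interval for exclusion.  From each group the column with the fewest
    no-calls is retained (ties broken by sample ID).  Unknown sample names
    raise KeyError.
    """
    for group in replicate_groups:
        for s in group:
            matrix.sample_index(s)  # raises on unknown

    discordant_pos: set[int] = set()
    kept: dict[str, str] = {}
    drop_cols: list[str] = []
    for group in replicate_groups:
        cols = {s: matrix.column(s) for s in group}
        names = list(group)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = cols[names[i]], cols[names[j]]
                diff = (a != b) & (a != MISSING) & (b != MISSING)
                discordant_pos.update(int(p) for p in matrix.positions[diff])
        no_calls = {s: int((cols[s] == MISSING).sum()) for s in names}
        keeper = min(names, key=lambda s: (no_calls[s], s))
        kept["+".join(sorted(names))] = keeper
        drop_cols.extend(s for s in names if s != keeper)

    regions = []
    for p in sorted(discordant_pos):
        iv = mask.interval_containing(p)
        if iv is not None:
            regions.append(iv)
    excluded = RegionMask.from_intervals(regions, merge=True)
    out = matrix.drop_samples(drop_cols)
    out = _drop_sites_in_regions(out, excluded)
    return out, mask.subtract(excluded), excluded, kept


def filter_recurrent_site_regions(
    matrix: GenotypeMatrix,
    mask: RegionMask,
    prelim_tree: Tree,
    min_branches: int = 3,
    platform_labels: dict[str, str] | None = None,
) -> tuple[GenotypeMatrix, RegionMask, RegionMask, list[int]]:
    """Excise callable intervals containing SNPs that require >= 3
    independent origins on the preliminary tree within one platform.

    Per platform subset of samples, each site's minimum number of state
    changes on the (pruned) tree is computed by small parsimony with the
    root held ancestral.  Sites needing >= ``min_branches`` changes in any
    platform mark their containing interval; sites needing exactly 2 are
    retained but flagged.  Returns (matrix, mask, excluded, flagged_positions).
    """
    tips = set(prelim_tree.leaf_names())
    missing = [s for s in matrix.samples if s not in tips]
    if missing:
        raise ValueError(f"samples absent from the preliminary tree: {missing}")

    if platform_labels is None:
        platform_labels = {s: matrix.platforms.get(s, "") for s in matrix.samples}
    platforms: dict[str, list[str]] = {}
    for s in matrix.samples:
        platforms.setdefault(platform_labels.get(s, ""), []).append(s)

    max_changes = np.zeros(matrix.n_sites)
    states = matrix.tip_states()
    for plat_samples in platforms.values():
        if len(plat_samples) < 3:
            continue
        drop = tips - set(plat_samples)
        subtree = prelim_tree.prune_leaves(drop) if drop else prelim_tree
        changes = min_state_changes(subtree, {s: states[s] for s in plat_samples},
                                    root_state=0)
        max_changes = np.maximum(max_changes, changes)

    bad = max_changes >= min_branches
    flagged = [int(p) for p in matrix.positions[max_changes == 2]]
    regions = []
    for p in matrix.positions[bad]:
        iv = mask.interval_containing(int(p))
        if iv is not None:
            regions.append(iv)
    excluded = RegionMask.from_intervals(regions, merge=True)
    out = _drop_sites_in_regions(matrix, excluded)
    flagged = [p for p in flagged if not excluded.contains_positions([p])[0]]
    return out, mask.subtract(excluded), excluded, flagged


def filter_missingness(
    matrix: GenotypeMatrix,
    mask: RegionMask,
    max_missing: float = 0.10,
    proximity: int = 1000,
) -> tuple[GenotypeMatrix, RegionMask, RegionMask]:
    """Drop sites with strictly more than ``max_missing`` no-calls, and
    excise the variant-free gap between two nearby such sites.

    The gap between consecutive dropped positions is excised when it is at
    most ``proximity`` bp long and contains no retained variant.
    """
    frac = matrix.missing_fraction()
    marked = frac > max_missing
    marked_pos = matrix.positions[marked]
    retained_pos = matrix.positions[~marked]

    regions: list[tuple[int, int]] = [(int(p) - 1, int(p)) for p in marked_pos]
    for p, q in zip(marked_pos[:-1], marked_pos[1:]):
        gap = int(q) - int(p)
        if gap <= proximity:
            between = np.count_nonzero((retained_pos > p) & (retained_pos < q))
            if between == 0 and gap > 1:
                regions.append((int(p), int(q) - 1))
    excluded = RegionMask.from_intervals(regions, merge=True)
    return _drop_sites_in_regions(matrix, excluded), mask.subtract(excluded), excluded


def run_qc_pipeline(
    matrix: GenotypeMatrix,
    mask: RegionMask,
    replicate_groups=(),
    window: int = 50,
    min_branches: int = 3,
    max_missing: float = 0.10,
    proximity: int = 1000,
    platform_labels: dict[str, str] | None = None,
    prelim_tree: Tree | None = None,
) -> QCResult:
    """Full QC pipeline in the fixed rule order.

    Replicate groups are pruned to the samples present in the matrix (so the
    pipeline is idempotent after replicate columns have been removed).  The
    preliminary tree for the recurrence rule is built from the current
    matrix by parsimony unless one is supplied.
    """
    report = FilterReport()
    report.sites_before = matrix.n_sites

    matrix = apply_region_mask(matrix, mask)
    report.callable_before = mask.length
    report.sites_excluded["region_mask"] = report.sites_before - matrix.n_sites

    groups = [[s for s in g if s in set(matrix.samples)] for g in replicate_groups]
    groups = [g for g in groups if len(g) >= 1]
    n = matrix.n_sites
    matrix, mask, excl, kept = filter_replicate_discordance(matrix, mask, groups)
    report.excluded_regions["replicate_discordance"] = excl
    report.sites_excluded["replicate_discordance"] = n - matrix.n_sites
    report.replicate_kept = kept

    n = matrix.n_sites
    matrix, mask, excl = filter_singleton_clusters(matrix, mask, window=window)
    report.excluded_regions["singleton_cluster"] = excl
    report.sites_excluded["singleton_cluster"] = n - matrix.n_sites

    if prelim_tree is None:
        from .phylogeny import build_parsimony_tree

        prelim_tree = build_parsimony_tree(matrix)
    n = matrix.n_sites
    matrix, mask, excl, flagged = filter_recurrent_site_regions(
        matrix, mask, prelim_tree, min_branches=min_branches,
        platform_labels=platform_labels,
    )
    report.excluded_regions["recurrent_site"] = excl
    report.sites_excluded["recurrent_site"] = n - matrix.n_sites
    report.recurrent_flagged = flagged

    n = matrix.n_sites
    matrix, mask, excl = filter_missingness(
        matrix, mask, max_missing=max_missing, proximity=proximity
    )
    report.excluded_regions["missingness"] = excl
    report.sites_excluded["missingness"] = n - matrix.n_sites

    report.callable_after = mask.length
    report.sites_after = matrix.n_sites
    return QCResult(matrix=matrix, mask=mask, report=report)
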