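"""Haplogroup affiliation of degraded (ancient, low-coverage) samples.

A sample is placed on the annotated haplotree by derived-allele path
support: a branch is *supported* when its observed panel sites show more
derived than ancestral calls, *contradicted* when the reverse, and
*pass-through* when unobserved.  The affiliation is the deepest supported
branch whose whole root path is free of contradictions; a derived call at a
site defining a sister of the assigned branch degrades the assignment one
node up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING
from .trees import Node, Tree

__all__ = [
    "SNPPanel",
    "AncientObservation",
    "Affiliation",
    "informative_site_panel",
    "observe_alleles",
    "place_sample",
]


@dataclass
class SNPPanel:
    """Branch-defining (single-origin) site panel.

    One row per informative site: 1-based position, ancestral and derived
    alleles, and the owning branch (child-node name).
    """

    table: pd.DataFrame  # columns: position, ancestral, derived, branch

    def __post_init__(self):
        required = ["position", "ancestral", "derived", "branch"]
        if list(self.table.columns[:4]) != required:
            raise ValueError(f"panel columns must start with {required}")
        if self.table["position"].duplicated().any():
            dup = self.table.loc[self.table["position"].duplicated(), "position"]
            raise ValueError(f"duplicate panel positions: {sorted(set(dup))[:5]}")

    @property
    def positions(self) -> np.ndarray:
        return self.table["position"].to_numpy(dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return len(self.table)

    def branch_of(self) -> dict[int, str]:
        return dict(zip(self.table["position"].astype(int), self.table["branch"]))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SNPPanel":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class AncientObservation:
    """Per-site allele states of one degraded sample over the panel.

    states: 1 derived, 0 ancestral, -1 missing; aligned with positions.
    """

    positions: np.ndarray
    states: np.ndarray
    source_sample: str | None = None
    truth_branch: str | None = None
    unmatched_alleles: int = 0

    @property
    def fraction_missing(self) -> float:
        return float(np.mean(self.states == MISSING)) if len(self.states) else 1.0

    def state_at(self) -> dict[int, int]:
        return {int(p): int(s) for p, s in zip(self.positions, self.states)}


@dataclass
class Affiliation:
    """Result of placing one sample on the haplotree."""

    branch: str | None
    status: str  # assigned | degraded_to_parent | unassigned
    path_support: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    # branch -> (derived, ancestral, missing) counts along the root path
    sister_conflicts: int = 0

    def to_dict(self) -> dict:
        return {
            "branch": self.branch,
            "status": self.status,
            "sister_conflicts": self.sister_conflicts,
            "path_support": {k: list(v) for k, v in self.path_support.items()},
        }


def informative_site_panel(
    tree: Tree,
    ancestral: str = "A",
    derived: str = "G",
    alleles: dict[int, tuple[str, str]] | None = None,
) -> SNPPanel:
    """Panel of single-origin branch-defining sites from the annotated tree.

    Every branch contributes its ``node.sites``; recurrent sites must
    already have been excluded from those lists (the site-to-branch mapping
    does this).  ``alleles`` optionally maps position -> (ancestral,
    derived) nucleotides.
    """
    rows = []
    for node in tree.postorder():
        if node.parent is None and not node.sites:
            continue
        for pos in node.sites:
            anc, der = (alleles or {}).get(int(pos), (ancestral, derived))
            rows.append({"position": int(pos), "ancestral": anc,
                         "derived": der, "branch": node.name})
    if not rows:
        raise ValueError("tree carries no site assignments; map sites first")
    table = pd.DataFrame(rows).sort_values("position").reset_index(drop=True)
    return SNPPanel(table)


def observe_alleles(
    observation_table: pd.DataFrame,
    panel: SNPPanel,
    min_depth: int = 1,
    sample_name: str | None = None,
) -> AncientObservation:
    """Map raw per-position allele observations onto the panel.

    ``observation_table`` rows carry (position, allele, depth).  Sites below
    ``min_depth``, absent from the table, or with an allele matching neither
    panel allele become missing (the latter counted as unmatched).
    """
    required = {"position", "allele", "depth"}
    if not required <= set(observation_table.columns):
        raise ValueError(f"observation table needs columns {sorted(required)}")
    bad = observation_table["position"].isna() | observation_table["depth"].isna()
    if bad.any():
        lines = (observation_table.index[bad] + 1).tolist()
        raise ValueError(f"malformed observation rows at lines {lines}")

    obs = observation_table[observation_table["depth"] >= min_depth]
    allele_at = dict(zip(obs["position"].astype(int), obs["allele"].astype(str)))
    states = np.full(panel.n_sites, MISSING, dtype=np.int8)
    unmatched = 0
    anc = panel.table["ancestral"].to_numpy()
    der = panel.table["derived"].to_numpy()
    for i, pos in enumerate(panel.positions):
        a = allele_at.get(int(pos))
        if a is None:
            continue
        if a == der[i]:
            states[i] = 1
        elif a == anc[i]:
            states[i] = 0
        else:
            unmatched += 1
    return AncientObservation(
        positions=panel.positions.copy(), states=states,
        source_sample=sample_name, unmatched_alleles=unmatched,
    )


def place_sample(
    obs: AncientObservation,
    tree: Tree,
    panel: SNPPanel,
    strict: bool = False,
    require_sister_confirmation: bool = True,
) -> Affiliation:
    """Affiliate one observation to a branch of the haplotree.

    Branch support = derived > ancestral calls among its panel sites (in
    ``strict`` mode any ancestral call contradicts); unobserved branches are
    pass-through.  Candidate branches — supported, with no contradicted
    branch on their root path — are ranked by total derived evidence on the
    path (equivalent to depth for nested candidates), and the assignment
    walks down the top candidate's path while each step's subtree evidence
    outweighs derived calls on its sisters, requiring an observed ancestral
    call on every sited sister whenever the remaining evidence is a single
    derived call (one sequencing error could fake it).  The walk's deepest
    supported branch is the assignment; a derived call at a site defining a
    sister of that branch finally moves it up one node
    (status ``degraded_to_parent``).  These checks are what keep
    low-coverage, error-bearing samples from landing on a side branch.
    """
    state_at = obs.state_at()
    branch_of = panel.branch_of()
    per_branch: dict[str, list[int]] = {}
    for pos, st in state_at.items():
        br = branch_of.get(pos)
        if br is None or st == MISSING:
            continue
        d, a = per_branch.get(br, [0, 0])
        if st == 1:
            d += 1
        else:
            a += 1
        per_branch[br] = [d, a]

    def verdict(name: str) -> str:
        if name not in per_branch:
            return "pass"
        d, a = per_branch[name]
        if strict:
            if a > 0:
                return "contradicted"
            return "supported" if d > 0 else "pass"
        if d > a:
            return "supported"
        if a > d:
            return "contradicted"
        return "pass"

    missing_per_branch: dict[str, int] = {}
    for pos, br in branch_of.items():
        if state_at.get(pos, MISSING) == MISSING:
            missing_per_branch[br] = missing_per_branch.get(br, 0) + 1

    # candidate = supported branch with a contradiction-free root path
    depth_of: dict[int, int] = {id(tree.root): 0}
    parent_chain: dict[int, list[Node]] = {id(tree.root): [tree.root]}
    candidates: list[tuple[int, int, int, str, Node]] = []
    for node in tree.preorder():
        if node.parent is not None:
            depth_of[id(node)] = depth_of[id(node.parent)] + 1
            parent_chain[id(node)] = parent_chain[id(node.parent)] + [node]
        if node.parent is None:
            continue
        if verdict(node.name) != "supported":
            continue
        path = parent_chain[id(node)][1:]  # skip root (not a branch)
        if any(verdict(p.name) == "contradicted" for p in path):
            continue
        n_supported = sum(1 for p in path if verdict(p.name) == "supported")
        n_derived = sum(per_branch.get(p.name, [0, 0])[0] for p in path)
        candidates.append((n_derived, n_supported, depth_of[id(node)], node.name, node))

    if not candidates:
        return Affiliation(branch=None, status="unassigned")

    # ranked by total derived evidence on the root path, then by the number
    # of supported path branches, then depth; for nested candidates this is
    # the deepest supported branch, while between incomparable subtrees it
    # weighs the observed derived calls rather than bare depth
    candidates.sort(key=lambda c: (-c[0], -c[1], -c[2], c[3]))
    best = candidates[0][4]

    def path_counts(node: Node) -> dict[str, tuple[int, int, int]]:
        out = {}
        for p in parent_chain[id(node)][1:]:
            d, a = per_branch.get(p.name, [0, 0])
            out[p.name] = (d, a, missing_per_branch.get(p.name, 0))
        return out

    # sister check along the descent: every step from the root towards the
    # chosen branch must have its sisters free of derived calls and — with
    # confirmation required — showing an observed ancestral call whenever
    # they carry defining SNPs at all.  The walk stops at the first
    # unconfirmed step and the assignment pulls back to the deepest
    # supported branch on the confirmed prefix.
    panel_sites_per_branch: dict[str, int] = {}
    for br in branch_of.values():
        panel_sites_per_branch[br] = panel_sites_per_branch.get(br, 0) + 1

    def sister_state(node: Node) -> tuple[int, int, bool]:
        """(blocking derived calls, all derived calls, confirmed) over the
        sisters of ``node``.  A sister that is itself contradicted (more
        ancestral than derived calls) is already ruled out, so its stray
        derived calls do not block the descent — but they still count for
        the absolute terminal check."""
        blocking = raw = 0
        confirmed = True
        for sib in node.parent.children:
            if sib is node:
                continue
            d, a = per_branch.get(sib.name, [0, 0])
            raw += d
            if d > 0 and d >= a:
                blocking += d
            if a == 0 and panel_sites_per_branch.get(sib.name, 0) > 0:
                confirmed = False
        return blocking, raw, confirmed

    def confirmed_assignment(target: Node) -> tuple[Node | None, int]:
        """Walk down the target's path; return (pulled-back node, conflicts).

        A step is taken when the derived calls on the candidate path at or
        below it (evidence of membership in the step's subtree) strictly
        outweigh any derived calls on its non-contradicted sisters; when
        that evidence is a single call — which one sequencing error could
        produce — every sited sister must additionally show an observed
        ancestral call.
        """
        path = parent_chain[id(target)][1:]
        d_own = [per_branch.get(n.name, [0, 0])[0] for n in path]
        d_below = np.cumsum(d_own[::-1])[::-1]
        accepted: list[Node] = []
        conflicts_seen = 0
        for k, step in enumerate(path):
            blocking, _raw, confirmed = sister_state(step)
            if blocking > 0:
                conflicts_seen += blocking
                if d_below[k] <= blocking:
                    break
            if require_sister_confirmation and not confirmed and d_below[k] < 2:
                break
            accepted.append(step)
        supported_prefix = [n for n in accepted if verdict(n.name) == "supported"]
        return (supported_prefix[-1] if supported_prefix else None), conflicts_seen

    current = None
    total_conflicts = 0
    for _, _, _, _, cand in candidates:
        current, total_conflicts = confirmed_assignment(cand)
        if current is not None:
            break
    if current is None:
        return Affiliation(branch=None, status="unassigned",
                           sister_conflicts=total_conflicts)

    # terminal sister check: any derived call at a site defining a sister of
    # the chosen branch moves the assignment up one node
    _blocking, terminal_conflicts, _conf = sister_state(current)
    if terminal_conflicts > 0:
        total_conflicts += terminal_conflicts
        current = current.parent  # may be the root: haplogroup-level affiliation
    status = (
        "assigned"
        if current is best and terminal_conflicts == 0
        else "degraded_to_parent"
    )
    return Affiliation(branch=current.name, status=status,
                       path_support=path_counts(current),
                       sister_conflicts=total_conflicts)
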