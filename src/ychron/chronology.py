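"""Calibrated molecular-clock dating with a Bayesian skyline coalescent prior.

The topology is fixed (on binary Y data it is determined by site
compatibility); the MCMC jointly samples internal-node ages, the clock rate
(optionally with relaxed lognormal per-branch multipliers), and the skyline
group sizes of the effective population size.

Model
-----
* Data: the SNP count on branch b is Poisson(r_b * L * t_b) with
  r_b = mu * m_b (mu the clock rate in mutations/bp/year, m_b = 1 under the
  strict clock), L the callable bases and t_b the branch duration in years.
* Tree prior: Bayesian skyline — coalescent intervals grouped into G groups
  of (nearly) equal event counts, each with its own constant Ne; while k
  lineages survive the coalescent rate is C(k,2) / (2 * Ne_j * g) per year
  (g the generation time in years; a pair coalesces after 2*Ne generations
  on average, the same convention as the simulator).
* Calibration: a normal prior on one node's age in years BP.
* Parameter priors: log-uniform on mu and on each Ne_j; relaxed-clock
  multipliers iid lognormal with mean 1 and stdev parameter s,
  s ~ Exponential(mean 0.3).

If every branch SNP count is zero the sampler runs prior-only (no Poisson
term), which is the standard sampler-validity check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import Tree

__all__ = [
    "ClockModel",
    "CalibrationPrior",
    "PosteriorTrace",
    "SkylineTrajectory",
    "run_dating_mcmc",
    "hpd_interval",
    "ess",
    "combine_chains",
    "summarize_node_ages",
    "clock_summary",
    "skyline_from_trace",
    "detect_expansion",
]


@dataclass
class ClockModel:
    """Strict or relaxed (uncorrelated lognormal) molecular clock."""

    mode: str = "strict"  # "strict" | "relaxed_lognormal"
    s_prior_mean: float = 0.3  # exponential prior mean of the lognormal stdev

    def __post_init__(self):
        if self.mode not in ("strict", "relaxed_lognormal"):
            raise ValueError(f"unknown clock mode {self.mode!r}")


@dataclass
class CalibrationPrior:
    """Normal age prior (years BP) on one named node."""

    node: str
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("calibration sd must be > 0")


@dataclass
class PosteriorTrace:
    """Thinned MCMC samples: one row per retained state."""

    node_names: tuple[str, ...]
    branch_names: tuple[str, ...]
    ages: np.ndarray            # (S, M) years BP
    mu: np.ndarray              # (S,)
    ne: np.ndarray              # (S, G)
    log_posterior: np.ndarray   # (S,)
    n_tips: int
    generation_time: float
    multipliers: np.ndarray | None = None  # (S, B) relaxed mode
    s: np.ndarray | None = None            # (S,) relaxed stdev
    # coalescent events per internal node (children - 1; > 1 at polytomies)
    events_per_node: tuple[int, ...] | None = None

    @property
    def n_states(self) -> int:
        return len(self.mu)

    def node_ages(self, name: str) -> np.ndarray:
        return self.ages[:, self.node_names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        data = {"log_posterior": self.log_posterior, "mu": self.mu}
        for i, name in enumerate(self.node_names):
            data[f"age:{name}"] = self.ages[:, i]
        for j in range(self.ne.shape[1]):
            data[f"ne:{j + 1}"] = self.ne[:, j]
        if self.s is not None:
            data["s"] = self.s
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class SkylineTrajectory:
    """Piecewise-constant Ne(t) summarised on a time grid."""

    times: np.ndarray   # years BP, ascending
    median: np.ndarray
    lower: np.ndarray   # 95% HPD
    upper: np.ndarray

    def __post_init__(self):
        if np.any(self.lower > self.median + 1e-9) or np.any(self.median > self.upper + 1e-9):
            raise ValueError("HPD envelope must bracket the median")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_bp": self.times, "ne_median": self.median,
            "ne_hpd_lower": self.lower, "ne_hpd_upper": self.upper,
        })


# ------------------------------------------------------------------ summaries
def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval holding >= ``prob`` of the samples
    (leftmost on ties)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("hpd_interval needs at least one sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    m = max(1, int(math.ceil(prob * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def ess(samples) -> float:
    """Effective sample size by the initial-positive-sequence rule.

    ESS = n / (1 + 2 * sum rho_k), with the autocorrelation sum truncated at
    the first non-positive consecutive pair; clipped to [0, n].  A constant
    series has no information and reports 0 (with a warning).
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("ess needs at least 10 samples")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        warnings.warn("constant series: ESS undefined, reporting 0", stacklevel=2)
        return 0.0
    # FFT autocovariance
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    rho = acov / acov[0]
    tau = 1.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        k += 2
    return float(min(n, max(0.0, n / tau)))


def combine_chains(traces: list[PosteriorTrace], burnin_fraction: float = 0.10) -> PosteriorTrace:
    """Concatenate chains after dropping the first ``burnin_fraction`` of each."""
    if not traces:
        raise ValueError("no traces to combine")
    first = traces[0]
    for t in traces[1:]:
        if (t.node_names != first.node_names or t.branch_names != first.branch_names
                or t.ne.shape[1] != first.ne.shape[1]
                or (t.multipliers is None) != (first.multipliers is None)):
            raise ValueError("traces have mismatched parameter sets")

    def cut(a):
        if a is None:
            return None
        return a[int(burnin_fraction * len(a)):]

    return PosteriorTrace(
        node_names=first.node_names,
        branch_names=first.branch_names,
        ages=np.concatenate([cut(t.ages) for t in traces]),
        mu=np.concatenate([cut(t.mu) for t in traces]),
        ne=np.concatenate([cut(t.ne) for t in traces]),
        log_posterior=np.concatenate([cut(t.log_posterior) for t in traces]),
        n_tips=first.n_tips,
        generation_time=first.generation_time,
        multipliers=(None if first.multipliers is None
                     else np.concatenate([cut(t.multipliers) for t in traces])),
        s=None if first.s is None else np.concatenate([cut(t.s) for t in traces]),
        events_per_node=first.events_per_node,
    )


def summarize_node_ages(trace: PosteriorTrace, tree: Tree, prob: float = 0.95) -> pd.DataFrame:
    """Posterior median and HPD of every internal-node age, Table-style."""
    rows = []
    for i, name in enumerate(trace.node_names):
        a = trace.ages[:, i]
        lo, hi = hpd_interval(a, prob)
        rows.append({"node": name, "age_median": float(np.median(a)),
                     "hpd_lower": lo, "hpd_upper": hi})
    df = pd.DataFrame(rows).sort_values("age_median", ascending=False).reset_index(drop=True)
    # flag any empirical violation of parent >= child in the medians
    med = {r["node"]: r["age_median"] for r in rows}
    for node in tree.postorder():
        if node.parent is not None and node.name in med and node.parent.name in med:
            if med[node.parent.name] < med[node.name] - 1e-9:
                warnings.warn(
                    f"median age of {node.name} exceeds its parent {node.parent.name}",
                    stacklevel=2,
                )
    return df


def clock_summary(trace: PosteriorTrace, prob: float = 0.95) -> dict:
    """Clock-rate posterior summary; includes the coefficient of rate
    variation (stdev/mean of branch rates) for relaxed-clock traces."""
    lo, hi = hpd_interval(trace.mu, prob)
    out = {"mu_median": float(np.median(trace.mu)), "mu_hpd": (lo, hi)}
    if trace.multipliers is not None:
        rates = trace.multipliers * trace.mu[:, None]
        cov = rates.std(axis=1) / rates.mean(axis=1)
        clo, chi = hpd_interval(cov, prob)
        out["cov_median"] = float(np.median(cov))
        out["cov_hpd"] = (clo, chi)
    return out


# ------------------------------------------------------------------ skyline
def _group_ids(n_events: int, groups: int) -> np.ndarray:
    """Assign the ordered coalescent events to groups of near-equal size
    (earlier groups take the extra events)."""
    base = n_events // groups
    sizes = np.full(groups, base, dtype=int)
    sizes[: n_events - base * groups] += 1
    return np.repeat(np.arange(groups), sizes)


def skyline_from_trace(
    trace: PosteriorTrace,
    generation_time: float | None = None,
    grid: np.ndarray | None = None,
    n_grid: int = 200,
    prob: float = 0.95,
) -> SkylineTrajectory:
    """Evaluate the per-state piecewise Ne(t) on a time grid and summarise
    pointwise with the median and HPD envelope."""
    del generation_time  # Ne is already in individuals in the trace
    S, M = trace.ages.shape
    G = trace.ne.shape[1]
    e_arr = np.asarray(trace.events_per_node or (1,) * M, dtype=int)
    n_events = int(e_arr.sum())
    if G > n_events:
        raise ValueError(f"{G} skyline groups but only {n_events} coalescent events")
    gid = _group_ids(n_events, G)
    # per group, the age of its most ancient event = the group's upper bound
    ends = np.nonzero(np.diff(np.concatenate([gid, [G]])))[0]
    events = np.sort(np.repeat(trace.ages, e_arr, axis=1), axis=1)
    boundaries = events[:, ends]  # (S, G)
    if grid is None:
        grid = np.linspace(0.0, float(np.median(events[:, -1])), n_grid)
    grid = np.asarray(grid, dtype=float)
    # group index of each grid time, per state (times beyond the root keep
    # the most ancient group's Ne)
    idx = np.minimum(
        np.sum(grid[None, None, :] > boundaries[:, :, None], axis=1), G - 1
    )  # (S, n_grid)
    values = np.take_along_axis(trace.ne, idx, axis=1)
    med = np.median(values, axis=0)
    lo = np.empty_like(med)
    hi = np.empty_like(med)
    for j in range(len(grid)):
        lo[j], hi[j] = hpd_interval(values[:, j], prob)
    return SkylineTrajectory(times=grid, median=med, lower=lo, upper=hi)


def detect_expansion(traj: SkylineTrajectory) -> bool:
    """Growth-detection criterion: the lower HPD bound at some recent time
    exceeds the upper HPD bound at some more ancient time."""
    upper_suffix_min = np.minimum.accumulate(traj.upper[::-1])[::-1]
    recent = traj.lower[:-1]
    return bool(np.any(recent > upper_suffix_min[1:]))


# ------------------------------------------------------------------ sampler
def run_dating_mcmc(
    tree: Tree,
    branch_snp_counts: dict[str, int],
    L: float,
    calibration: CalibrationPrior,
    clock_model: ClockModel | None = None,
    skyline_groups: int = 5,
    chains: int = 2,
    iterations: int = 200_000,
    thin: int = 20,
    seed: int = 0,
    generation_time: float = 31.0,
    mu_bounds: tuple[float, float] = (1e-11, 1e-8),
    ne_bounds: tuple[float, float] = (1.0, 1e9),
) -> list[PosteriorTrace]:
    """Sample node ages, clock rate and skyline Ne on the fixed topology.

    ``branch_snp_counts`` maps child-node names to assigned SNP counts
    (absent branches count 0).  Runs ``chains`` independent chains with
    seeds ``seed, seed+1, ...``; deterministic given the seed.
    """
    clock_model = clock_model or ClockModel()
    return [
        _run_single_chain(
            tree, branch_snp_counts, L, calibration, clock_model, skyline_groups,
            iterations, thin, seed + c, generation_time, mu_bounds, ne_bounds,
        )
        for c in range(chains)
    ]


def _run_single_chain(
    tree: Tree,
    branch_snp_counts: dict[str, int],
    L: float,
    calibration: CalibrationPrior,
    clock: ClockModel,
    G: int,
    iterations: int,
    thin: int,
    seed: int,
    g: float,
    mu_bounds: tuple[float, float],
    ne_bounds: tuple[float, float],
) -> PosteriorTrace:
    rng = np.random.default_rng(seed)
    relaxed = clock.mode == "relaxed_lognormal"

    # polytomies collapse several coalescent events onto one age variable,
    # which breaks the scale invariance of the time posterior; resolve them
    # into binary ladders whose extra nodes carry no SNPs and whose ages are
    # sampled like any other (the data cannot distinguish resolutions)
    if any(len(node.children) > 2 for node in tree.postorder()):
        from .trees import resolve_polytomies

        tree = resolve_polytomies(tree)

    internal = tree.internal_nodes()   # postorder: children before parents
    M = len(internal)
    if M < 1:
        raise ValueError("dating needs at least one internal node")
    n_tips = tree.n_leaves
    # a polytomy of c children stands for c-1 simultaneous coalescent events
    e_arr = np.array([len(node.children) - 1 for node in internal], dtype=int)
    n_events = int(e_arr.sum())
    assert n_events == n_tips - 1
    if G > n_events:
        raise ValueError(f"{G} skyline groups exceed the {n_events} coalescent events")
    idx_of = {id(node): i for i, node in enumerate(internal)}
    node_names = tuple(node.name for node in internal)
    if calibration.node not in node_names:
        raise ValueError(f"calibration node {calibration.node!r} not an internal node")
    cal_idx = node_names.index(calibration.node)
    root_idx = idx_of[id(tree.root)]

    branches = tree.branches()
    B = len(branches)
    branch_names = tuple(b.name for b in branches)
    n_b = np.array([float(branch_snp_counts.get(b.name, 0)) for b in branches])
    prior_only = bool(np.all(n_b == 0))
    b_par = np.array([idx_of[id(b.parent)] for b in branches])
    # child slot: internal index, or M for tips (age pinned at 0)
    b_child = np.array([idx_of.get(id(b), M) for b in branches])
    parent_of = np.array(
        [idx_of[id(node.parent)] if node.parent is not None else -1 for node in internal]
    )
    children_of = [
        np.array([idx_of[id(c)] for c in node.children if not c.is_leaf], dtype=int)
        for node in internal
    ]

    kvals = np.arange(n_tips, 1, -1, dtype=float)     # lineages per interval
    cvals = kvals * (kvals - 1) / 2.0
    gid = _group_ids(n_events, G)
    cnt = np.bincount(gid, minlength=G).astype(float)

    # ---------------- initial state: clock-like ages from the SNP counts
    # (mean SNP path length from each node to its tips, scaled so the
    # calibrated node starts at its prior mean), so the chain starts near a
    # data-consistent tree shape
    t = np.zeros(M)
    if all(node.age > 0 for node in internal):
        for node in internal:
            t[idx_of[id(node)]] = node.age
    else:
        snp_depth: dict[int, float] = {}
        for node in tree.postorder():
            if node.is_leaf:
                snp_depth[id(node)] = 0.0
            else:
                snp_depth[id(node)] = float(np.mean([
                    snp_depth[id(c)] + branch_snp_counts.get(c.name, 0) + 0.5
                    for c in node.children
                ]))
        for i, node in enumerate(internal):
            t[i] = snp_depth[id(node)]
        # enforce strict parent > child ordering before scaling
        for i, node in enumerate(internal):
            kids = children_of[i]
            if len(kids):
                t[i] = max(t[i], t[kids].max() * 1.0001 + 1e-9)
    t = t * (calibration.mean / t[cal_idx])
    total_time0 = float(np.sum(t[b_par] - np.append(t, 0.0)[b_child]))
    mu = float(np.clip(n_b.sum() / (L * total_time0) if n_b.sum() else 7e-10,
                       mu_bounds[0] * 1.01, mu_bounds[1] * 0.99))
    ne = np.full(G, float(np.clip(t[root_idx] / (2 * g), *ne_bounds)))
    m = np.ones(B)
    s = clock.s_prior_mean

    t_ext = np.append(t, 0.0)
    log_mu_lo, log_mu_hi = math.log(mu_bounds[0]), math.log(mu_bounds[1])
    log_ne_lo, log_ne_hi = math.log(ne_bounds[0]), math.log(ne_bounds[1])

    def data_ll(t_ext_, mu_, m_):
        if prior_only:
            return 0.0
        tau = t_ext_[b_par] - t_ext_[b_child]
        theta = mu_ * L * m_ * tau
        return float(np.sum(n_b * np.log(theta) - theta))

    def coal_parts(t_):
        events = np.sort(np.repeat(t_, e_arr))
        dt = np.diff(events, prepend=0.0)
        contrib = cvals * dt / (2.0 * g)
        A = np.bincount(gid, weights=contrib, minlength=G)
        return A

    def coal_ll(A, ne_):
        return float(np.sum(-A / ne_ - cnt * np.log(2.0 * ne_ * g)))

    def cal_ll(t_):
        z = (t_[cal_idx] - calibration.mean) / calibration.sd
        return -0.5 * z * z

    def mult_prior(m_, s_):
        if not relaxed:
            return 0.0
        lm = np.log(m_)
        return float(np.sum(-lm - math.log(s_) - (lm + s_ * s_ / 2.0) ** 2 / (2 * s_ * s_))
                     - s_ / clock.s_prior_mean)

    cur_data = data_ll(t_ext, mu, m)
    cur_A = coal_parts(t)
    cur_coal = coal_ll(cur_A, ne)
    cur_cal = cal_ll(t)
    cur_mult = mult_prior(m, s)

    def total_lp():
        return (cur_data + cur_coal + cur_cal + cur_mult
                - math.log(mu) - float(np.sum(np.log(ne))))

    n_keep = iterations // thin
    out_ages = np.empty((n_keep, M))
    out_mu = np.empty(n_keep)
    out_ne = np.empty((n_keep, G))
    out_lp = np.empty(n_keep)
    out_m = np.empty((n_keep, B)) if relaxed else None
    out_s = np.empty(n_keep) if relaxed else None

    # move schedule: age slides dominate; global scale moves keep mu and the
    # timescale mixing jointly
    weights = [("age", M), ("root", 3.0), ("mu", 3.0), ("ne", G), ("updown", 6.0)]
    if relaxed:
        weights += [("mult", max(2.0, B / 4.0)), ("s", 2.0)]
    kinds = [k for k, _ in weights]
    probs = np.array([w for _, w in weights], dtype=float)
    probs /= probs.sum()
    cum = np.cumsum(probs)

    kept = 0
    for it in range(iterations):
        kind = kinds[int(np.searchsorted(cum, rng.random()))]
        if kind == "age":
            i = int(rng.integers(M))
            if i == root_idx:
                kind = "root"
            else:
                kids = children_of[i]
                lo = float(t[kids].max()) if len(kids) else 0.0
                hi = float(t[parent_of[i]])
                new = lo + rng.random() * (hi - lo) if hi > lo else t[i]
                old = t[i]
                t[i] = t_ext[i] = new
                new_data = data_ll(t_ext, mu, m)
                new_A = coal_parts(t)
                new_coal = coal_ll(new_A, ne)
                new_cal = cal_ll(t) if i == cal_idx else cur_cal
                dlp = (new_data - cur_data) + (new_coal - cur_coal) + (new_cal - cur_cal)
                if dlp >= 0 or rng.random() < math.exp(dlp):
                    cur_data, cur_coal, cur_cal, cur_A = new_data, new_coal, new_cal, new_A
                else:
                    t[i] = t_ext[i] = old
        if kind == "root":
            i = root_idx
            kids = children_of[i]
            lo = float(t[kids].max()) if len(kids) else 0.0
            f = math.exp(0.2 * (rng.random() - 0.5))
            new = t[i] * f
            if new > lo:
                old = t[i]
                t[i] = t_ext[i] = new
                new_data = data_ll(t_ext, mu, m)
                new_A = coal_parts(t)
                new_coal = coal_ll(new_A, ne)
                new_cal = cal_ll(t) if i == cal_idx else cur_cal
                dlp = ((new_data - cur_data) + (new_coal - cur_coal)
                       + (new_cal - cur_cal) + math.log(f))
                if dlp >= 0 or rng.random() < math.exp(dlp):
                    cur_data, cur_coal, cur_cal, cur_A = new_data, new_coal, new_cal, new_A
                else:
                    t[i] = t_ext[i] = old
        elif kind == "mu":
            f = math.exp(0.4 * (rng.random() - 0.5))
            new_mu = mu * f
            if log_mu_lo <= math.log(new_mu) <= log_mu_hi:
                new_data = data_ll(t_ext, new_mu, m)
                # log-uniform prior: -log(mu); Hastings: +log f -> they cancel
                dlp = new_data - cur_data
                if dlp >= 0 or rng.random() < math.exp(dlp):
                    mu, cur_data = new_mu, new_data
        elif kind == "ne":
            j = int(rng.integers(G))
            f = math.exp(1.0 * (rng.random() - 0.5))
            new_ne = ne[j] * f
            if log_ne_lo <= math.log(new_ne) <= log_ne_hi:
                dlp = (-cur_A[j] / new_ne - cnt[j] * math.log(new_ne * g)) - (
                    -cur_A[j] / ne[j] - cnt[j] * math.log(ne[j] * g))
                if dlp >= 0 or rng.random() < math.exp(dlp):
                    ne[j] = new_ne
                    cur_coal = coal_ll(cur_A, ne)
        elif kind == "updown":
            f = math.exp(0.25 * (rng.random() - 0.5))
            new_mu = mu / f
            if not (log_mu_lo <= math.log(new_mu) <= log_mu_hi):
                f = 1.0
                new_mu = mu
            t_new = t * f
            t_ext_new = np.append(t_new, 0.0)
            new_data = data_ll(t_ext_new, new_mu, m)
            new_A = cur_A * f
            new_coal = coal_ll(new_A, ne)
            z = (t_new[cal_idx] - calibration.mean) / calibration.sd
            new_cal = -0.5 * z * z
            # Jacobian: M ages scaled up, mu scaled down
            dlp = ((new_data - cur_data) + (new_coal - cur_coal) + (new_cal - cur_cal)
                   + (M - 1) * math.log(f))
            if dlp >= 0 or rng.random() < math.exp(dlp):
                t, t_ext, mu = t_new, t_ext_new, new_mu
                cur_data, cur_coal, cur_cal, cur_A = new_data, new_coal, new_cal, new_A
        elif kind == "mult":
            b = int(rng.integers(B))
            f = math.exp(0.6 * (rng.random() - 0.5))
            new_mb = m[b] * f
            old_mb = m[b]
            m[b] = new_mb
            new_data = data_ll(t_ext, mu, m)
            new_mult = mult_prior(m, s)
            dlp = (new_data - cur_data) + (new_mult - cur_mult) + math.log(f)
            if dlp >= 0 or rng.random() < math.exp(dlp):
                cur_data, cur_mult = new_data, new_mult
            else:
                m[b] = old_mb
        elif kind == "s":
            f = math.exp(0.5 * (rng.random() - 0.5))
            new_s = s * f
            new_mult = mult_prior(m, new_s)
            dlp = (new_mult - cur_mult) + math.log(f)
            if dlp >= 0 or rng.random() < math.exp(dlp):
                s, cur_mult = new_s, new_mult

        if (it + 1) % thin == 0 and kept < n_keep:
            out_ages[kept] = t
            out_mu[kept] = mu
            out_ne[kept] = ne
            out_lp[kept] = total_lp()
            if relaxed:
                out_m[kept] = m
                out_s[kept] = s
            kept += 1

    return PosteriorTrace(
        node_names=node_names,
        branch_names=branch_names,
        ages=out_ages[:kept],
        mu=out_mu[:kept],
        ne=out_ne[:kept],
        log_posterior=out_lp[:kept],
        n_tips=n_tips,
        generation_time=g,
        multipliers=out_m[:kept] if relaxed else None,
        s=out_s[:kept] if relaxed else None,
        events_per_node=tuple(int(e) for e in e_arr),
    )
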