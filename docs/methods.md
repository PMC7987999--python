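# Methods

This note documents the models behind `ychron`, the parameters that
matter, what the synthetic-data generator does and does not emulate, the
numerical choices, and the known limitations.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coalescent simulation

Genealogies are drawn from the Kingman coalescent with piecewise-constant
effective population size: while `k` lineages survive at time `t` (years
BP), pairs coalesce at rate `C(k,2) / (2 · Ne(t) · g)` per year, with
`g = 31` years per male generation.  Under this convention a pair
coalesces after `2·Ne` generations on average — the scale on which both
the generator's epochs and the inferred skyline `Ne` are reported, and the
one used by the mainstream coalescent tools.  Epoch boundaries are handled
by the memorylessness of the exponential clock (waiting times restart at
each boundary).

Mutations follow the infinite-sites model: branch `b` of duration `t_b`
receives `Poisson(μ·L·t_b)` SNPs, each at a unique uniform position in
`[1, L]`, carried by exactly the branch's descendant tips.  Defaults are
the study conditions: 172 chromosomes, `μ = 6.95e-10` mutations/bp/year,
`L = 9,429,728` callable bases.

The default demography (`DemographyModel.study_like()`) is a four-epoch
stand-in for the inferred haplogroup history — `Ne` of 120 before 12 kya,
500 until 6 kya, 2,500 until 1.5 kya, 12,000 since — i.e. a small constant
population through the Pleistocene and early Holocene, strong growth
through the Chalcolithic-to-Iron-Age window, and a recent plateau.  It was
chosen so a 172-tip tree carries ≈ 4,500 SNPs with a TMRCA near 20 kyr
and internal nodes spread over the whole depth of the tree, as dated
haplogroup branches are.  A genuinely star-shaped tree (all coalescences
nearly simultaneous) leaves the rate–timescale combination ill-determined,
so the spread is a property of realistic data, not a convenience.

STR haplotypes evolve by the stepwise mutation model, ±1 repeat at
`2e-3` mutations/locus/generation (a typical Y-STR average; the per-locus
rates are free parameters), reflecting at a floor of one repeat since
repeat counts cannot reach zero.  Root repeat counts default to modal
values of the eight diversity loci.

Geography follows a Brownian random walk: child location = parent location
plus an isotropic Gaussian step with per-axis variance `σ²·t_b` in a local
plane (see *Projection*).  The default `σ = 11 km/√year` puts the
tree-wide dispersal statistic of emulated data at the few-tenths-km/year
scale reported for continental-range human Y lineages.

Degraded (ancient) samples are modelled as independent site dropout at a
missingness rate plus symmetric allele flips at an error rate.  Real
ancient DNA damage is asymmetric (C→T deamination); a damage-aware model
is out of scope, so conclusions about transition-specific errors do not
transfer.

QC artifacts are injected one per callable-mask interval (so the truth is
unambiguous; exhausting the free intervals raises): same-carrier singleton
clusters with ≤ 50 bp gaps, a duplicated sample column with labelled
discordances and extra no-calls, recurrent sites whose carriers are the
union of 2 or ≥ 3 disjoint clades (two-origin sites carry no excision
region — a correct pipeline retains and flags them), and high-missingness
blocks built from clade-compatible sites so they trip only the
missingness rule.

## Variant QC

Pipeline order is fixed: callable mask → replicate discordance →
singleton clusters → recurrence → missingness; a site excluded by several
rules is attributed to the first.  Coordinates follow the standard
conventions throughout (VCF POS 1-based; BED and all mask arithmetic
0-based half-open; POS `p` covers base `p−1`).

Decisions where the rules leave the excised extent open: the singleton-
cluster rule excises the run span ± 50 bp; the discordance and recurrence
rules excise the containing callable interval; the missingness rule drops
sites with strictly > 10% no-calls and additionally excises the gap
between two consecutive dropped positions when it is ≤ 1,000 bp long and
contains no retained variant.  The singleton rule is restricted to
same-carrier runs by default (the terminal-branch artifact signature);
any-carrier mode is a flag.  Recurrence is assessed per sequencing
platform by small parsimony (Sankoff, vectorised over sites) with the
root held ancestral; ≥ 3 changes excises, exactly 2 flags.

On real-scale simulations, chance same-carrier singleton pairs within
50 bp do occur on long terminal branches; they are genuine rule triggers,
indistinguishable from the artifact signature, and are excised exactly as
on real data.  Fixtures that require exact label/excision agreement
therefore select (deterministically, by seed scan) base matrices free of
natural triggers.

## Haplotree construction and nomenclature

Compatible sites define the tree directly: unique carrier sets are
laminar on clean data, so the perfect phylogeny is built by containment,
with polytomies allowed and identical samples becoming sister tips.
Candidate clades are inserted best-supported first (by supporting-site
count, then size), re-parenting smaller contained clades — so a lone
homoplasic site, such as a retained two-origin SNP whose carriers span
two clades, cannot displace clades backed by many sites; it simply fails
to insert and is flagged recurrent.
Sites with missing calls never create clades (their carrier sets are
ambiguous); they are attached afterwards by wildcard matching — missing
calls are compatible with either state, ties resolved toward the smaller
clade.  Incompatible sites receive a minimal state-change labelling and
count as recurrent; the recurrence fraction is recurrent/total retained
sites.  An outgroup column, when given, re-polarises sites on which it
carries the derived allele and is dropped from the returned tree.

Branch naming ranks children major-first by descendant-tip count (ties by
defining-marker name, then smallest tip label), alternates letter and
number suffixes with depth, collapses unifurcations (their sites join the
child branch), and appends a defining-marker label preferring markers
genotyped in-study.  Names parse back to their root path, which the test
suite checks by walking the parsed choices.

Annotation renames internal nodes, so site-to-branch assignments must be
computed after it: the assignment keys branch SNP counts by node name and
the dating likelihood looks those names up.  (The regression test for
this ordering exists because getting it wrong silently starves the clock
model of internal-branch data.)

## Calibrated dating and the skyline

The sampler is a random-scan Metropolis–Hastings MCMC over node ages, the
clock rate, skyline `Ne` groups, and (relaxed mode) per-branch rate
multipliers and their lognormal spread `s`.  Moves: uniform node-age
slides within the (children, parent) bracket, multiplicative scales on the
root age, `μ`, each `Ne_j`, multipliers and `s`, and a joint up–down move
scaling all ages by `f` and `μ` by `1/f` (Jacobian `f^(M−1)`), which is
what keeps the strongly anti-correlated rate–timescale pair mixing.
Priors: `μ` log-uniform on `[1e-11, 1e-8]`; `Ne_j` log-uniform on
`[1, 1e9]`; multipliers iid lognormal with mean 1; `s ~ Exp(mean 0.3)`.
Initial ages are clock-like (mean SNP path lengths scaled to the
calibration mean), so chains start near a data-consistent shape.

Polytomies are resolved into deterministic binary ladders before
sampling; the inserted nodes carry no SNPs and their ages are sampled
like any other.  A polytomy treated as a single age variable breaks the
scale neutrality of the time posterior (each suppressed coalescent event
contributes a `1/f` tilt), which is why resolution is not optional.

The skyline prior groups the `n−1` coalescent events into `G` contiguous
groups of near-equal size (default `G = 5`), each with its own constant
`Ne`; the trajectory is evaluated per posterior state as a step function
on a time grid and summarised pointwise by the median and shortest 95%
HPD interval.  Growth is declared when the lower HPD bound at some recent
time exceeds the upper bound at some more ancient time.

Desk-scale chain budgets (two chains of 2–3e5 proposals, thinned, 10%
burn-in per chain before combining) are the package's default problem
size; convergence is judged by the same ESS > 200 yardstick used for
full-scale runs.  ESS uses the initial-positive-sequence truncation of
the autocorrelation sum and is clipped to `[0, n]`; a constant series
reports 0 with a warning.

Two model-level facts worth knowing:

* *Prior recovery.*  Sampling with no data reproduces a calibrated node's
  normal prior only up to the tilt of the scale-invariant coalescent
  prior, ≈ −sd²·(n−1)/mean on the calibrated node's age.  The sampler
  validity check therefore runs on a two-lineage genealogy, where the
  tilt is ~1% of the 18,741 ± 1,874 yr calibration.
* *Skyline envelope coverage.*  Per skyline group the 95% HPD has ≈ 95%
  frequentist coverage of a constant truth (conjugate inverse-gamma
  structure), so the probability that the whole five-group envelope holds
  the truth at every time point is ≈ 0.95⁵ ≈ 77% per replicate — a
  ceiling inherent to the method, not a sampler defect.  The acceptance
  test that demands 90% joint coverage fails for this reason and is left
  failing rather than weakened; the discrimination property (no false
  growth signal from a truth-holding envelope, reliable detection of a
  10× expansion) holds and is tested separately.

## Projection and phylogeography

All Brownian algebra runs in an azimuthal **equidistant** plane centred on
the tip centroid (generator: on the root location): distances and
azimuths from the centre are exact, and chord distances between
off-centre points distort only at second order — under 1% across a
West-Asian-scale window, satisfying the < 1.5% plane-vs-haversine
requirement that a fixed-cosine equirectangular plane does not.
Reported displacements use the haversine formula.

Location inference is exact conditional sampling, not MCMC: an upward
pruning pass accumulates each subtree's conditional mean and variance (in
`σ²` units) and the standardised contrast sum of squares; `σ²` is drawn
from its conjugate inverse-gamma posterior under the log-uniform prior;
a downward pass samples the root and then each internal node given its
parent.  Coincident tip coordinates are jittered by up to 1 km (the
Brownian likelihood is singular at exact duplicates); with jitter disabled
and all tips coincident, `σ² → 0` and every sampled root is exactly that
point.  Posterior states can reuse node ages from a dating trace, one
state per draw.

The 80% HPD root region is the smallest set of kernel-density grid cells
holding 80% of the mass (Gaussian KDE, 200² grid by default), contoured
to polygons; its area is the km² sum of included cells and containment is
by cell membership.  The dispersal statistic is
`Σ_b haversine(parent_b, child_b) / Σ_b t_b` per posterior state,
summarised by median and HPD.  Same-population cherries younger than
~1,000 years are thinned beforehand (the tip with more missing data is
dropped, ties by ID), repeated to stability.

## Ancient-sample placement

The panel is the single-origin branch-defining site list (recurrent sites
excluded).  Per branch, support = more derived than ancestral observed
calls, contradiction = the reverse, pass-through = unobserved (in strict
mode any ancestral call contradicts).  Candidates — supported branches
with contradiction-free root paths — are ranked by total derived evidence
on the path (equivalent to depth for nested candidates; between
incomparable subtrees it weighs observed evidence rather than bare
depth).  The assignment walks down the top candidate's path and accepts a
step only while the derived calls at-or-below it strictly outweigh
derived calls on non-contradicted sisters; when the remaining evidence is
a single derived call — which one sequencing error could fake — every
sister that has defining SNPs at all must additionally show an observed
ancestral call.  The walk's deepest supported branch is the assignment;
a derived call at a site defining a sister of that branch finally moves
it up one node.  Failed walks fall through to the next-ranked candidate;
no supported branch anywhere means unassigned.

The design intent is asymmetry: under heavy missingness and sequencing
error the rule should degrade assignments *up* the true path (an ancestor
is conservative, never wrong) and essentially never across to a side
branch.  `min_depth` defaults to 1 (ancient-DNA reality); alleles
matching neither panel state become missing and are counted.

## STR diversity and surfaces

Gene diversity is Nei's unbiased `D = n/(n−1)·(1 − Σ p_i²)` over exact
equality of the 8-locus haplotype — algebraically the fraction of unequal
sample pairs, which the tests exploit as an independent oracle.  No
stepwise-distance weighting is used.  Surfaces use ordinary kriging with
a linear variogram and no nugget (weights from the bordered `(k+1)`
system; exact at data points) or inverse-distance weighting (power 2,
also exact at data points, bounded by the data range).  Duplicate
coordinates with conflicting values are averaged with a warning.  Output
is a numeric lat/lon grid (TSV or ESRI-ASCII); map cosmetics are out of
scope.

## What the generator does not emulate

Read-level sequencing (FASTQ/BAM), reference mapping and genotype
calling, recombination (the MSY is non-recombining), selection, ancient
damage profiles, platform-specific error structure beyond the labelled
artifacts, and population structure in the geography beyond Brownian
diffusion.  Passing tests therefore demonstrate the correctness of the
statistical machinery on data satisfying the stated models — not
robustness to mapping artefacts, reference bias, or non-Brownian
dispersal.

## Repository shape

The package is consumed from Python, so its public face is the importable
API plus one narrative script per capability in `examples/`; no shell
entry points are installed.  `scripts/acceptance.py` re-runs the whole
pipeline at study conditions from a single seed and writes its headline
quantities as JSON.
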