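# Methods

## The metrics

`tiptempo` quantifies, for each species on a dated phylogeny, how often
and how recently a discrete trait changed along that species' own
root-to-tip history. All three metrics are evaluated on *stochastic
character maps* — complete trait histories that assign a state to every
node and a sequence of (state, dwell-time) segments to every branch —
so that change times inside branches are available, not just node
states.

For a species *s*, let the root-to-tip path visit N internal nodes
(root included, tip excluded), let t be the number of state changes
observed over the N consecutive node-to-node comparisons along the path
(the comparison of the last internal node against the tip state is
included), and let *a* be the tip state.

* **Transition Rate** `TR = t / N`, dimensionless in [0, 1]. TR counts
  only changes *fixed at nodes*: a within-branch excursion that leaves
  state *a* and returns before the next node does not change any node
  comparison and leaves TR untouched. TR = 0 means tip and all
  ancestral nodes share a state; TR = 1 means every node comparison
  changed.
* **Stasis Time** `ST` (Ma): the longest contiguous stretch of time the
  lineage spent in the current tip state *a*, anywhere along its
  history. Dwell segments are merged across node boundaries, so a run
  may span several branches; a brief within-branch flip truncates a
  run even though TR ignores it. The maximal run may predate later
  excursions, so ST > LT is possible and is not an error.
* **Last Transition Time** `LT` (Ma): the duration of the terminal run
  in *a* — the time since the lineage last entered the state it shows
  today. A lineage that never left *a* has ST = LT = its full depth.

N counts the root and excludes the tip. Under this convention t ≤ N
always, TR = 1 is attainable exactly, and for a tree with n tips the
expected path length is ≈ 2·ln n nodes. ST is restricted to the
species' own root-to-tip history (not the whole tree), matching the
lineage-indexed definition. A `st_mode="branchwise"` compatibility
option returns the maximum *single-segment* dwell instead of the
maximum merged run.

Per-species values are collected over every (phylogeny × simulation)
map into an *estimate cube* (species × trees × simulations); the
cross-estimate spread is the phylogenetic + mapping uncertainty that
all downstream summaries propagate.

## Mk model and stochastic mapping

Trait evolution is modeled as a continuous-time Markov chain with k
states (Mk). Three parameterizations are supported: ER (one rate), SYM
(symmetric, k(k−1)/2 rates) and ARD (all rates different, k(k−1)).
The likelihood is the standard post-order pruning algorithm with
per-node rescaling; transition matrices for all branches of a tree are
produced from a single eigendecomposition when Q is symmetric (ER/SYM)
and from a general eigendecomposition with an `expm` fallback for ARD.

Fitting maximizes the likelihood on the log-rate scale with L-BFGS-B
from ≥ 5 dispersed starts (rates span orders of magnitude and the ARD
surface can be multimodal). Rates are bounded above at ~100 expected
changes per average branch: beyond that the likelihood sits on its
saturation plateau (every transition row ≈ stationary), so the bound
loses no information while keeping path simulation tractable for
saturated data whose MLE is formally infinite. Convergence tolerance
is 1e-8 on the log-likelihood. The root prior defaults to the
stationary distribution of the fitted Q (uniform for ER/SYM); a flat
prior is available. SYM-vs-ARD choice is by AIC, ties to the
fewer-parameter model.

Maps are drawn by the standard two-stage scheme: a joint draw of node
states (root from prior × partial likelihood, then preorder
conditional draws), followed by endpoint-conditioned path sampling on
each branch. Paths are sampled by rejection of unconditioned forward
trajectories (cheap when the endpoints are probable), falling back
after 10,000 failures to exact uniformization: the jump count is drawn
from its exact conditioned distribution under a dominating Poisson
process, jump states from the discrete bridge, jump times as uniform
order statistics, and virtual jumps collapsed. Sampling therefore
always terminates and is exact in both regimes. Zero-length branches
copy the parent state.

Q is re-fitted on every phylogeny of the tree set (topologies and
branch lengths differ across trees); one master seed spawns a
deterministic substream per (tree, simulation) pair so any subset of
maps is reproducible in isolation.

## Diet states and imputation

Diet percentages (insects/invertebrates, plants, fruits+seeds) map to
four states: a specialist state when exactly one category is ≥ 50% and
the others < 50%, generalist otherwise. Exact two-way 50/50 ties are
generalist — it is the residual category. Percentages are used as
given, not renormalized to 100. Missing percentage rows (< 50% of
species) are filled by iterative random-forest regression on the
observed percentage columns only, deliberately without phylogenetic
predictors so imputed traits are not forced to covary with the
phylogeny they are later mapped on; imputed values are clipped to
[0, 100], observed cells are never altered, and the result is
deterministic per seed.

## Spatial design

All geometry is planar (km) under a Lambert cylindrical equal-area
projection with its standard parallel and center at (15°S, 56°W); the
closed-form projection round-trips to < 1e-6 degrees and preserves
areas to < 0.5% on small test polygons. Each ecoregion polygon is
covered by a square grid (default cell width 26.4 km — consistent with
the half-cell 13.2 km buffer below); cell centroids inside the polygon
are candidates. The k candidates nearest the polygon boundary are the
*ecotone* points and the k farthest the *core* points (default k = 10;
ties at the k-th rank break by ascending point id). Boundary distance
is the exact planar distance to the polygon boundary. Species
composition at a point is every species whose range polygon intersects
the disc of 13.2 km (half a cell) around it; a species found at both
core and ecotone points of the same ecoregion is removed from that
ecoregion (exclusivity filter, idempotent). Small-ranged species are
those with range area strictly below 4.16 square degrees, areas
measured in square degrees on unprojected maps.

Point covariates: position, habitat (forest/open), their interaction,
the summed area of neighboring ecoregions (sq deg), counts of forest-
and open-habitat neighbors overlapped by the point buffer, and
Andes/Atlantic Rainforest flags; quantitative columns are standardized
(mean 0, sample SD 1) and factor reference levels are core / open /
core-open. Moran's I uses row-standardized inverse-distance weights by
default (k-nearest available) with an upper-tail permutation p-value.
The exported tables are model-ready for any mixed-model software;
fitting those models is outside this package's scope.

## Assemblage level and uncertainty

aTR/aST/aLT at a point are unweighted means over the species present
(no abundance data exist); empty points are NaN and excluded with a
warning. Uncertainty per point is the sample SD (n−1) across all
(phylogeny × simulation) estimates; a uniform without-replacement
subsample of estimate pairs (default 2,000) supports
expensive per-estimate downstream models. The within/between-phylogeny
randomization draws, per iteration, 10 estimates from simulations of
one phylogeny and 10 estimates from one simulation index shared across
10 phylogenies (an independent-simulation variant is available behind
a flag), pools each set over points, and reports the proportion of
iterations with within-SD < between-SD per metric. Faith's PD is the
summed branch length of the minimal root-inclusive subtree spanning
the present species; the root-inclusive convention makes single-
species PD equal the tree height and is stated because the bare
definition is ambiguous there.

## Synthetic data

The generator produces every input from one seed: birth–death trees
conditioned on the tip count (after reaching n extant tips the process
runs one more exponential waiting time, the standard
snapshot-before-next-event rule, so pure-birth root ages have mean
Σ_{k=2..n} 1/(bk)); tree sets emulating phylogenetic uncertainty by a
per-tree log-normal depth factor, per-branch log-normal length noise
and jitter-proportional random tip-label swaps (re-ultrametrized by
terminal-branch extension); forward-simulated trait histories whose
ground truth is kept for oracle tests; rectangular ecoregion tilings
with checkerboard/random/block habitats and Andes/Atlantic flags on
the outer columns; and circular species ranges with log-normal
(right-skewed) areas placed along the centroid-to-boundary segment of
a round-robin home ecoregion.

Scenario defaults (4 trait states, symmetric process at 0.1
transitions per state-pair per Ma, 40 tips, 10 trees × 10 simulations,
3×3 landscape of 150 km ecoregions, 10 + 10 points per ecoregion,
13.2→10 km buffers at the 20 km synthetic cell width, log-normal range
areas with median ≈ 1,200 km²) are sized so one full pipeline run
takes seconds while every structural feature of the design — shared
tip sets, exclusivity filtering, assemblage averaging, uncertainty
propagation — is exercised. A planted "ecotone effect" multiplies the
transition intensity on branches all of whose descendant tips are
ecotone-affiliated (with tip-wise affiliation, essentially their
terminal branches); the default multiplier 8 over the base rate gives
roughly one extra expected change on an affiliated terminal branch.
Species affiliation follows a randomized-block design:
phylogenetically adjacent tips (label order equals preorder position,
so consecutive labels are usually close relatives) are paired, a fair
coin decides which member of each pair is core- vs ecotone-affiliated,
and both members share a home ecoregion. The coin flip makes the
core-ecotone contrast exactly unbiased under the null (a deterministic
assignment rule would correlate affiliation with tree structure and
bias it), while pairing within clades cancels clade-level phylogenetic
noise from the contrast — without it, the shared-tree correlation of
TR among relatives dominates the between-replicate variance and
swamps moderate planted effects.

What the generator does *not* emulate: real ecoregion geometry and
range-map shapes, taxonomic structure of a real phylogeny, empirical
diet distributions, or spatially autocorrelated habitat suitability.
Passing pipeline tests therefore demonstrate the correctness of the
computations and the absence of design-induced artifacts, not the
ecological conclusions one would draw from real data.

## Numerical choices and limitations

* Dwell-time bookkeeping is conserved to 1e-9 Ma per branch; lineage
  depth equals root age minus tip age to the same tolerance.
* Transition matrices are clipped to [0, 1] and re-normalized row-wise
  after eigendecomposition round-off.
* Distance ties in point selection and AIC ties in model choice have
  deterministic documented tie-breaks.
* Polytomies and zero-length branches are legal throughout; zero
  branches contribute zero dwell and force state copying.
* Non-ultrametric trees are tolerated with a warning (imputed tips may
  break ultrametricity); node ages assume root age = deepest leaf.
* The package does not fit mixed models or GLS on the exported tables,
  render maps, or manipulate topology beyond reading and indexing.
* Mapping is empirical-Bayes (ML Q plugged into the conditional path
  distribution); full MCMC over Q is out of scope.
* Test and acceptance problem sizes (e.g. 10 trees × 10 simulations at
  40 tips for the end-to-end checks, 80-tip trees for ensemble means)
  are the package's chosen desk-scale study conditions; the code runs
  unchanged at 100 × 100 on hundreds of tips, just longer.
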