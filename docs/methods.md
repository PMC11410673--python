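# Methods

## The model

`netctrl` treats cortical activity as a linear time-invariant system on the
structural connectome,

    dx/dt = A_norm x(t) + B u(t),

where `x(t)` is a per-region activity vector, `A_norm` the normalized
adjacency, `B` a positive diagonal input matrix and `u(t)` the control
input.  The adjacency is normalized as

    A_norm = A / (|λ_max| + c) − I,

which rescales the spectrum so that the leading mode is marginally stable at
`c = 0` (the default: activity decays onto the dominant connectome mode) and
strictly stable for `c > 0` (`c = 0.01·|λ_max|` is the standard decaying
variant; `normalize_adjacency(..., relative=True)`).  The model assumes
linear, noise-free dynamics with time-invariant coupling — a deliberately
coarse but analytically tractable account of activity spread along white
matter.

### Optimal control energy

For a transition from `x(0) = x0` to `x(T) = xT` the optimal input minimizes

    J(u) = ∫₀ᵀ (xT − x(t))ᵀ(xT − x(t)) + ρ u(t)ᵀu(t) dt

subject to the dynamics and both endpoint constraints.  `ρ` trades
trajectory length against input magnitude (default 1, equal weighting);
`T` is the horizon (default 1).  The Pontryagin conditions reduce the
problem to a linear state–costate system with constant forcing,

    d/dt [x; λ] = [[A, −BBᵀ/(2ρ)], [−2I, −Aᵀ]] [x; λ] + [0; 2xT],

whose endpoint map is computed exactly from one augmented matrix exponential;
the unknown initial costate is obtained by solving an `n × n` linear system,
and the trajectory is then evaluated forward with a fixed-step propagator.
The reported energy is the input magnitude `∫ uᵀu dt` (ρ is a cost weight,
not part of the energy) integrated by trapezoidal quadrature on `n_steps`
samples (default 1,000; quadrature error is far below the 1% oracle
tolerance already at 250 steps).  Because the endpoint map is exact, the
forward-evaluated trajectory hits `xT` to ~1e−10 relative error; a relative
endpoint error above 1e−6 flags the result.

Two independent checks guard this solver: a discretized 400-step quadratic
program solved through its sparse KKT system (tests), and the closed-form
Gramian minimum-energy solution, `E_min = vᵀW⁻¹v` with
`W = ∫₀ᵀ e^{As} BBᵀ e^{Aᵀs} ds` and `v = xT − e^{AT}x0`, which the optimal
energy approaches monotonically from above as `ρ → ∞`.

### Control weight modes

* `uniform` — identity `B`.
* `thickness_delta` — `B_ii = 1 + d_i` for a signed Cohen's-d map of
  case–control cortical-thickness change; atrophied regions contribute less
  endogenous input.  Values `d ≤ −1` are rejected (non-positive input).
* `receptor` — `B_ii = 1 + minmax01(map)` for a non-negative density map.
* `unit_mean_map` — the map rescaled to unit mean, making a heterogeneous
  input pattern comparable to the uniform model in total input.

### Transition statistics

With the all-to-all energy table `E` (rows sources, columns targets):

* `Δ(i,j) = E(i→j) − E(j→i)`; its column means give the per-state
  reach-minus-leave score (positive: harder to reach than leave).
* `target_sd[i]` is the s.d. of row `i` (energy variability as the *target*
  varies); `source_sd[j]` the s.d. of column `j` (variability as the
  *source* varies).  Diagonals are excluded.  Under drift dynamics the
  target identity dominates cost, so target variability exceeds source
  variability; the variability test is an unpaired two-sided permutation
  t-test between the two vectors.
* Relay analysis searches single intermediates only:
  `min_k E(i→k) + E(k→j) < E(i→j)`.
* Domain tests compare a domain's median statistic against label
  permutations over the labelled states, one-sided ("higher median"), with
  add-one correction; tiny problems can be enumerated exactly.
* The energy–distance relation is the Spearman correlation between pairwise
  Euclidean state distance and energy over ordered off-diagonal pairs.

### Network-based variance and effective resistance

Effective resistance `ω_ij = (e_i − e_j)ᵀ Q (e_i − e_j)` with `Q` the
Moore–Penrose pseudoinverse of the weighted Laplacian; it is proportional to
random-walk commute time and requires a connected graph (disconnected input
raises an error naming the components).  The network variance of a map is
`var(p) = ½ Σ_{ij} p_i p_j d²` after rescaling the map to a distribution
(minimum subtracted, divided by the sum).  `ω` itself is used as the squared
distance `d²`, following the convention of the statistic's source; the
`PairDistanceMatrix.convention` field records this choice.

### Null models

*Degree-preserving*: Maslov–Sneppen swaps carry weights with the edges, so
the binary degree sequence and the weight multiset are preserved exactly;
connectivity is re-checked and failing draws resampled (up to 50 times).
Default 10 swaps per edge.

*Geometry-preserving*: edges are assigned to Euclidean-length bins (default
10, bins with fewer than two edges merged downward); a swap is accepted only
if the multiset of bins is unchanged, so the binned length histogram is
preserved exactly; weights are then re-assigned within each bin by length
rank, which preserves the weight–length relationship to high accuracy.
Because the acceptance rate of bin-constrained swaps is low on small graphs,
the attempt budget is much larger than for unconstrained swaps.

Empirical-vs-null comparisons re-normalize every null member before
computing its mean all-to-all energy and report
`p = (1 + #{null ≤ empirical}) / (1 + n_members)` for the "empirical
cheaper" direction.

### Spin nulls

Spin permutations rotate per-hemisphere spherical parcel centroids by a
uniform random rotation (mirrored across hemispheres) and re-assign each
parcel the value of the nearest rotated parcel (`assignment="nearest"`, the
standard method) or by optimal bijective matching
(`assignment="bijective"`, which preserves the value multiset — hence mean
and variance — exactly).  Nearest assignment can duplicate and drop values;
on coarse parcellations (a few dozen parcels) this inflates or deflates the
total input capacity of null modulation maps enough to confound
location-specific tests, which is why the planted-effect recovery analysis
uses bijective assignment.  Screening compares, per ordered state pair, the
energy under the empirical map's control weights against the rotated-map
distribution with two one-sided add-one-corrected p-values (facilitation
and disfacilitation) and summarizes per target the percentage of sources
significant at `alpha` (default 0.05).  The empirical map is never part of
its own null distribution.

### Predictors and dominance

Each state is characterized by map mean and s.d., Spearman correlations with
binary degree, strength, participation coefficient
(`P_i = 1 − Σ_m (s_im/s_i)²`, 0 for isolated nodes) and a supplied cortical
hierarchy map, and its network variance.  Partial Spearman correlations of
each characterization with mean energy-to-reach control for map mean and
s.d. (rank regression residuals).  Dominance analysis fits all `2^p − 1`
submodels over the five characterizations and averages each predictor's
incremental R² within and then across submodel sizes; the dominances sum to
the full-model unadjusted R² (machine precision).  The decomposition is
exact for unadjusted R² only — a conservation property asserted in tests —
so unadjusted R² is partitioned even where adjusted R² is quoted elsewhere.

## Synthetic data: what it emulates, and what it does not

The generators produce, from a single seed: spherical per-hemisphere parcel
centroids (each hemisphere covers the full unit sphere, as cortical surfaces
do after spherical inflation — this is what makes spin rotations
value-preserving — with the two hemispheric shells placed side by side in
3-D); spatially embedded connectomes with an exact edge count at the target
density (default 68 nodes, 27%), exponential distance-dependent connection
probability (`exp(−d/40 mm)`) and lognormal weights damped by the same
kernel, giving the weight–length anticorrelation of tractography networks;
participant ensembles (multiplicative weight noise, small edge
replacements); smooth activation maps built by distance-kernel mixing of
white noise, with per-map mean and s.d. drawn log-uniformly from
(0.2, 6.0) × (0.1, 3.0) and *coupled* through a shared magnitude position —
meta-analytic association maps are strongly magnitude-heterogeneous across
terms, and a term's overall prevalence scales its whole map, which is what
makes transition energy track inter-state distance so tightly; receptor-like
maps (positively skewed, non-negative) and atrophy-like maps (signed,
extremes at +0.87/−0.59 Cohen's d) with optional planted effect regions
recorded as ground truth.

Not emulated: realistic modular/hub topology beyond what geometry induces,
hemispheric functional asymmetries, receptor co-expression structure,
measurement noise in the maps, and subcortex.  Passing tests therefore show
that the algorithms behave correctly under the stated geometric and
statistical conditions — not that any particular empirical claim holds in
real data.

## Numerical choices and degenerate inputs

* Boundary systems with condition number above 1e12 raise a conditioning
  error rather than returning garbage; the Gramian solver does the same.
* Symmetry is enforced as `(A + Aᵀ)/2` with a warning when asymmetry
  exceeds 1e−8; diagonals are zeroed.
* All-zero adjacency, constant maps (for network variance, Moran's I, or
  receptor scaling) and duplicate states (for the distance relation) raise
  explicit degenerate-input errors.
* Consensus bin count defaults to `⌈√Ē⌉` for mean participant edge count Ē.
* Rank ties use average ranks throughout.
* Permutation p-values use the add-one correction except in exhaustive
  enumeration mode, where the exact tail fraction is returned.
* Every stochastic routine takes an explicit seed; ensembles derive member
  seeds from one generator, so fixed seeds give bit-identical outputs.

## Problem sizes used in the shipped analyses

The test suite and `scripts/acceptance.py` run the pipeline at 20–68 nodes
with 4–12 states, 20–99 null members and 25–200 spin rotations — scaled-down
study conditions chosen so the full analysis remains a few minutes of
single-CPU compute while every qualitative direction (energy–distance
coupling, target-dominated variability, the efficiency advantage of
spatially embedded wiring, planted-effect recovery) is reproduced.  The
planted-effect recovery simulation uses a 50-parcel sphere: with
substantially fewer parcels the number of effectively distinct spin
rotations is too small for any map to reach p ≤ 0.05 against 200 rotations,
regardless of effect size.

## Known limitations

* The linear model ignores nonlinearity, noise and time-varying coupling;
  energies are meaningful comparatively, not biophysically.
* Nearest-assignment spin nulls are approximate on coarse parcellations
  (see above); bijective assignment is exact on moments but slightly relaxes
  spatial-autocorrelation preservation.
* The geometry-preserving null preserves the length histogram only at bin
  resolution.
* Dominance analysis is exhaustive and limited to 15 predictors.
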