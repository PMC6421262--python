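# Methods

## The problem

A focal (ectopic or paced) heartbeat starts at one point of the ventricular
surface and spreads outward. Given a body-surface potential map (BSPM — the
electrodes × time-samples matrix recorded during one beat) and the patient's
geometry, we want the origin of that beat. `ectoloc` implements the
template-matching ("fastest route") family of solutions: every node of the
heart mesh is tried as a candidate origin, its activation sequence is
simulated, mapped to simulated electrode signals, and compared with the
measured map. The candidate whose simulated map matches best is the estimated
origin. Two comparison rules are implemented:

* **fra_cc** — Pearson correlation between the two maps, flattened jointly
  over electrodes and samples (the classic rule);
* **fra_dtw** — the reciprocal total cost of a multichannel dynamic time
  warping (DTW) alignment of the two maps (the warping rule). Warping
  compensates for local conduction-velocity (CV) errors that a
  uniform-velocity candidate model cannot represent.

## Models and their assumptions

### Activation model (fastest route)

The heart surface is a closed triangulated mesh carrying both epicardium and
endocardium. Excitation travels along mesh edges at a global CV of 0.8 m/s
(0.8 mm/ms); explicit wall-crossing connector edges conduct at half speed,
mimicking slower transmural propagation. Spherical regions can scale the
local CV (membership decided at edge midpoints; overlapping regions multiply;
a `cv_factor` of 1/3 slows three-fold). All-pairs fastest-route times are
computed by Dijkstra's algorithm on this weighted graph; the activation
sequence of focus *f* is row *f* of that matrix. Assumptions: no fiber
anisotropy beyond the transmural factor, no curved-front (eikonal)
correction, single initiation site (an elementwise-minimum helper exists for
forward-simulating multifocal beats, but the search is single-focus).

### Source and forward model (equivalent dipole layer)

During depolarization each surface element is a uniform double layer that
switches on at its activation time τ and stays on (Heaviside kernel,
H(0) = 1; no repolarization, so T waves are out of scope). The
infinite-medium lead field of a triangle is its signed solid angle at the
electrode (computed with the exact two-argument-arctangent formula), lumped
barycentrically to vertices and scaled by 1/4π. Node area weights are the
barycentric third of incident triangle areas, kept explicit so the transfer
matrix is "per unit area". Because the surface is closed, a fully activated
layer produces *zero* external field to machine precision — this analytic
cancellation is asserted in the tests and acceptance script. A bounded
homogeneous torso is available through a collocation boundary-element solve
(deflated singular Neumann system, zero-mean potential gauge, interior
evaluation by the representation formula); the localization studies use the
infinite medium, since the per-column normalization absorbs the bulk
conductivity and the homogeneous-torso correction changes patterns only
mildly at realistic standoffs.

### Normalization and scoring

Both reference and candidate maps are normalized column-wise: each time
sample's electrode vector is centred and scaled to unit population variance
(`sklearn.preprocessing.scale` on axis 0). Columns whose variance is at
float-cancellation level (≤ 1e-10 of the largest column's) are set to zero
rather than having noise amplified to unit variance — this matters for the
fully-depolarized tail of a simulated beat, which is analytically zero.
Candidate sequences are linearly time-rescaled so their duration equals the
reference duration; this is the duration matching that makes the DTW setting
one of equal-length sequences.

### Dynamic time warping

The local cost between two time samples is the euclidean norm of their
electrode-vector difference, so the whole multichannel map is aligned at
once. Feasible paths start at (1,1), end at (T,T), are componentwise
nondecreasing, and move in steps {(1,0),(0,1),(1,1)}; consequently
T ≤ L ≤ 2T−1. The optimum is found by the standard dynamic program on an
accumulated-cost matrix with a sentinel row/column, and the path is recovered
by backtracking from (T,T). No global band constraint is applied.

Numerical choices: ties in the backtracking argmin prefer the diagonal
predecessor, then the vertical — identical inputs therefore yield the plain
diagonal path, which the identity tests rely on. At the boundary rows the
backtracking moves are forced horizontal/vertical. Costs accumulate in
double precision in path order, so the DP total is bitwise equal to the
brute-force minimum over enumerated paths (the test suite checks exact
equality against an exhaustive enumeration oracle; path counts for
T = 1, 2, 3 are the central Delannoy numbers 1, 3, 13). The total cost is
independently re-summed along the returned path inside `dtw_distance`
(relative tolerance 1e-12). The O(T²) recurrence has a loop-carried
dependency, so the inner loop is numba-compiled.

Maps are scored by 1/c*, the reciprocal optimal cost; an exact match (c*=0,
which occurs under inverse crime) maps to +∞ and wins the argmax. Ties are
broken toward the lowest node index and reported.

## Synthetic geometry

`generate_heart` builds a ventricle-like closed surface: an outer (epi) and
inner (endo) half-ellipsoid shell — defaults 90 mm apex-to-base, 50 mm
equatorial radius, 10 mm wall — joined at a basal rim through an unlabeled
ring of vertices (the cut face of the wall, standing in for the valve
annulus). No mesh edge joins epi to endo directly; explicit connector edges
(one per endo vertex, to its nearest epi vertex) provide the transmural
crossings and are the only transmural-flagged edges. On-surface geodesics
exclude them, so epi-to-endo distances route around the rim, which matches
how localization errors are measured for leads separated by the wall. A
small seeded vertex jitter (10 % of the mean spacing) breaks the rotational
symmetry. `n_subdiv=3` gives ≈ 750 nodes — the default study resolution.

Electrodes are placed quasi-uniformly (farthest-point sampling) on the
vertices of a closed ellipsoidal torso surface enclosing the heart at a
standoff (default 40 mm; the generator supports the full 240-electrode
clinical layout, and the studies here use 64 for speed).

What the generator does *not* emulate: two ventricles with a septum, fiber
anisotropy, atria, lungs/blood conductivity compartments, measurement noise
(evaluated and found immaterial for these global-map scores), and real torso
shape. Passing tests therefore demonstrate internal correctness of the
machinery and the *mechanism* of the warping advantage, not clinical-grade
error magnitudes.

## Study scenarios

**Canonical slow-CV demonstration** (`make_slow_cv_demo`): on the jitter-free
geometry, the focus is the epicardial apex and a spherical patch of radius
20 mm with CV reduced three-fold is centred 60 mm up a meridian. The apical
focus makes the patch *gate* the expanding wavefront (delayed isochrones lie
downstream of it). The reference map is simulated with the patched
conduction field; both searches then use the unaltered times matrix. In this
configuration the correlation search lands several millimetres away from the
focus, displaced *away* from the patch (matching the patched sequence's
late arrival there is cheapest for a uniform-CV candidate that starts
farther from the patch), while the warping search recovers the focus
exactly and its reciprocal-distance map has a much smaller top-percentile
plateau. On this smooth single-ventricle surface a mid-lateral focus lets
the wavefront flow around the patch and the correlation search remains
exact — the displacement magnitude is geometry-specific.

**Paired battery** (`scenario_battery`): 20 randomized scenarios emulating
paired pacing-site localization in cardiomyopathy patients. Foci alternate
between an epicardial lateral/apical site (LV-lead analogue) and an
endocardial apical site (RV-lead analogue). Each scenario adds one slow
patch placed basally of the pacing site (where post-infarct scar typically
sits), radius U(15, 25) mm, CV reduction log-uniform on [1.5, 6] (geometric
centre 3.0), centre 45–75 mm from the focus. One master seed spawns
per-scenario seeds; infeasible draws are regenerated with an advanced seed
and counted. The summary reports mean/SD/median/quartiles/min/max of the
paired geodesic errors, the correct-surface ratio, BCa confidence intervals
per statistic, and the Wilcoxon signed-rank p. At these conditions the
warping search is exact in every scenario while the correlation search errs
in roughly half of them (by up to ~15 mm), making the paired Wilcoxon test
strongly significant; because the correlation search is error-free in the
other half, the *median* correlation error can still be 0 — a degeneracy of
the single-patch design (real clinical data carry pervasive model error and
give nonzero medians for both methods).

## Statistics

* Quartiles are linear-interpolation (type 7); mean/SD use the n−1
  convention.
* Wilcoxon signed-rank: zeros dropped; exact two-sided p for n ≤ 25 via the
  exact null distribution of the positive-rank sum (dynamic programming over
  doubled midranks, so ties are handled); continuity-corrected normal
  approximation with tie correction otherwise (worst-case gap to exact at
  n = 25 measured below 0.01).
* BCa bootstrap (default 1000 replications, Mersenne-twister generator):
  bias correction z₀ from the fraction of bootstrap replicates below the
  estimate (half-counting equals), acceleration from jackknife skewness,
  2.5/97.5 adjusted percentiles. All-equal samples collapse to a zero-width
  interval. Empirical coverage for the median of n = 20 lognormal samples is
  ≈ 94–95 % over 200 Monte-Carlo repetitions.

## Degenerate inputs and tie-breaks

Zero-variance maps score a correlation of 0 with a warning; all-zero
activation sequences cannot be duration-scaled (rejected); a span that would
truncate the slowest node is rejected; float round-up of scaled activation
times past the target span is clamped, so the latest node is always on in
the final sample; disconnected graph components surface as infinite travel
times and are rejected by the full search.

## Problem sizes

Default study sizes — ≈ 750-node hearts, 64 electrodes, 1 ms sampling,
≈ 120–220 sample references, 20 inverse-crime foci, 20 battery scenarios,
1000 bootstrap replications — were chosen so the whole test suite and the
acceptance script each run in minutes on one CPU while staying at the
coarse end of clinically plausible discretizations.

## Known limitations

Single-ventricle topology (no septum, no LV/RV chamber labels — the
correct-surface ratio is epi/endo only); depolarization-only sources;
homogeneous conductor in the localization studies; edge-graph geodesics
(upper bounds on exact polyhedral geodesics, consistent with the activation
model); the correlation-failure magnitude depends on mesh resolution and
focus/patch geometry, so only its direction and the paired comparison are
asserted, not millimetre values.
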