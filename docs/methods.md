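# Methods

`optotract` implements the computational chain of histology-guided
("optogenetically validated") tractography for cortico–subcortical
pathways, together with the point-process analysis of subthalamic spike
trains under photostimulation.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not emulate.

## 1. Terminal geometry of streamlines

A whole-brain tractogram is reduced to a candidate pathway in three steps.

**Seed selection.**  Streamlines are kept when at least one vertex of the
polyline lies within a sphere of diameter 1 mm (default) centred on the
injection site inside the deep nucleus.  The boundary is inclusive and the
test is point-based, not segment-based; at typical streamline step sizes
(≤ 0.5 mm) the difference is negligible against a 0.5 mm radius.

**Depth and angle.**  For each selected streamline the *last* crossing of
the cortical surface before its cortical terminal is located.  Crossings
are detected as sign changes of the signed surface distance (offset from
the closest mesh point projected on the face normal — well defined for
open sheets) sampled at the polyline vertices, then refined by bisection
on the crossing segment (12 iterations, ≈ segment/4096 resolution).  Two
quantities characterize the terminal:

* **Δ (depth, mm)** — arc length along the polyline from the crossing to
  the terminal point;
* **θ (angle, °)** — angle between the terminal tangent and the *inward*
  surface normal, so a fiber entering perpendicular to the cortex has
  θ = 0.  The tangent is the principal axis of the last k = 3 points
  (single-segment tangents are noisy at step scale); the normal is
  barycentrically interpolated at the crossing from vertex normals.

Δ is interpreted in millimetres throughout (primate cortical thickness is
2–3 mm; micrometre depths would be sub-cellular).

**Filtering.**  A terminal passes the window (Δ₀, θ₀) when
|Δ − Δ₀| ≤ tol_Δ and |θ − θ₀| ≤ tol_θ.  Default tolerances are half the
*minimal* spacing of the search grid — ±0.5 mm for depths {2, 3} mm and
±7.5° for angles {0, 30, 45}° — so that adjacent windows touch but never
overlap; overlapping windows make the grid argmax ill-defined exactly at
the planted parameter (a terminal at 30° would sit on the boundary of the
45° window, and sub-millidegree measurement noise would split otherwise
identical objective values).

**Density maps.**  Each kept terminal deposits unit mass at its crossing
vertex; with smoothing radius s > 0 (default 2 mm) the mass is spread over
the geodesic neighborhood with Gaussian weights (σ = s/2), renormalized
per terminal.  Total map mass equals the terminal count exactly — the
conservation law the tests enforce at 1e-9.

## 2. Histology block and fluorescence maps

Serial sections (every 8th 40 µm section → 0.32 mm default spacing) are
segmented per slice (Otsu per section, or one fixed global threshold) and
stacked into an anisotropic voxel block.  Gaps between sampled sections
are *not* interpolated; volume statistics are computed on the sampled
slabs, which is unbiased for volume fractions.  Per-region statistics are
plain voxel counting: a region's *share* of all fluorescent volume (shares
sum to 100% including an "unassigned" row) and the fluorescent *fraction*
of the region's own volume.

Fluorescence is projected to the cortical surface by assigning each
fluorescent voxel's volume to its nearest vertex when that vertex lies
within 3 mm (default cap, limiting leakage across sulci); farther volume
is logged as unassigned, so projected + unassigned equals the block total
exactly.

## 3. Local correlation and (Δ, θ) optimization

Tractography density and histology fluorescence maps live on the same
surface and are compared by a per-vertex Pearson correlation over the
geodesic neighborhood of radius 3 mm (default; the comparison is stable at
2–4 mm).  Geodesic distances are shortest paths along mesh edges
(Dijkstra); the approximation error is negligible when the radius is
several edge lengths.  A vertex is *undefined* when its neighborhood has
fewer than 3 vertices or zero variance in either map; undefined vertices
are excluded from area sums.  The **correlated area** of a region is the
sum of vertex areas where r strictly exceeds the threshold (0.5 default).

The optimizer evaluates every (Δ, θ) grid cell: filter terminals → density
map → local correlation against that subject's histology map → correlated
area in the region; the objective is the arithmetic mean across subjects,
and ties break toward smaller θ, then smaller Δ.  No multiple-testing
control is applied — the optimization is a selection, not an inference,
and reported r values are descriptive.

The whole-target connectivity report applies each region's optimal window
to streamlines intersecting the full target mask and reports, per region,
its share of all kept fibers (sums to 100% per hemisphere) and the
fraction of the region's surface within the density smoothing radius of at
least one terminal ("projecting" surface).  Means and sems (n − 1
denominator) are taken across hemispheres.

## 4. Spike-train photosensitivity

Units fire tonically; the OFF (pre-stimulation) period is modeled as a
Poisson process — constant rate by default, with piecewise-constant and
Gaussian-kernel (reflection edge-corrected, Λ exact via the normal CDF)
intensities available.  By the time-rescaling theorem, τ_k = Λ(t_k) − Λ(t₀)
is unit-rate Poisson under a correct model.  Four residual tests check
that hypothesis, each at Bonferroni level α/4 (α = 0.05 default), with
rejection of any test rejecting the model:

1. **uniformity** — KS of τ/Λ-span against Uniform(0,1);
2. **exponentiality** (Berman) — u_k = 1 − exp(−Δτ_k) against Uniform(0,1);
3. **independence** — Fisher-z on the lag-1 correlation of the u_k;
4. **counting band** — sup |N(s) − s| over [0, Λ-span] against the
   distribution of sup |W| for standard Brownian motion (alternating theta
   series).  The Brownian-*motion* law is the correct unconditional limit
   here: the endpoint deviation (N(Λ) − Λ)/√Λ is asymptotically standard
   normal, so a Brownian-bridge (Kolmogorov) band would be strongly
   anti-conservative.  When the model was estimated from data of
   integrated mass Λ_fit, the band is widened by √(1 + Λ/Λ_fit) to absorb
   plug-in rate error (delta method); the event-based tests are
   scale-invariant or insensitive at realistic estimation error and need
   no correction.

Below 10 events the three event-based tests are skipped (underpowered
flag); the counting band, valid for any event count, still runs — a
silenced unit (empty ON period) is therefore correctly rejected, since its
centered counting process drifts to −Λ.

**Classification.**  The OFF model is first validated on itself: a model
fitted on the first OFF half is tested on the held-out second half
(projected as its time-averaged constant rate — exactly the fitted model
for the constant kind).  If the self-check rejects, the unit is
*unclassifiable* (excluded from fractions).  Otherwise ON spikes are
rescaled under the full-OFF model; the unit is **photosensitive** iff that
fit is rejected.  Pulse-locked structure (5 ms pulses at 130 Hz) is not
modeled; the analysis operates at the period-rate scale.

**Population statistics.**  The photosensitive fraction is k/n over
classifiable units.  Firing rates of photosensitive units over
(OFF, ON, POST) enter a one-way repeated-measures ANOVA with
Greenhouse–Geisser correction (fractional dfs always reported), Tukey HSD
pairwise comparisons using the within-subject error term and studentized
range distribution, and a Shapiro–Wilk test on the per-unit ON−OFF
differences.  The ON change is the mean of per-unit percentages.  Paired
fluorescence measures are compared with the exact two-sided Wilcoxon
signed-rank test (exact null up to n = 25, zeros dropped); percentages are
rounded to one decimal and p values to three in reports.

## 5. Synthetic data: what it emulates, and what not

The generators provide every input with known ground truth:

* **Surface** — a 30 × 30 mm sinusoidally folded sheet (amplitude 1.5 mm,
  wavelength 15 mm) so normals vary and θ filtering is non-trivial (sphere
  normals would make θ degenerate with position); labels grow from random
  seed vertices by multi-source shortest paths, giving contiguous regions.
* **Tractogram** — pathway streamlines run from the deep seed point
  through the surface, ending exactly Δ* beyond the crossing with terminal
  direction at θ* to the inward normal (plus optional Gaussian jitter);
  decoys come in equal thirds missing the seed sphere, at wrong depth
  (+2 mm), or wrong angle (+35°), probing each filter clause separately.
* **Histology** — ribbon voxels (0–2.5 mm below the surface, judged at the
  nearest vertex) are lit by Bernoulli thinning with probability
  proportional to the origin map, scaled by the inverse of each vertex's
  candidate-voxel count; without that calibration surface curvature biases
  concave vertices to capture up to ~1.6× more ribbon volume and the
  generator→projection round trip decorrelates.
* **Spikes** — OFF/POST at baseline rate (default 18.2 Hz), ON at
  baseline × multiplier (default 1.449, i.e. a +44.9% step), 60 s periods;
  Poisson via exponential gaps or gamma-renewal with matched mean rate
  (ISI CV = 1/√shape).

Not emulated: realistic cortical folding, diffusion physics and streamline
propagation errors, staining variation, slice-to-slice misregistration,
pulse-locked spiking, bursting or non-stationary baselines.  Passing tests
therefore demonstrate correctness of the *computational chain* under its
stated assumptions, not robustness to those real-data effects.

## 6. Problem sizes and determinism

Simulation experiments use a 20 × 20-vertex sheet per subject, 50 pathway
plus 30 decoy streamlines, two subjects, and 100 seeds per jitter
condition for grid recovery; point-process calibration uses 1000 unit-rate
replicates of ~200 events and 100 power replicates — sizes at which the
binomial error of the reported rates is a few percent.  Every generator
and experiment is a pure function of (parameters, seed); all randomness
flows from `numpy.random.default_rng` seeded from the run configuration.

## 7. Known limitations

* Geodesic distances are graph shortest paths, slightly overestimating
  true surface geodesics on coarse meshes.
* The crossing search assumes the terminal run does not re-cross the
  surface within Δ of the last crossing (true for gentle folds and
  Δ ≤ 3 mm).
* The nearest-vertex voxel→surface assignment is Euclidean; across tight
  sulci it can leak volume (mitigated by the 3 mm cap, not eliminated).
* Time-varying OFF models (piecewise, kernel) are projected to their mean
  rate when extrapolated beyond the fitted window; genuinely
  non-stationary baselines would require a covariate model instead.
* The exact Wilcoxon p is computed after dropping zero differences, the
  common convention; ties among non-zero differences use mid-ranks.
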