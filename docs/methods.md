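# Methods

## Scope and model

`smtpop` analyzes fast single-molecule tracking (SMT) of a nuclear protein
recorded in many cells at once, as acquired with HILO illumination and
stroboscopic excitation on a TIRF microscope.  The measurement model is:

- Each molecule occupies one diffusive state with coefficient `D` and moves by
  2D Brownian motion; between consecutive frames (interval `dt`) its per-axis
  displacement is Gaussian with variance `2 D dt`.
- Localization adds independent per-axis Gaussian error `sigma`, so the
  *observed* squared radial lag-1 displacement `r²` is exponential with mean
  `4 (D dt + sigma²)`.
- Detection is restricted to an axial slab of depth `dz`; a molecule whose
  z-walk leaves the slab is lost.  Track length is otherwise
  photobleaching-limited, modeled as geometric with mean `mean_track_len`
  localizations.

A cell's **diffusion spectrum** is a normalized occupation vector over a fixed
log-spaced grid of diffusion coefficients (101 points over 0.01–100 μm²/s by
default).  The **fraction bound (FB)** is the occupation mass strictly below a
threshold, 0.15 μm²/s by default, the mobility regime indistinguishable from a
chromatin-tethered histone control.

## Spectrum inference

Occupations maximize the finite-mixture likelihood of a cell's pooled lag-1
jumps over the fixed grid:

    L(w) = prod_i  sum_k  w_k · Exp(r²_i | mean 4 (D_k dt + sigma²))

fitted by EM from a uniform start (relative log-likelihood tolerance 1e-8,
at most 2000 iterations).  Only lag-1 jumps are used — at 3–5 localizations
per track there is little multi-lag information, and lag-1 keeps the
likelihood exact.  `sigma` is a configured constant; a calibration helper
estimates it from an immobile control as `sqrt(mean r²/4 − D dt)`.

For speed, jumps are histogram-compressed onto shared log-spaced bins
(600 bins spanning the pooled range, geometric bin centers, exact zeros kept
in their own bin) so that all cells of a dataset share one likelihood matrix
and EM runs batched across cells.  The compression resolution is far below
the grid spacing; batched fits reproduce unbinned per-cell fits to within
0.002 in FB at the default conditions.  An optional Dirichlet
regularization (`dirichlet_alpha`) provides a state-array-style smoothed
variant; it is off by default.

### Defocalization correction

Fast molecules leave the detection slab between frames, so observed jumps
over-represent slow states.  The survival probability of a molecule with
coefficient `D` starting uniformly in an absorbing slab of depth `dz` is

    S_D(t) = sum_{k odd} 8/(k² π²) · exp(−k² π² D t / dz²),

evaluated by the series where it converges quickly and by the boundary-layer
approximation `1 − (4/dz)·sqrt(D t/π)` for `π² D t/dz² < 0.04`.

Because trajectories carry several jumps, the number of observed lag-1 jumps
per molecule is

    E(D) = sum_{m≥1} q^m · S_D(m·dt),     q = 1 − 1/mean_track_len,

and pooled jump counts per state are proportional to `w · E(D)`.  The
estimated occupations are therefore divided by `E(D)/E(0)` and renormalized.
Dividing by the single-frame survival `S_D(dt)` instead (available as
`mode="single_frame"`) under-corrects badly at mean track length 4 —
measured FB ≈ 0.68 at a true FB of 0.40 — because it ignores the compounding
of slab losses over a track's lifetime; the jump-count weights recover the
truth to within ±0.015 at population scale.

### QC

Cells need at least `min_jumps` (default 100) pooled lag-1 jumps; cells below
the gate are excluded and counted.  Gap-spanning localization pairs are never
turned into jumps.

## Synthetic data generator

The generator defines the study conditions every validation runs under:

- Acquisition defaults: `dt = 0.01 s`, `sigma = 0.035 μm`, `dz = 0.7 μm`,
  pixel 0.11 μm, mean track length 4.  These are typical for stroboscopic
  HILO fast SMT; they are configurable, and nothing downstream assumes them.
- Two-state mixtures with `D_bound = 0.01` and `D_free = 5 μm²/s`; per-cell
  FB drawn from a truncated normal around the condition mean (SD 0.05,
  emulating cell-to-cell heterogeneity), ~300 generated trajectories per
  cell, 150 cells per condition.
- The z-walk is simulated in 4 substeps per frame with Brownian-bridge
  boundary-crossing probabilities per substep, so first-exit statistics match
  the continuous-absorption series used in the correction (validated against
  the series to <2% in expected jump count).
- Nuclei are reflecting disks laid out without overlap in square FOVs;
  positive (stem-like) marker cells are smaller and brighter, with bimodal
  marker intensities (means 1000 vs 100, SD 50).
- State is fixed per trajectory (the statistic is occupation-based, not
  rate-based); optional Markov switching is deliberately not implemented.
- Tracks shorter than 2 localizations are discarded at generation, as they
  would never be observed as trajectories.

### DR/PAPA classes

PAPA (proximity-assisted photoactivation) classes are assigned
statistically, not photophysically: each trajectory is an "oligomer" with
probability `oligomer_fraction`, and PAPA labels are drawn preferentially
from oligomers with an enrichment factor `e` (an oligomer's PAPA probability
is `share·e/(f e + 1 − f)`).  `PapaDesign.from_class_fb` solves the monomer
FB and enrichment in closed form so the DR and PAPA classes carry requested
bound fractions (defaults target 0.41 vs 0.52).  Labeled trajectories are
relocated into read windows of an alternating violet-DR / green-PAPA
schedule; classing then proceeds from data alone via the window containing a
trajectory's first localization, with truncation at window boundaries.

### What the generator does not emulate

Motion blur (stroboscopic excitation is treated as instantaneous sampling),
dye photophysics and reactivation kinetics, state switching within a track,
non-disk nuclear shapes, out-of-focus PSF changes, and detection/linking
errors under dense labeling.  Passing tests therefore demonstrate that the
estimator stack recovers truth *under the stated measurement model*, not that
it is robust to every real-data artifact.

## Population statistics

- The resampling unit is always the cell.  The population point estimate is
  the FB of the full-sample mean spectrum (equal to the mean of per-cell
  FBs); the 95% CI is the 2.5/97.5 percentile over B = 1000 cell resamples.
- Group FB comparisons use a two-sided Mann–Whitney U by default; a
  difference-of-means permutation test (10⁴ permutations) is the alternative.
- The PAPA comparison is paired when both classes pass QC in ≥3 common
  cells: the permutation null flips per-cell DR/PAPA labels (sign flips of
  per-cell deltas, 2·10⁴ flips).
- Heatmap ordering sorts by decreasing FB (ties by cell key); hierarchical
  mode is Ward linkage on Euclidean distances between occupation vectors.
- FB–feature correlations are Pearson with a least-squares line; cells with
  undefined features are dropped and counted, zero-variance features yield an
  explicitly undefined result.
- Significance stars follow the usual 0.05/0.01/0.001/0.0001 ladder.

## Imaging stages

Spot detection is Laplacian-of-Gaussian candidates refined by
background-subtracted centroids (≤0.1 px error on noiseless spots). Linking
is greedy nearest-neighbor per frame pair, smallest distance first, ties to
the lower trajectory id, default radius `2.45·sqrt(4 D_max dt)` and no gap
closing.  Nuclear segmentation is Otsu → hole filling → distance-transform
watershed → size filter; features are pixel-count areas, centroid-based mean
two-nearest-nuclei distances (undefined below 3 nuclei per FOV), and
per-label mean channel intensities.  Marker classes come from per-FOV Otsu
thresholds by default (recorded per FOV); trajectories belong to the nucleus
containing the majority of their localizations, ties discarded and counted.

## Numerical choices and degenerate inputs

- Spectra are renormalized after correction; sums are enforced to 1 within
  1e-9 and FB is nondecreasing in the threshold by construction.
- Empty populations, all-background images, single-cell bootstraps,
  constant-intensity Otsu inputs and zero-jump cells all return explicit
  empty/flagged results rather than raising.
- All randomness flows through `numpy.random.default_rng` seeds; identical
  config + seed gives byte-identical trajectory tables and report payloads.

## Validation scales

The canned experiments (`smtpop.experiments`) use: 150 cells × 4 FB settings
for recovery; 60 cells/group for control separation; 100 repeats × 50 cells
(B = 500) for bootstrap coverage; 20 seeds × 120 cells for marker
stratification; 200 statistic-level repeats for null calibration; 10 seeds ×
120 cells for PAPA power and 200 reduced-scale repeats (12 cells) for its
type-I rate, which does not depend on scale.  These sizes were chosen to
estimate each property with comfortable Monte-Carlo margins while keeping a
full validation run under ~15 minutes on one core.

## Known limitations

- The estimator inherits the finite-mixture identifiability limits of
  exponential mixtures: per-cell spectra at a few hundred jumps carry ~0.1
  FB noise, and component positions between grid neighbors are not resolved.
- The defocalization weights assume the geometric bleaching model and a
  uniform axial start; strongly non-geometric bleaching would mis-weight.
- Manual, biology-driven QC of abnormal cells is not modeled; QC here is
  purely count-based.
- Kinetic rates (k_on/k_off), residence times and anomalous exponents are
  out of scope.
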