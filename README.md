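# smtpop

Diffusion-spectrum analysis of fast single-molecule tracking (SMT) in
heterogeneous cell populations — organoid-derived monolayers and similar
multicellular systems where a transcription factor's chromatin binding varies
cell by cell.

## The problem and who this is for

Fast SMT images individual fluorescently tagged protein molecules at ~100
frames/s and links them into short trajectories (3–5 localizations each).
In a differentiating monolayer, hundreds of cells are recorded per session,
and the question is quantitative: *what fraction of molecules is immobile —
i.e., chromatin-bound — in each cell, and how does that fraction vary with
cell state, morphology and molecular interactions?*  This package is for
microscopists and computational biologists who have trajectory tables (or
raw frames plus a bulk-labeled nuclear channel) and want per-cell diffusion
spectra, bound fractions, and defensible population statistics.

## Model and statistic

Per cell, pooled lag-1 squared displacements are modeled as a mixture over a
fixed log-spaced grid of diffusion coefficients D (101 points, 0.01–100
μm²/s).  Under 2D Brownian motion with frame interval Δt and localization
error σ, a state's squared radial jump is exponential with mean
4(DΔt + σ²); occupations **w** maximize

&nbsp;&nbsp;&nbsp;&nbsp;L(**w**) = ∏ᵢ Σₖ wₖ · Exp(r²ᵢ | 4(DₖΔt + σ²))

via EM, are corrected for defocalization (loss of fast molecules from the
axial detection slab of depth Δz, weighted by the expected number of
observed jumps per molecule), and renormalized.  The **fraction bound** is

&nbsp;&nbsp;&nbsp;&nbsp;FB = Σ_{Dₖ < 0.15 μm²/s} wₖ ,

with uncertainty from bootstrapping whole cells.  DR-vs-PAPA illumination
classes (direct reactivation vs proximity-assisted photoactivation) compare
the bound fraction of all molecules against that of self-associated ones.

Because real deposited SMT datasets are far beyond desk scale, the package
ships a first-class synthetic generator (`smtpop.synthdata`) that emulates
the acquisition — Brownian states, localization error, geometric
photobleaching, axial-slab truncation, nuclear layouts, bimodal marker
intensities, DR/PAPA schedules — with full ground truth, so every stage is
testable end to end.  See `docs/methods.md` for the model details.

## Worked example

```python
from smtpop import (AcquisitionParams, DiffusionGrid, PopulationConfig,
                    simulate_population, extract_jumps, infer_spectra,
                    bootstrap_summary)
from smtpop.popstats import ExperimentSet

acq = AcquisitionParams()                # dt=0.01 s, sigma=0.035 um, dz=0.7 um
config = PopulationConfig(n_cells=60, n_trajectories=300, fb_mean=0.40)
dataset = simulate_population(config, acq, seed=42)

jumps = extract_jumps(dataset.trajectories, acq)
spectra, excluded = infer_spectra(jumps, DiffusionGrid.default(), acq)
exp = ExperimentSet.from_spectra(spectra)
s = bootstrap_summary(exp, B=1000, seed=7)
print(f"mean FB {s.mean_fb:.3f} (95% CI {s.ci_low:.3f}-{s.ci_high:.3f}, n={s.n_cells})")
```

prints

```
mean FB 0.403 (95% CI 0.382-0.426, n=60)
```

a cell-bootstrapped mean bound fraction of 0.403 against a configured truth
of 0.40 — the estimator recovers the simulated chromatin-bound share well
within the CI.  The same flow as numbered drivers, each writing tables under
`results/`:

```bash
python analysis/01_simulate_dataset.py      # trajectories + ground truth
python analysis/02_infer_spectra.py         # per-cell spectra and FB
python analysis/03_population_statistics.py # bootstrap CI, FB-morphology correlations
python analysis/04_marker_stratification.py # marker+/- class FBs and test
python analysis/05_papa_comparison.py       # DR vs PAPA bound fractions
```

Step 04, for instance, reports
`positive: FB 0.492 (95% CI 0.460-0.521, n=31)` vs
`negative: FB 0.395 (95% CI 0.377-0.414, n=89)`, p = 6.3e-06 — the
marker-positive (stem-like) class carries the higher bound fraction it was
simulated with (0.48 vs 0.38).

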