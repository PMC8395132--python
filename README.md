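# smtrack

Single-molecule tracking (SMT) analysis for membrane-protein lateral
diffusion: subpixel spot localization, frame-per-frame linking,
mean-square-displacement (MSD) analysis, motion-mode classification,
population statistics, and dual-channel Pearson colocalization — together
with a synthetic-data module that generates trajectories, movies and
two-channel images with known ground truth, so every stage of the chain is
verifiable by parameter recovery.

The intended users are microscopists and image analysts working with
objective-type TIRF SMT of membrane proteins (tetraspanins, receptors,
lipid-anchored probes), where individual fluorophore-labeled molecules are
imaged at ~100 ms per frame and their motion alternates between free
(Brownian) diffusion and transient confinement in membrane microdomains.

## The models

Trajectories are analyzed through the time-averaged MSD at lag `t`:

* Brownian diffusion: `MSD(t) = 4 D t`
* directed transport: `MSD(t) = 4 D t + v² t²`
* confined diffusion in a square domain of side `L`:
  `MSD(t) = (L²/3) (1 − e^(−12 D t / L²))`, with the confinement diameter
  `Ø = 2L/√π` (equal-area circle)

The apparent diffusion coefficient **D1–4** is the slope/4 of a linear fit
through the first four MSD points, with a free intercept that absorbs the
constant `4σ²` offset contributed by localization noise (σ ≈ 50 nm).
A sliding-window neural-network classifier, trained purely on synthetic
trajectories, labels every point of a trajectory as Brownian, confined or
directed; contiguous runs become segments, each fitted with its own model,
and trajectories are categorized Brownian / confined / mixed / directed.
Population outputs are mode fractions, median apparent D (overall, per
mode, and for the Brownian subpopulation), 1,000-trajectory distribution
exports for violin plots, and Mann–Whitney U comparisons between
conditions. See `docs/methods.md` for assumptions, defaults and
limitations.

## Worked example

Fit the confined-diffusion model to a simulated trajectory trapped in a
0.4 µm domain:

```python
from smtrack import (SimulationConfig, simulate_confined, compute_msd,
                     fit_confined)

cfg = SimulationConfig(D=0.05, L=0.4, loc_sigma=0.05, n_steps=4000, seed=42)
traj = simulate_confined(cfg)
curve = compute_msd(traj, max_lag_points=20)
fit = fit_confined(curve)
print(f"fitted L      = {fit.L:.3f} um   (true 0.400)")
print(f"fitted D      = {fit.D:.4f} um^2/s (true 0.0500)")
print(f"plateau L^2/3 = {fit.L**2/3:.4f} um^2 (true 0.0533)")
print(f"conf diameter = {fit.conf_diameter:.3f} um")
print(f"noise offset  = {fit.intercept:.4f} um^2 (4*sigma^2 = 0.0100)")
```

prints

```
fitted L      = 0.402 um   (true 0.400)
fitted D      = 0.0354 um^2/s (true 0.0500)
plateau L^2/3 = 0.0539 um^2 (true 0.0533)
conf diameter = 0.454 um
noise offset  = 0.0130 um^2 (4*sigma^2 = 0.0100)
```

The domain side and plateau are recovered to better than 1%; `D` inside a
domain that equilibrates within a few frames is only weakly constrained by
the MSD curve (only the first lags carry information about it), which is
why mode fractions and domain sizes — not in-domain D — are the robust
confined-motion readouts.

The same chain runs from the shell; stages compose, each output feeding
the next:

```
smtrack simulate-traj --mode switching --n-traj 100 --out trajs.csv
smtrack train-classifier --out classifier.joblib
smtrack analyze --traj-csv trajs.csv --classifier classifier.joblib --out cls.csv
smtrack summarize --classification cls.csv --out summary.csv
```

and `smtrack run --seed 1 --out-dir run1` executes the full
simulate → filter → classify → summarize pipeline, writing a config
snapshot, a run log of every filter decision, and deterministic CSV
outputs.

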