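# Methods

`smtrack` implements the analysis chain used in single-molecule tracking
(SMT) studies of membrane-protein lateral diffusion: subpixel localization
of fluorophores, frame-per-frame linking into trajectories, mean-square-
displacement (MSD) analysis, point-wise motion-mode classification,
population statistics, and dual-channel Pearson colocalization. Because raw
experimental trajectories of this kind are rarely deposited, the package
carries a first-class synthetic-data module whose generators have exactly
the statistical structure the analysis assumes, so every stage is validated
by parameter recovery against known ground truth.

## Motion models

All simulations and fits use three canonical 2D models, written in terms of
the MSD at time lag `t`:

| mode     | MSD(t)                              | parameters |
|----------|-------------------------------------|------------|
| Brownian | `4 D t`                             | D (um^2/s) |
| directed | `4 D t + v^2 t^2`                   | D, v (um/s) |
| confined | `L^2/3 * (1 - exp(-12 D t / L^2))`  | D, L (um)  |

`L` is the side of a square confinement domain; the confined expression is
the large-time expansion of diffusion in a reflecting square box, whose
plateau is the variance of the uniform equilibrium distribution,
`2 * Var_per_axis = L^2/3` summed over two axes. The confinement diameter
reported alongside `L` is the diameter of the circle of equal area,
`d = 2 L / sqrt(pi)` (for `L = 0.4 um`, `d ≈ 0.451 um`).

Localization noise with per-axis SD `sigma` (default 0.05 um, the
conventional precision of objective-type TIRF SMT) adds a constant
`4 sigma^2 ≈ 0.01 um^2` to every observed MSD lag. All fits therefore carry
a free intercept; the apparent diffusion coefficient `D1-4` is the slope/4
of an ordinary least-squares line through the first four MSD points. A
through-origin variant is available (`fit_d14(..., through_origin=True)`)
but biases `D` upward at small `D`, measurably so below ~0.05 um^2/s.
Negative fitted slopes are clamped to 1e-5 um^2/s and flagged rather than
discarded, so mode-fraction denominators stay stable.

## Synthetic generators

* **Brownian**: independent Gaussian increments with per-axis variance
  `2 D dt`. Default frame interval `dt = 0.1 s` (100 ms integration).
* **Confined**: the free path folded into the square by specular
  reflection (a triangle-wave map, exactly equivalent to iteratively
  reflecting each step). Trajectories start from the uniform equilibrium
  distribution unless an entry point is given.
* **Directed**: Brownian increments plus a constant drift `v dt` in a
  random fixed direction.
* **Switching**: alternating Brownian and confined epochs with
  exponentially distributed dwell times (defaults 2 s each; redrawn when
  shorter than 10 frames so ground truth stays resolvable). The dwell law
  is an assumption — transient confinement kinetics are not constrained by
  typical SMT data — and is configurable. The confinement square is
  re-centered on the entry position of each confined epoch, keeping every
  epoch consistent with the plateau model.
* **Movies**: emitters rendered as pixel-integrated isotropic Gaussians
  (PSF SD 1.3 px, pixel size 0.1 um/px by default), Poisson photon noise,
  constant background, additive Gaussian read noise. The camera model is
  generic EMCCD/sCMOS-like; fixed-pattern noise and EM excess noise are not
  modeled.
* **Colocalization pairs**: two dot images sharing a fraction `f` of dot
  positions; radii and intensities are drawn independently per channel, so
  even `f = 1` yields a correlation well below 1 under a foreground mask —
  as in real two-color labeling, where co-clustering does not imply equal
  stoichiometry.

What the generators deliberately do not emulate: blinking/bleaching
photophysics, hop diffusion between adjacent domains, anomalous
(fractional) diffusion, 3D motion, and spatially varying background.
Passing recovery tests therefore demonstrates correctness of the analysis
under its own model assumptions, not robustness to every experimental
artifact.

## Localization and linking

Candidates are local maxima above `background + k_sigma * SD` (robust
median/MAD statistics, default `k_sigma = 5`), merged within one ROI
half-width to the brighter peak. Each candidate is refined by least-squares
fitting of an axis-aligned elliptical Gaussian (amplitude, x, y, sigma_x,
sigma_y, offset) integrated over pixels on a 7x7 ROI; background statistics
come from the ROI border ring. Fits are rejected — with a logged reason —
on non-convergence, a center leaving the ROI, a peak below 2x the
background noise SD, or an implausible width (< 0.3 px or wider than the
ROI). Rotation of the ellipse is intentionally not fitted: for
near-isotropic PSFs the 6-parameter axis-aligned fit is stable and
unbiased in position.

Linking is greedy globally-nearest-neighbor per frame transition: candidate
pairs sorted by distance, accepted in increasing order, each spot used
once, links beyond `max_disp` forbidden (default 1.0 um per 100 ms frame,
the ~99.9th percentile single-frame step at D = 0.6 um^2/s). Ties break on
spot index for determinism. Gap closing is off by default (`max_gap = 0`).
At single-molecule imaging densities (<= 0.05 emitters/um^2) this greedy
scheme agrees with minimum-total-distance matching essentially always;
dense fields would require LAP/Kalman approaches that are out of scope.
Trajectories shorter than 41 localized points are discarded (inclusive
boundary), the conventional minimum for stable D1-4 estimates.

## Motion-mode classification

A sliding window (default W = 15 frames, stride 1) is described by
scale-invariant features: the window MSD at lags 2..8 normalized by the
lag-1 MSD, straightness, gyration-tensor asymmetry, efficiency, step-length
kurtosis, and step autocorrelation at lags 1-3 (near zero for free
diffusion, negative under confinement, positive under drift). A
one-hidden-layer feed-forward network (32 units, softmax over
brownian/confined/directed, early stopping on a 20% validation split,
fixed seed) is trained on balanced windows from pure-mode simulations.

The default training grid covers the membrane regime (D 0.01-0.5 um^2/s,
L up to 0.7 um, v up to 2 um/s, 50 nm noise) but only combinations whose
mode signature is resolvable *within one window*: a confined domain must
equilibrate well inside the window and its plateau must clear the noise
floor `4 sigma^2` (excluding, e.g., L = 1 um at D <= 0.5 um^2/s, or any
L <= 0.2 um at the default noise — plateau 0.013 um^2 against a 0.01 um^2
floor is indistinguishable from immobility); a drift must traverse at
least about twice the diffusion length per window (excluding, e.g.,
v = 0.5 um/s at D = 0.1 um^2/s, where drift and diffusion displacements are
equal); Brownian motion below D ≈ 0.05 um^2/s is dominated by localization
noise at this timescale. Including such combinations does not make the
classifier better at them — they are information-theoretically ambiguous at
W = 15 — it only injects label noise that degrades the resolvable regime
(a gradient-boosting probe on the unrestricted grid plateaus near 78%
window accuracy; the restricted grid trains to ~94% held-out with
per-class recalls above 0.88). Users analyzing slower or weaker-contrast
motion should increase the window, the trade-off being coarser
segmentation.

Per-point labels are the majority vote of all windows covering the point.
Runs shorter than a minimum are merged into the longer neighbor; the
minimum defaults to one full window (15 frames) rather than the 10-frame
confidence bound, because a mode switch asserted on fewer points than one
window of evidence is almost always vote noise — at the 10-frame setting,
21/150 pure Brownian test trajectories acquired spurious confined segments
(categorizing them "mixed"), versus 10/150 at one window, with switching
trajectories still detected as mixed in 84%. Both the window and the
minimum run are explicit arguments.

Contiguous same-label runs become segments; each segment's MSD is fitted
with its mode's model, and the whole-trajectory D1-4 is recorded — that is
the quantity population distributions ("violin plots") are built from. The
trajectory category is `brownian`/`confined` when uniform, `mixed` when
both occur, and `directed` when any directed segment appears (directed
trajectories are counted separately and excluded from the three-mode
fractions).

As an MSD-only cross-check, `select_model` fits all three models to one
curve and prefers the linear null unless an alternative reduces the
residual sum of squares at least 20-fold (a gate calibrated to a ~5%
false-alternative rate on Brownian simulations — time-averaged MSD errors
are strongly correlated across lags, so nominal F/AIC penalties
under-penalize), with one physical override: a curve whose fitted linear
rise is smaller than its intercept is saturated and is classified
confined, since an MSD that does not grow is a plateau, not free diffusion
with an implausibly large offset. Single-trajectory confined detection by
this route relies on saturation; the intermediate regime (visible curvature
but no plateau within the fitted lags) is genuinely ambiguous at
single-trajectory noise and tends to be read as Brownian.

## Population statistics and colocalization

Population summaries report the median apparent D over all trajectories
and per category, mode fractions over {brownian, confined, mixed}
(directed/unclassified reported separately), and across-experiment SDs of
the fractions when an experiment grouping is provided — matching the
convention of error bars over independent experiments rather than
bootstrap. Distribution exports subsample to 1,000 trajectories per group
with a seeded generator when more are available.

The Mann-Whitney U test uses average ranks; the two-sided p-value comes
from exact enumeration of rank assignments whenever the smaller group has
at most 8 observations (and the arrangement count is modest), otherwise
from the normal approximation with tie correction and continuity
correction. Fully tied data yield p = 1 with a warning.

Colocalization is the Pearson correlation coefficient over a cell mask:
Otsu threshold of the Gaussian-smoothed summed channels, largest connected
component retained. The coefficient is always reported on [-1, 1], never
as a percentage. No Costes randomization or Manders splitting is provided.

## Problem sizes and numerics

Recovery checks use 1,000 trajectories of 41 points per diffusion level
for D1-4, 30 trajectories of 4,000 points for the confined plateau, 2,000
trajectories for the directed ensemble, 4,000 windows per class for
classifier training, and 100 switching trajectories of 200 frames for
segmentation — sizes at which Monte-Carlo error sits well inside the 5-10%
recovery tolerances. Nonlinear fits run with positivity bounds and
data-derived initialization (`L0 = sqrt(3 * max MSD)`, `D0` from the D1-4
line); per-segment fits cap the lag range at `min(n/4, 20)` lags to balance
noise against curvature visibility. All generators and the training
pipeline are deterministic under a fixed seed, with per-stage substreams
derived from one global seed via `SeedSequence`.
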