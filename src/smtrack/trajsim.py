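"""Synthetic ground-truth generators for single-molecule tracking.

Simulates 2D trajectories of membrane molecules under the three canonical
motion modes — free (Brownian) diffusion, confinement inside a square
membrane domain, and directed transport — plus trajectories that switch
between Brownian and confined epochs (``mixed`` motion). Also renders
synthetic single-molecule movies (Gaussian PSF, Poisson shot noise, Gaussian
read noise) and dual-channel dot images with a controllable shared fraction,
providing known ground truth for every downstream analysis stage.

Units: positions in micrometers, time in seconds, diffusion coefficients in
um^2/s. Observed positions are the true positions plus isotropic Gaussian
localization noise (default SD 50 nm per axis), which adds a constant
4*sigma^2 offset to the observed MSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import erf

MODE_BROWNIAN = "brownian"
MODE_CONFINED = "confined"
MODE_DIRECTED = "directed"


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a single-trajectory simulation.

    Parameters
    ----------
    dt : float
        Frame interval in seconds (default 0.1 s, i.e. 100 ms integration).
    n_steps : int
        Number of points in the trajectory (>= 2).
    D : float
        Diffusion coefficient, um^2/s.
    loc_sigma : float
        Localization noise SD per axis, um (default 0.05 um = 50 nm).
    L : float
        Side of the square confinement domain, um (confined modes only).
    v : float
        Drift speed, um/s (directed mode only).
    dwell_brownian, dwell_confined : float
        Mean dwell times (s) of the exponential epochs of switching motion.
    min_epoch_frames : int
        Minimum epoch length in frames for switching motion; epochs shorter
        than this are redrawn so ground truth stays resolvable by a
        10-frame-scale classifier.
    seed : int
        RNG seed. Identical seed implies identical output.
    """

    dt: float = 0.1
    n_steps: int = 100
    D: float = 0.1
    loc_sigma: float = 0.05
    L: float = 0.3
    v: float = 0.5
    dwell_brownian: float = 2.0
    dwell_confined: float = 2.0
    min_epoch_frames: int = 10
    seed: int = 0

    def validate(self, *, need_L: bool = False, need_dwell: bool = False) -> None:
        if self.dt <= 0:
            raise ConfigError(f"dt must be > 0, got {self.dt}")
        if self.n_steps < 2:
            raise ConfigError(f"n_steps must be >= 2, got {self.n_steps}")
        if self.D < 0:
            raise ConfigError(f"D must be >= 0, got {self.D}")
        if self.loc_sigma < 0:
            raise ConfigError(f"loc_sigma must be >= 0, got {self.loc_sigma}")
        if self.v < 0:
            raise ConfigError(f"v must be >= 0, got {self.v}")
        if need_L and self.L <= 0:
            raise ConfigError(f"L must be > 0, got {self.L}")
        if need_dwell:
            if self.dwell_brownian <= 0 or self.dwell_confined <= 0:
                raise ConfigError("dwell times must be > 0")
            if self.dwell_brownian < self.dt or self.dwell_confined < self.dt:
                raise ConfigError("dwell times must be at least one frame")


@dataclass
class Trajectory:
    """A time-ordered 2D single-molecule trajectory.

    ``xy`` holds observed positions in um, one row per frame; ``frames`` are
    strictly increasing integer frame indices; ``truth_labels`` (optional)
    record the generating motion mode of each point.
    """

    id: int | str
    frames: np.ndarray
    xy: np.ndarray
    dt: float = 0.1
    truth_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n, 2)")
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and xy must have equal length")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frames must be strictly increasing")
        if self.truth_labels is not None and len(self.truth_labels) != len(self.frames):
            raise ValueError("truth_labels must match trajectory length")

    def __len__(self) -> int:
        return len(self.frames)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _observe(true_xy: np.ndarray, loc_sigma: float, rng: np.random.Generator) -> np.ndarray:
    if loc_sigma == 0:
        return true_xy.copy()
    return true_xy + rng.normal(0.0, loc_sigma, size=true_xy.shape)


def _brownian_steps(n: int, D: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    # per-axis increment variance 2*D*dt  =>  E|dr|^2 = 4*D*dt
    return rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n, 2))


def _reflect(coords: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by specular reflection (triangle wave)."""
    width = hi - lo
    y = np.mod(coords - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return lo + y


def simulate_brownian(config: SimulationConfig) -> Trajectory:
    """Free 2D diffusion: independent Gaussian increments of variance 2*D*dt
    per axis, so the ensemble MSD obeys MSD(t) = 4*D*t."""
    config.validate()
    rng = _rng(config.seed)
    steps = _brownian_steps(config.n_steps - 1, config.D, config.dt, rng)
    true_xy = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    xy = _observe(true_xy, config.loc_sigma, rng)
    return Trajectory(
        id=0, frames=np.arange(config.n_steps), xy=xy, dt=config.dt,
        truth_labels=[MODE_BROWNIAN] * config.n_steps,
    )


def simulate_confined(config: SimulationConfig, *, center: Sequence[float] = (0.0, 0.0),
                      start: Sequence[float] | None = None) -> Trajectory:
    """Diffusion confined to a square domain of side L with reflecting walls.

    The time-averaged MSD of this process saturates at the plateau L^2/3,
    matching the confined model L^2/3 * (1 - exp(-12*D*t/L^2)).
    """
    config.validate(need_L=True)
    rng = _rng(config.seed)
    true_xy = _confined_path(
        config.n_steps, config.D, config.dt, config.L,
        np.asarray(center, float),
        None if start is None else np.asarray(start, float), rng,
    )
    xy = _observe(true_xy, config.loc_sigma, rng)
    return Trajectory(
        id=0, frames=np.arange(config.n_steps), xy=xy, dt=config.dt,
        truth_labels=[MODE_CONFINED] * config.n_steps,
    )


def _confined_path(n: int, D: float, dt: float, L: float, center: np.ndarray,
                   start: np.ndarray | None, rng: np.random.Generator) -> np.ndarray:
    lo, hi = center - L / 2.0, center + L / 2.0
    if start is None:
        start = rng.uniform(lo, hi)  # equilibrium start: uniform in the box
    start = np.clip(start, lo, hi)
    steps = _brownian_steps(n - 1, D, dt, rng)
    # specular reflection == folding the free path with a triangle wave
    free = start + np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    pos = np.empty((n, 2))
    for ax in range(2):
        pos[:, ax] = _reflect(free[:, ax], lo[ax], hi[ax])
    return pos


def simulate_directed(config: SimulationConfig) -> Trajectory:
    """Brownian diffusion plus constant drift of speed v in a random fixed
    direction; ensemble MSD(t) = 4*D*t + v^2*t^2."""
    config.validate()
    rng = _rng(config.seed)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    drift = config.v * config.dt * np.array([np.cos(theta), np.sin(theta)])
    steps = _brownian_steps(config.n_steps - 1, config.D, config.dt, rng) + drift
    true_xy = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    xy = _observe(true_xy, config.loc_sigma, rng)
    return Trajectory(
        id=0, frames=np.arange(config.n_steps), xy=xy, dt=config.dt,
        truth_labels=[MODE_DIRECTED] * config.n_steps,
    )


def simulate_switching(config: SimulationConfig, *, start_mode: str = MODE_BROWNIAN) -> Trajectory:
    """Alternating Brownian and confined epochs (``mixed`` motion).

    Dwell times are exponential with means ``dwell_brownian`` and
    ``dwell_confined``; epochs shorter than ``min_epoch_frames`` are redrawn.
    The confinement square is re-centered on the position at epoch entry, so
    each confined epoch is consistent with the plateau model. ``truth_labels``
    record the generating mode per point and partition the trajectory exactly.
    """
    config.validate(need_L=True, need_dwell=True)
    rng = _rng(config.seed)
    n = config.n_steps
    xy = np.empty((n, 2))
    labels: list[str] = []
    xy[0] = 0.0
    mode = start_mode
    i = 0
    while i < n:
        mean_dwell = config.dwell_brownian if mode == MODE_BROWNIAN else config.dwell_confined
        for _ in range(1000):
            epoch_frames = int(np.ceil(rng.exponential(mean_dwell) / config.dt))
            if epoch_frames >= config.min_epoch_frames:
                break
        epoch_frames = min(epoch_frames, n - i)
        j = i + epoch_frames
        if mode == MODE_BROWNIAN:
            steps = _brownian_steps(epoch_frames - (1 if i == 0 else 0), config.D, config.dt, rng)
            base = xy[i] if i == 0 else xy[i - 1]
            seg = base + np.cumsum(steps, axis=0)
            if i == 0:
                xy[1:j] = seg[: j - 1]
            else:
                xy[i:j] = seg
        else:
            entry = xy[i] if i == 0 else xy[i - 1]
            count = j - i + (0 if i == 0 else 1)
            seg = _confined_path(count, config.D, config.dt, config.L,
                                 center=entry, start=entry, rng=rng)
            xy[i:j] = seg[0 if i == 0 else 1:]
        labels.extend([mode] * epoch_frames)
        mode = MODE_CONFINED if mode == MODE_BROWNIAN else MODE_BROWNIAN
        i = j
    obs = _observe(xy, config.loc_sigma, rng)
    return Trajectory(id=0, frames=np.arange(n), xy=obs, dt=config.dt, truth_labels=labels)


def simulate_ensemble(config: SimulationConfig, n_traj: int, mode: str = MODE_BROWNIAN) -> list[Trajectory]:
    """Generate ``n_traj`` independent trajectories of one mode, with
    per-trajectory seeds derived deterministically from ``config.seed``."""
    sim = {
        MODE_BROWNIAN: simulate_brownian,
        MODE_CONFINED: simulate_confined,
        MODE_DIRECTED: simulate_directed,
        "switching": simulate_switching,
    }[mode]
    children = np.random.SeedSequence(config.seed).spawn(n_traj)
    out = []
    for k, child in enumerate(children):
        sub = replace(config, seed=int(child.generate_state(1)[0] % (2**31)))
        t = sim(sub)
        t.id = k
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# Movie rendering


@dataclass(frozen=True)
class MovieConfig:
    """Camera / optics model for rendering synthetic movies.

    ``pixel_size`` converts um positions to px; the PSF is an isotropic 2D
    Gaussian integrated over each pixel; photon shot noise is Poisson and
    read noise additive Gaussian on top of a constant background.
    """

    shape: tuple[int, int] = (64, 64)
    pixel_size: float = 0.1        # um per px
    psf_sigma: float = 1.3         # px
    photons: float = 2000.0        # photons per emitter per frame
    background: float = 10.0       # photons per px per frame
    read_noise: float = 1.0        # counts, Gaussian SD
    seed: int = 0

    def validate(self) -> None:
        if min(self.shape) <= 0 or self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ConfigError("shape, pixel_size and psf_sigma must be positive")
        if self.photons < 0 or self.background < 0 or self.read_noise < 0:
            raise ConfigError("photons, background and read_noise must be >= 0")


def gaussian_spot_image(shape: tuple[int, int], x: float, y: float, sigma: float,
                        photons: float) -> np.ndarray:
    """Pixel-integrated isotropic Gaussian PSF (photon units, sums to ~photons)."""
    ny, nx = shape
    xs = np.arange(nx)
    ys = np.arange(ny)
    s = sigma * np.sqrt(2.0)
    fx = 0.5 * (erf((xs + 0.5 - x) / s) - erf((xs - 0.5 - x) / s))
    fy = 0.5 * (erf((ys + 0.5 - y) / s) - erf((ys - 0.5 - y) / s))
    return photons * np.outer(fy, fx)


def render_movie(trajs: Sequence[Trajectory], movie: MovieConfig) -> tuple[np.ndarray, "pd.DataFrame"]:
    """Render trajectories into a photon-noise-limited image stack.

    Returns ``(stack, truth)`` where ``stack`` is a (n_frames, ny, nx)
    float array in counts and ``truth`` a per-frame emitter table
    (frame, emitter_id, x_px, y_px, photons). Every trajectory position must
    fall inside the field of view after um -> px conversion.
    """
    import pandas as pd

    movie.validate()
    ny, nx = movie.shape
    for t in trajs:
        px = t.xy / movie.pixel_size
        if (px[:, 0].min() < 0 or px[:, 0].max() > nx - 1
                or px[:, 1].min() < 0 or px[:, 1].max() > ny - 1):
            raise ValueError(f"trajectory {t.id} leaves the field of view")
    n_frames = 1 + max(int(t.frames.max()) for t in trajs) if trajs else 0
    rng = _rng(movie.seed)
    stack = np.empty((n_frames, ny, nx))
    rows = []
    ideal = np.full((n_frames, ny, nx), float(movie.background))
    for t in trajs:
        px = t.xy / movie.pixel_size
        for f, (x, y) in zip(t.frames, px):
            ideal[f] += gaussian_spot_image((ny, nx), x, y, movie.psf_sigma, movie.photons)
            rows.append({"frame": int(f), "emitter_id": t.id, "x_px": x, "y_px": y,
                         "photons": movie.photons})
    for f in range(n_frames):
        frame = rng.poisson(ideal[f]).astype(float)
        if movie.read_noise > 0:
            frame += rng.normal(0.0, movie.read_noise, size=frame.shape)
        stack[f] = frame
    truth = pd.DataFrame(rows, columns=["frame", "emitter_id", "x_px", "y_px", "photons"])
    return stack, truth


# ---------------------------------------------------------------------------
# Dual-channel colocalization images


@dataclass(frozen=True)
class ColocConfig:
    """Synthetic dual-channel dot images with a known shared fraction.

    A fraction ``shared_fraction`` of dot positions is identical in both
    channels; the remainder are independent. Dot radii are drawn uniformly
    from ``radius_range`` (px); intensities from ``intensity_range``.
    """

    shape: tuple[int, int] = (128, 128)
    n_dots: int = 60
    shared_fraction: float = 0.5
    radius_range: tuple[float, float] = (1.5, 3.0)
    intensity_range: tuple[float, float] = (500.0, 1500.0)
    background: float = 20.0
    noise_sigma: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ConfigError("shared_fraction must be in [0, 1]")
        if self.n_dots < 1:
            raise ConfigError("n_dots must be >= 1")


def _render_dots(shape, positions, radii, intensities) -> np.ndarray:
    img = np.zeros(shape)
    for (x, y), r, a in zip(positions, radii, intensities):
        img += gaussian_spot_image(shape, x, y, r, a)
    return img


def generate_coloc_pair(config: ColocConfig) -> tuple[np.ndarray, np.ndarray, float]:
    """Two dot images sharing a fraction ``f`` of dot positions.

    Returns ``(image_a, image_b, f)``; f is the realized ground-truth
    shared fraction (== config.shared_fraction).
    """
    config.validate()
    rng = _rng(config.seed)
    ny, nx = config.shape
    margin = config.radius_range[1] * 2.0
    n_shared = int(round(config.shared_fraction * config.n_dots))

    def draw_pos(n):
        return np.column_stack([rng.uniform(margin, nx - margin, n),
                                rng.uniform(margin, ny - margin, n)])

    shared = draw_pos(n_shared)
    imgs = []
    for _ in range(2):
        own = draw_pos(config.n_dots - n_shared)
        pos = np.vstack([shared, own]) if len(shared) else own
        radii = rng.uniform(*config.radius_range, size=config.n_dots)
        inten = rng.uniform(*config.intensity_range, size=config.n_dots)
        img = config.background + _render_dots(config.shape, pos, radii, inten)
        if config.noise_sigma > 0:
            img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
        imgs.append(img)
    return imgs[0], imgs[1], config.shared_fraction
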