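"""Subpixel single-molecule localization by 2D elliptical Gaussian fitting.

Candidate spots are local maxima above a robust background threshold; each
candidate is refined by least-squares fitting of an axis-aligned elliptical
Gaussian (pixel-integrated) over a small ROI, yielding subpixel center,
per-axis widths, amplitude and offset. The localization precision of the
instrument is estimated as the SD of repeated position fits of an immobile
emitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.special import erf


@dataclass
class Spot:
    """A fitted spot: subpixel position and elliptical Gaussian parameters (px)."""

    frame: int
    x: float
    y: float
    sigma_x: float
    sigma_y: float
    amplitude: float
    offset: float
    residual: float


class FitRejection(Exception):
    """A candidate whose Gaussian fit failed quality control."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def robust_background(image: np.ndarray) -> tuple[float, float]:
    """Background mean and SD via median / scaled MAD (outlier-resistant)."""
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    return med, 1.4826 * mad


def detect_candidates(frame_image: np.ndarray, k_sigma: float = 5.0,
                      merge_radius: int = 3) -> list[tuple[int, int]]:
    """Pixel-level spot candidates: local maxima above background + k_sigma*SD.

    Maxima closer than ``merge_radius`` px are merged to the brighter one.
    Returns (row, col) integer positions.
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("frame_image must be a 2D image of at least 3x3 px")
    if k_sigma <= 0:
        raise ValueError("k_sigma must be > 0")
    bg, sd = robust_background(img)
    if sd == 0:
        sd = max(np.std(img), 1e-12)
    thresh = bg + k_sigma * sd
    footprint = np.ones((3, 3), dtype=bool)
    is_max = (img == ndimage.maximum_filter(img, footprint=footprint)) & (img > thresh)
    coords = np.argwhere(is_max)
    if len(coords) == 0:
        return []
    # merge near-duplicates, keeping the brighter peak
    order = np.argsort(-img[coords[:, 0], coords[:, 1]])
    kept: list[tuple[int, int]] = []
    for i in order:
        r, c = coords[i]
        if all((r - rk) ** 2 + (c - ck) ** 2 >= merge_radius**2 for rk, ck in kept):
            kept.append((int(r), int(c)))
    kept.sort()
    return kept


def _elliptical_gaussian(coords, amp, x0, y0, sx, sy, off):
    """Axis-aligned elliptical Gaussian integrated over pixels."""
    xs, ys = coords
    tx = 0.5 * (erf((xs + 0.5 - x0) / (sx * np.sqrt(2)))
                - erf((xs - 0.5 - x0) / (sx * np.sqrt(2))))
    ty = 0.5 * (erf((ys + 0.5 - y0) / (sy * np.sqrt(2)))
                - erf((ys - 0.5 - y0) / (sy * np.sqrt(2))))
    return amp * tx * ty + off


def fit_elliptical_gaussian(frame_image: np.ndarray, candidate: tuple[int, int],
                            roi_half_width: int = 3, frame: int = 0,
                            min_amplitude_sigma: float = 2.0) -> Spot:
    """Least-squares elliptical Gaussian fit around a candidate pixel.

    The ROI is (2*roi_half_width+1)^2 and must lie fully inside the image;
    background statistics come from the ROI border ring. Raises
    :class:`FitRejection` on non-convergence, a center drifting outside the
    ROI, or an amplitude below ``min_amplitude_sigma`` times the background
    noise SD.
    """
    img = np.asarray(frame_image, dtype=float)
    r0, c0 = candidate
    h = roi_half_width
    if r0 - h < 0 or c0 - h < 0 or r0 + h >= img.shape[0] or c0 + h >= img.shape[1]:
        raise FitRejection("roi_outside_image")
    roi = img[r0 - h:r0 + h + 1, c0 - h:c0 + h + 1]
    border = np.concatenate([roi[0], roi[-1], roi[1:-1, 0], roi[1:-1, -1]])
    bg = float(np.median(border))
    bg_sd = float(np.std(border))
    ys, xs = np.mgrid[0:roi.shape[0], 0:roi.shape[1]]
    amp0 = max(float(roi.max() - bg), 1e-6)
    p0 = (amp0 * 2 * np.pi * 1.0, float(h), float(h), 1.2, 1.2, bg)
    lower = [1e-9, -1.0, -1.0, 0.2, 0.2, -np.inf]
    upper = [np.inf, roi.shape[1], roi.shape[0], float(roi.shape[1]), float(roi.shape[0]), np.inf]
    try:
        popt, _ = curve_fit(
            _elliptical_gaussian, (xs.ravel(), ys.ravel()), roi.ravel(),
            p0=p0, bounds=(lower, upper), maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitRejection(f"no_convergence: {exc}") from exc
    amp, x0, y0, sx, sy, off = (float(p) for p in popt)
    if not (0 <= x0 <= 2 * h and 0 <= y0 <= 2 * h):
        raise FitRejection("center_outside_roi")
    # a PSF narrower than ~a third of a pixel or wider than the ROI is a
    # noise artifact, not a diffraction-limited spot
    if min(sx, sy) < 0.3 or max(sx, sy) > 2.0 * h:
        raise FitRejection("implausible_width")
    peak = amp * (_elliptical_gaussian((np.array([x0]), np.array([y0])),
                                       amp, x0, y0, sx, sy, 0.0)[0] / max(amp, 1e-12))
    if bg_sd > 0 and peak < min_amplitude_sigma * bg_sd:
        raise FitRejection("amplitude_below_noise")
    model = _elliptical_gaussian((xs.ravel(), ys.ravel()), *popt)
    resid = float(np.sqrt(np.mean((roi.ravel() - model) ** 2)) / max(amp, 1e-12))
    return Spot(frame=frame, x=c0 - h + x0, y=r0 - h + y0,
                sigma_x=sx, sigma_y=sy, amplitude=amp, offset=off, residual=resid)


def localize_frame(frame_image: np.ndarray, frame: int = 0, k_sigma: float = 5.0,
                   roi_half_width: int = 3) -> tuple[list[Spot], list[str]]:
    """Detect + fit all spots in one frame; returns (spots, rejection reasons)."""
    spots: list[Spot] = []
    rejections: list[str] = []
    for cand in detect_candidates(frame_image, k_sigma=k_sigma,
                                  merge_radius=roi_half_width):
        try:
            spots.append(fit_elliptical_gaussian(frame_image, cand,
                                                 roi_half_width=roi_half_width,
                                                 frame=frame))
        except FitRejection as rej:
            rejections.append(rej.reason)
    return spots, rejections


def localize_stack(stack: np.ndarray, k_sigma: float = 5.0,
                   roi_half_width: int = 3) -> "pd.DataFrame":
    """Localize every frame of a stack; returns a detections table
    (frame, x_px, y_px, sigma_x, sigma_y, amplitude, offset, residual)."""
    import pandas as pd

    rows = []
    for f, frame_image in enumerate(stack):
        spots, _ = localize_frame(frame_image, frame=f, k_sigma=k_sigma,
                                  roi_half_width=roi_half_width)
        for s in spots:
            rows.append({"frame": s.frame, "x_px": s.x, "y_px": s.y,
                         "sigma_x": s.sigma_x, "sigma_y": s.sigma_y,
                         "amplitude": s.amplitude, "offset": s.offset,
                         "residual": s.residual})
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "sigma_x", "sigma_y",
                                       "amplitude", "offset", "residual"])


def estimate_localization_precision(positions: np.ndarray, pixel_size: float = 1.0) -> float:
    """Localization precision from repeated fits of one immobile emitter.

    ``positions``: (n, 2) fitted positions (px or um); returns the per-axis
    SD averaged over x and y, scaled by ``pixel_size`` to um. Requires at
    least 20 positions for a stable estimate.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError("positions must have shape (n, 2)")
    if len(pos) < 20:
        raise ValueError(f"need >= 20 positions, got {len(pos)}")
    sds = pos.std(axis=0, ddof=1)
    return float(sds.mean() * pixel_size)
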