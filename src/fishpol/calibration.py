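"""Calibration of the characteristic fluorescent "mRNA unit".

Workflow: subtract a scalar background, find isolated candidate spots,
fit each to an isotropic 2D Gaussian point-spread function, filter the
fits by size, then trim the amplitude distribution from above until
both the amplitude and width distributions are unimodal.  The means of
the surviving distributions define the unit: amplitude ``A_u``, width
``sigma_u`` and integrated intensity ``I_u = 2 pi A_u sigma_u^2``.
All counts downstream are denominated in these units; a unit likely
corresponds to a small cluster of transcripts rather than a single
molecule, and no attempt is made to decompose it further.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import shapely
from scipy import optimize, stats
from shapely.geometry import Polygon
from skimage.feature import peak_local_max

from .image import FluorescenceImage

MIN_SUPPORT = 10

__all__ = [
    "SpotCandidate",
    "UnitModel",
    "subtract_background",
    "detect_peaks",
    "fit_psf",
    "derive_unit",
    "calibrate_unit",
]


@dataclass
class SpotCandidate:
    """One candidate spot: detected peak plus (optionally) its PSF fit."""

    center: tuple[float, float]  # (row, col), subpixel after fitting
    peak_value: float
    fit_amplitude: float = float("nan")
    fit_sigma: float = float("nan")
    fit_background: float = float("nan")
    fit_rss: float = float("nan")
    accepted: bool = False


@dataclass(frozen=True)
class UnitModel:
    """The calibrated mRNA unit.

    ``integrated_intensity`` is the volume under the unit's Gaussian,
    ``2 pi * amplitude * sigma**2`` — the denominator of the linear
    count estimate and the photometric size of one placement in the
    image-reconstruction estimate.
    """

    amplitude: float
    sigma: float
    n_support: int = 0
    trim_fraction_applied: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.sigma <= 0:
            raise ValueError("unit amplitude and sigma must be > 0")

    @property
    def integrated_intensity(self) -> float:
        return 2.0 * math.pi * self.amplitude * self.sigma**2

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "sigma": self.sigma,
            "integrated_intensity": self.integrated_intensity,
            "n_support": self.n_support,
            "trim_fraction_applied": self.trim_fraction_applied,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UnitModel":
        return cls(
            amplitude=float(d["amplitude"]),
            sigma=float(d["sigma"]),
            n_support=int(d.get("n_support", 0)),
            trim_fraction_applied=float(d.get("trim_fraction_applied", 0.0)),
        )


def subtract_background(
    image: FluorescenceImage, cell_mask: Polygon | None = None
) -> FluorescenceImage:
    """Subtract a scalar background estimate, clipping at zero.

    The background is the median of pixels outside ``cell_mask`` when a
    mask is given, else the global median.  The value is recorded on
    the returned image's ``background`` attribute.
    """
    px = image.pixels
    if cell_mask is not None:
        rr, cc = np.indices(px.shape)
        inside = shapely.contains_xy(cell_mask, cc.ravel(), rr.ravel()).reshape(px.shape)
        outside = ~inside
        if not outside.any():
            raise ValueError("cell_mask covers the entire image; no background pixels")
        bg = float(np.median(px[outside]))
    else:
        bg = float(np.median(px))
    out = np.clip(px - bg, 0.0, None)
    return image.with_pixels(out, background=bg)


def robust_noise_scale(pixels: np.ndarray) -> float:
    """Robust noise scale that bright spots cannot inflate.

    Median absolute deviation (Gaussian-consistent) for ordinary
    images.  Background-subtracted images are clipped at zero, which
    piles up pixels at 0 and deflates the MAD; when more than a
    quarter of the pixels sit at zero the scale falls back to the
    one-sided quantile deviation (84.13th percentile minus median),
    which equals one sigma for half-clipped Gaussian noise.
    """
    med = float(np.median(pixels))
    if np.mean(pixels == 0.0) > 0.25:
        return float(np.percentile(pixels, 84.13)) - med
    return 1.4826 * float(np.median(np.abs(pixels - med)))


def detect_peaks(
    image: FluorescenceImage,
    min_separation_px: float = 3.0,
    k_sigma: float = 5.0,
) -> list[SpotCandidate]:
    """Find candidate spots as isolated local maxima.

    Peaks are 8-neighbourhood local maxima of the (background-
    subtracted) image whose value strictly exceeds ``k_sigma`` times
    the MAD-based noise scale, with no two peaks closer than
    ``min_separation_px``.  Returned sorted by decreasing peak value.
    """
    if min_separation_px <= 0:
        raise ValueError("min_separation_px must be > 0")
    px = image.pixels
    thr = k_sigma * robust_noise_scale(px)
    coords = peak_local_max(
        px,
        min_distance=max(1, int(math.ceil(min_separation_px))),
        threshold_abs=thr,
        exclude_border=False,
    )
    cands = [
        SpotCandidate(center=(float(r), float(c)), peak_value=float(px[r, c]))
        for r, c in coords
        if px[r, c] > max(thr, 0.0)
    ]
    cands.sort(key=lambda s: s.peak_value, reverse=True)
    return cands


def _gauss2d(coords, amplitude, r0, c0, sigma, background):
    rr, cc = coords
    return (
        background
        + amplitude * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2))
    ).ravel()


def fit_psf(
    image: FluorescenceImage,
    candidate: SpotCandidate,
    window_px: int = 11,
) -> SpotCandidate:
    """Least-squares fit of ``background + A exp(-r^2 / 2 sigma^2)``.

    The fit runs over a ``window_px``-wide square window centred on the
    candidate; the window must lie within the image.  On success the
    returned candidate carries the fitted amplitude, width, local
    background and residual sum of squares, and is flagged accepted.
    Singular or non-converging fits are returned not accepted.
    """
    half = window_px // 2
    r, c = int(round(candidate.center[0])), int(round(candidate.center[1]))
    rows, cols = image.shape
    if r - half < 0 or r + half >= rows or c - half < 0 or c + half >= cols:
        raise ValueError(
            f"fit window ({window_px} px at ({r}, {c})) extends off the image"
        )
    win = image.pixels[r - half : r + half + 1, c - half : c + half + 1]
    if np.ptp(win) == 0:
        return replace(candidate, accepted=False)
    rr, cc = np.mgrid[r - half : r + half + 1, c - half : c + half + 1].astype(float)
    p0 = [float(win.max() - win.min()), float(r), float(c), 1.5, float(win.min())]
    lo = [0.0, r - half, c - half, 0.1, -np.inf]
    hi = [np.inf, r + half, c + half, float(window_px), np.inf]
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d, (rr, cc), win.ravel(), p0=p0, bounds=(lo, hi), max_nfev=300
        )
    except (RuntimeError, ValueError):
        return replace(candidate, accepted=False)
    amp, r0, c0, sigma, bg = (float(v) for v in popt)
    rss = float(np.sum((_gauss2d((rr, cc), *popt) - win.ravel()) ** 2))
    ok = amp > 0 and 0 < sigma < window_px
    return replace(
        candidate,
        center=(r0, c0),
        fit_amplitude=amp,
        fit_sigma=sigma,
        fit_background=bg,
        fit_rss=rss,
        accepted=ok,
    )


def bimodality_coefficient(values: np.ndarray) -> float:
    """Sarle's bimodality coefficient b = (g1^2 + 1) / (g2 + 3(n-1)^2/((n-2)(n-3))).

    Values above ~0.555 (the uniform distribution's coefficient)
    indicate possible bi- or multimodality.  A zero-variance sample is
    treated as perfectly unimodal (returns 0).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return 0.0
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, fisher=True, bias=False)
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def _kde_mode_count(values: np.ndarray, grid_size: int = 512) -> int:
    x = np.asarray(values, dtype=float)
    if np.var(x) == 0:
        return 1
    kde = stats.gaussian_kde(x)
    lo, hi = x.min(), x.max()
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    interior = dens[1:-1]
    peaks = (interior > dens[:-2]) & (interior >= dens[2:])
    return max(1, int(peaks.sum()))


def _is_unimodal(values: np.ndarray, criterion: str, threshold: float) -> bool:
    # a distribution whose entire spread is within 5% of its mean is
    # already "fine" for calibration purposes: it cannot hide a second
    # mode of distinct spots, and moment-based criteria blow up on
    # such near-degenerate samples (tiny tails dominate skew/kurtosis)
    if np.ptp(values) <= 0.05 * abs(float(np.mean(values))):
        return True
    if criterion == "bimodality":
        return bimodality_coefficient(values) < threshold
    if criterion == "kde_modes":
        return _kde_mode_count(values) <= 1
    raise ValueError(f"unknown unimodality criterion {criterion!r}")


def derive_unit(
    candidates: list[SpotCandidate],
    size_bounds: tuple[float, float] = (0.8, 3.0),
    trim_step: float = 0.02,
    unimodality_threshold: float = 0.555,
    criterion: str = "bimodality",
    min_support: int = MIN_SUPPORT,
    return_survivors: bool = False,
) -> "UnitModel | tuple[UnitModel, list[SpotCandidate]]":
    """Derive the unit from accepted PSF fits by trim-to-unimodal.

    Candidates with fitted width outside ``size_bounds`` are dropped;
    then both fit-parameter distributions are thresholded from above:
    at each iteration the top ``trim_step`` quantile of whichever
    distribution(s) (amplitude, width) still fails the unimodality
    criterion is removed, until both pass.  The unit is the mean of
    the surviving amplitudes and widths.

    Criteria: ``"bimodality"`` (Sarle's coefficient below
    ``unimodality_threshold``, default) or ``"kde_modes"`` (a Gaussian
    kernel density estimate with Silverman bandwidth has a single
    interior mode).
    """
    if not 0 < trim_step < 1:
        raise ValueError("trim_step must be in (0, 1)")
    sel = [
        c
        for c in candidates
        if c.accepted and size_bounds[0] <= c.fit_sigma <= size_bounds[1]
    ]
    if len(sel) < min_support:
        raise ValueError(
            f"insufficient isolated spots: {len(sel)} accepted candidates in "
            f"size bounds {size_bounds}, need >= {min_support}"
        )
    n_start = len(sel)
    while True:
        amps = np.array([c.fit_amplitude for c in sel])
        sigs = np.array([c.fit_sigma for c in sel])
        amp_ok = _is_unimodal(amps, criterion, unimodality_threshold)
        sig_ok = _is_unimodal(sigs, criterion, unimodality_threshold)
        if amp_ok and sig_ok:
            break
        n_drop = max(1, int(math.ceil(trim_step * len(sel))))
        drop: set[int] = set()
        if not amp_ok:
            drop.update(np.argsort(amps)[-n_drop:].tolist())
        if not sig_ok:
            drop.update(np.argsort(sigs)[-n_drop:].tolist())
        sel = [c for i, c in enumerate(sel) if i not in drop]
        if len(sel) < min_support:
            raise ValueError(
                "insufficient isolated spots: trimming to unimodality left "
                f"{len(sel)} candidates, need >= {min_support}"
            )
    unit = UnitModel(
        amplitude=float(np.mean([c.fit_amplitude for c in sel])),
        sigma=float(np.mean([c.fit_sigma for c in sel])),
        n_support=len(sel),
        trim_fraction_applied=1.0 - len(sel) / n_start,
    )
    return (unit, sel) if return_survivors else unit


def calibrate_unit(
    images: FluorescenceImage | list[FluorescenceImage],
    cell_masks: Polygon | list[Polygon] | None = None,
    min_separation_px: float = 3.0,
    k_sigma: float = 5.0,
    window_px: int = 11,
    size_bounds: tuple[float, float] = (0.8, 3.0),
    trim_step: float = 0.02,
    unimodality_threshold: float = 0.555,
    criterion: str = "bimodality",
) -> tuple[UnitModel, list[SpotCandidate]]:
    """End-to-end calibration: subtract, detect, fit, derive.

    Candidates are pooled across all images before the unit is derived
    (calibration is per experiment, not per cell).  Peaks whose fit
    window would extend off the image are skipped.
    """
    if isinstance(images, FluorescenceImage):
        images = [images]
    if cell_masks is not None and not isinstance(cell_masks, list):
        cell_masks = [cell_masks]
    pooled: list[SpotCandidate] = []
    for i, img in enumerate(images):
        mask = cell_masks[i] if cell_masks is not None else None
        sub = subtract_background(img, mask)
        for cand in detect_peaks(sub, min_separation_px, k_sigma):
            try:
                pooled.append(fit_psf(sub, cand, window_px))
            except ValueError:
                continue  # window off image: not an isolated, fittable spot
    unit = derive_unit(
        pooled,
        size_bounds=size_bounds,
        trim_step=trim_step,
        unimodality_threshold=unimodality_threshold,
        criterion=criterion,
    )
    if unit.n_support < 2 * MIN_SUPPORT:
        warnings.warn(
            f"unit calibrated from only {unit.n_support} spots; "
            "consider pooling more images",
            stacklevel=2,
        )
    return unit, pooled
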