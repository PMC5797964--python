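"""Fluorescence-intensity quantification and FRAP recovery fitting.

Two independent capabilities live here:

* whole-cell / on-spindle intensity measurements inside a fixed-diameter
  circle after background subtraction, and group ratios thereof (used to
  express fold-overexpression of a construct relative to controls);
* FRAP trace normalization (pre-bleach value mapped to 1, first post-bleach
  frame to 0) and a single-exponential recovery fit
  ``F(t) = A * (1 - exp(-k t))`` whose half-time ``t_half = ln 2 / k``
  summarizes microtubule turnover at spindle poles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    FitFailureError,
    NoBleachDetectedError,
    ParameterError,
    UndefinedRatioError,
)

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# Intensity measurements
# ---------------------------------------------------------------------------

@dataclass
class IntensityMeasurement:
    """Background-subtracted total intensity in one region of one image."""

    total_intensity: float  # a.u., clipped at 0
    region: str  # "fixed_circle" or "spindle_mask"
    circle_diameter_um: float | None
    background_per_voxel: float
    n_pixels: int = 0


def estimate_background(image: np.ndarray, oocyte_mask: np.ndarray) -> float:
    """Median intensity outside the oocyte mask (the package's convention
    for 'background subtraction')."""
    outside = np.asarray(image)[~np.asarray(oocyte_mask, dtype=bool)]
    if outside.size == 0:
        raise ParameterError("oocyte mask covers the whole image; no background region")
    return float(np.median(outside))


def measure_fixed_circle(
    image: np.ndarray,
    pixel_size_um: tuple[float, float],
    center_um: tuple[float, float],
    diameter_um: float,
    background: float,
) -> IntensityMeasurement:
    """Sum of background-subtracted intensity inside a fixed circle.

    ``image`` is a 2D plane or max-projection; pixels whose centres fall
    within the circle contribute ``max(intensity - background, 0)``. Using
    one circle diameter (the mean oocyte diameter of the batch) across all
    compared cells makes totals comparable between groups.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ParameterError("measure_fixed_circle expects a 2D image")
    if diameter_um <= 0:
        raise ParameterError("diameter_um must be > 0")
    py, px = pixel_size_um
    cy, cx = center_um
    r = diameter_um / 2.0
    ny, nx = image.shape
    if cy - r < 0 or cx - r < 0 or cy + r > ny * py or cx + r > nx * px:
        raise ParameterError("circle exceeds image bounds")
    yy = (np.arange(ny) + 0.5) * py
    xx = (np.arange(nx) + 0.5) * px
    inside = (yy[:, None] - cy) ** 2 + (xx[None, :] - cx) ** 2 <= r**2
    values = np.clip(image[inside] - background, 0, None)
    return IntensityMeasurement(
        total_intensity=float(values.sum()),
        region="fixed_circle",
        circle_diameter_um=float(diameter_um),
        background_per_voxel=float(background),
        n_pixels=int(inside.sum()),
    )


def expression_ratio(
    group_a: list[IntensityMeasurement], group_b: list[IntensityMeasurement]
) -> dict:
    """Ratio of mean total intensities, mean(group_a) / mean(group_b).

    Both groups must be measured in the same region type with the same
    circle diameter; group sizes and SDs are reported alongside the ratio.
    """
    if not group_a or not group_b:
        raise ParameterError("both groups must be nonempty")
    regions = {m.region for m in group_a + group_b}
    if len(regions) != 1:
        raise ParameterError(f"mixed region types {sorted(regions)}")
    diameters = {m.circle_diameter_um for m in group_a + group_b}
    if len(diameters) != 1:
        raise ParameterError("all measurements must share one circle diameter")
    a = np.array([m.total_intensity for m in group_a])
    b = np.array([m.total_intensity for m in group_b])
    if b.mean() == 0:
        raise UndefinedRatioError("denominator group has zero mean intensity")
    return {
        "ratio": float(a.mean() / b.mean()),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)) if a.size > 1 else 0.0,
        "sd_b": float(b.std(ddof=1)) if b.size > 1 else 0.0,
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

@dataclass
class FrapTrace:
    """A bleach-recovery time series in raw and normalized units.

    ``times`` are in seconds; entry ``pre_bleach_index`` is the single
    pre-bleach frame, ``first_post_index`` the first frame after bleaching.
    Normalization maps the pre-bleach value to exactly 1 and the first
    post-bleach value to exactly 0.
    """

    times: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray
    pre_bleach_index: int = 0
    first_post_index: int = 1

    @property
    def post_bleach_times(self) -> np.ndarray:
        """Post-bleach time axis rebased to 0 at the first post-bleach frame."""
        t = self.times[self.first_post_index:]
        return t - t[0]

    @property
    def post_bleach_values(self) -> np.ndarray:
        return self.normalized[self.first_post_index:]


@dataclass
class FrapFit:
    """Single-exponential recovery fit ``F(t) = A (1 - exp(-k t))``."""

    k: float  # 1/s
    plateau: float  # A, dimensionless mobile fraction
    t_half: float  # s, ln2 / k
    rss: float

    def __post_init__(self) -> None:
        assert self.k > 0
        assert abs(self.t_half * self.k - LN2) < 1e-12


def normalize_frap(
    times, raw, pre_bleach_index: int = 0, first_post_index: int = 1
) -> FrapTrace:
    """Affine-normalize a raw trace: pre-bleach -> 1, first post-bleach -> 0.

    Invariant under positive affine transforms of the raw intensities, so
    fits are comparable across cells with different expression levels.
    """
    times = np.asarray(times, dtype=np.float64)
    raw = np.asarray(raw, dtype=np.float64)
    if times.shape != raw.shape or times.ndim != 1:
        raise ParameterError("times and raw must be 1D arrays of equal length")
    pre = raw[pre_bleach_index]
    post = raw[first_post_index]
    if pre <= post:
        raise NoBleachDetectedError(
            f"pre-bleach value {pre} is not above first post-bleach value {post}"
        )
    normalized = (raw - post) / (pre - post)
    return FrapTrace(
        times=times,
        raw=raw,
        normalized=normalized,
        pre_bleach_index=pre_bleach_index,
        first_post_index=first_post_index,
    )


_K_STARTS = (LN2 / 10.0, LN2 / 60.0, LN2 / 300.0)


def fit_frap(trace: FrapTrace, plateau_max: float = 1.5) -> FrapFit:
    """Least-squares single-exponential recovery fit on the post-bleach samples.

    The pre-bleach sentinel is excluded and t = 0 sits at the first
    post-bleach frame. Initialization is multi-start over recovery rates
    corresponding to half-times of 10, 60 and 300 s with the plateau seeded
    at the last sample; the best residual sum of squares wins, so the fit is
    deterministic. The plateau is bounded by ``plateau_max`` (default 1.5)
    to guard against pathological extrapolation.
    """
    t = trace.post_bleach_times
    y = trace.post_bleach_values
    if t.size < 5:
        raise ParameterError(f"need >= 5 post-bleach samples, got {t.size}")

    def residuals(theta):
        k, a = theta
        return a * (1.0 - np.exp(-k * t)) - y

    a0 = float(np.clip(y[-1], 1e-3, plateau_max))
    best = None
    rss_trail = []
    for k0 in _K_STARTS:
        try:
            sol = least_squares(
                residuals,
                x0=[k0, a0],
                bounds=([1e-8, 1e-6], [np.inf, plateau_max]),
                method="trf",
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        rss_trail.append(rss)
        if sol.success and (best is None or rss < best[0]):
            best = (rss, sol.x)
    if best is None:
        raise FitFailureError("recovery fit failed from all starts", rss_trail)
    rss, (k, a) = best
    return FrapFit(k=float(k), plateau=float(a), t_half=LN2 / float(k), rss=rss)
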