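"""3D segmentation chain for the three channels of an oocyte z-stack.

Replicates the structure of classic ImageJ-style spindle analysis:

* oocyte boundary from the bright-field channel via a local variance filter
  and triangle thresholding;
* spindle body from the microtubule channel via 3D Gaussian smoothing
  (radius 2 voxels) and Kapur maximum-entropy thresholding;
* aMTOC spots from the spot channel via a difference-of-Gaussians band-pass
  and maximum-entropy thresholding, with a minimum-volume filter.

Histograms use 256 bins after a linear min-max rescale of the considered
voxels (the 8-bit convention of classic ImageJ-style tools); the returned
threshold is a bin index that is mapped back to intensity units when
binarizing. Filters work in voxel units; object volumes and centroids are
physical (µm³, µm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateHistogramError,
    NoOocyteFoundError,
    NoSpindleFoundError,
    ParameterError,
    SizeError,
)
from .volume import MicroscopyVolume, indices_to_um

N_BINS = 256
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# Histograms and automatic thresholds
# ---------------------------------------------------------------------------

@dataclass
class Histogram256:
    """256-bin histogram of a voxel population, linearly rescaled min..max."""

    counts: np.ndarray
    vmin: float
    vmax: float

    @property
    def n_nonzero_bins(self) -> int:
        return int(np.count_nonzero(self.counts))

    def bin_to_value(self, bin_index: int) -> float:
        """Intensity corresponding to a bin index (upper edge convention)."""
        if self.vmax == self.vmin:
            return self.vmin
        return self.vmin + (bin_index + 1) / N_BINS * (self.vmax - self.vmin)


def histogram256(values: np.ndarray) -> Histogram256:
    """Build the 8-bit-convention histogram of the considered voxels."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ParameterError("cannot histogram an empty voxel set")
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        counts = np.zeros(N_BINS, dtype=np.int64)
        counts[0] = values.size
        return Histogram256(counts=counts, vmin=vmin, vmax=vmax)
    counts, _ = np.histogram(values, bins=N_BINS, range=(vmin, vmax))
    return Histogram256(counts=counts.astype(np.int64), vmin=vmin, vmax=vmax)


def triangle_threshold(h: Histogram256) -> int:
    """Triangle-method threshold bin.

    Draws the line from the histogram peak to the farthest nonempty bin on
    the longer-tail side and returns the bin maximizing the perpendicular
    distance between histogram and line. Ties break toward the peak-nearest
    (i.e. lower-distance-index) bin, matching the first argmax.
    """
    counts = np.asarray(h.counts, dtype=np.float64)
    nonzero = np.flatnonzero(counts)
    if nonzero.size < 2:
        raise DegenerateHistogramError("triangle threshold needs >= 2 nonzero bins")
    peak = int(np.argmax(counts))
    lo, hi = int(nonzero[0]), int(nonzero[-1])
    # side with the longer tail measured from the peak
    if (hi - peak) >= (peak - lo):
        tail = hi
        bins = np.arange(peak, tail + 1)
    else:
        tail = lo
        bins = np.arange(tail, peak + 1)
    if tail == peak:
        raise DegenerateHistogramError("peak coincides with the histogram extreme")
    # distance from (b, counts[b]) to the peak->tail chord; the common
    # denominator is constant so the numerator alone ranks candidates
    x1, y1 = float(peak), counts[peak]
    x2, y2 = float(tail), float(counts[tail])
    num = np.abs((y2 - y1) * bins - (x2 - x1) * counts[bins] + x2 * y1 - y2 * x1)
    t = int(bins[int(np.argmax(num))])
    return t


def max_entropy_threshold(h: Histogram256) -> int:
    """Kapur maximum-entropy threshold bin.

    Maximizes the sum of Shannon entropies of the normalized sub-histograms
    at or below t (background) and above t (foreground); ties break toward
    the lower bin. Invariant to uniform scaling of the counts.
    """
    counts = np.asarray(h.counts, dtype=np.float64)
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("max-entropy threshold needs >= 2 nonzero bins")
    p = counts / counts.sum()
    cum = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cum_plogp = np.cumsum(plogp)
    total_plogp = cum_plogp[-1]
    best_t, best_h = None, -np.inf
    for t in range(N_BINS - 1):
        p0, p1 = cum[t], 1.0 - cum[t]
        if p0 <= 0 or p1 <= 0:
            continue
        h0 = np.log(p0) - cum_plogp[t] / p0
        h1 = np.log(p1) - (total_plogp - cum_plogp[t]) / p1
        if h0 + h1 > best_h:
            best_h, best_t = h0 + h1, t
    if best_t is None:
        raise DegenerateHistogramError("no threshold separates the histogram")
    return int(best_t)


def binarize(volume_data: np.ndarray, h: Histogram256, threshold_bin: int) -> np.ndarray:
    """Foreground mask: voxels whose histogram bin exceeds the threshold bin."""
    if h.vmax == h.vmin:
        return np.zeros(volume_data.shape, dtype=bool)
    bins = np.clip(
        ((volume_data - h.vmin) / (h.vmax - h.vmin) * N_BINS).astype(np.int64),
        0,
        N_BINS - 1,
    )
    return bins > threshold_bin


# ---------------------------------------------------------------------------
# Filters (voxel units)
# ---------------------------------------------------------------------------

def variance_filter(
    v: MicroscopyVolume, radius_vox: int | tuple[int, int, int] = 3
) -> MicroscopyVolume:
    """Local population variance in a box window of half-width ``radius_vox``.

    Texture detector for the bright-field oocyte boundary: textured
    cytoplasm has high local variance, flat background near zero. Borders
    are mirror-padded. ``radius_vox`` may be one integer (cubic window) or
    a per-axis triple.
    """
    radii = (radius_vox,) * 3 if np.isscalar(radius_vox) else tuple(radius_vox)
    if any(r < 1 for r in radii):
        raise ParameterError("radius_vox must be >= 1")
    size = tuple(2 * int(r) + 1 for r in radii)
    if any(n < s for n, s in zip(v.shape, size)):
        raise SizeError(f"volume shape {v.shape} smaller than window size {size}")
    data = v.data
    mean = ndimage.uniform_filter(data, size=size, mode="reflect")
    mean_sq = ndimage.uniform_filter(data * data, size=size, mode="reflect")
    var = np.clip(mean_sq - mean * mean, 0, None)
    return v.with_data(var, channel_name=f"{v.channel_name}:variance")


def gaussian_filter_3d(v: MicroscopyVolume, radius_vox: float = 2.0) -> MicroscopyVolume:
    """Isotropic-in-voxel Gaussian smoothing with sigma = ``radius_vox``.

    Mirror boundary handling conserves the total intensity (to float
    precision), so segmentation thresholds are not biased at the borders.
    """
    if radius_vox <= 0:
        raise ParameterError("radius_vox must be > 0")
    out = ndimage.gaussian_filter(v.data, sigma=radius_vox, mode="reflect")
    return v.with_data(out, channel_name=f"{v.channel_name}:gauss{radius_vox:g}")


def physical_sigma_vox(
    radius_vox: float, voxel_size: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Per-axis sigma (voxel units) of a physically isotropic Gaussian.

    The smoothing radius is specified in units of the finest voxel edge
    (the in-plane pixel); coarser axes get proportionally smaller sigmas so
    the blur is isotropic in µm. On anisotropic stacks (e.g. 1 µm z-step vs
    0.25 µm pixels) this avoids smearing the spindle by several µm axially.
    """
    finest = min(voxel_size)
    return tuple(radius_vox * finest / v for v in voxel_size)  # type: ignore[return-value]


def dog_filter(
    v: MicroscopyVolume, sigma_small_vox: float = 1.5, sigma_large_vox: float = 3.0
) -> MicroscopyVolume:
    """Difference-of-Gaussians band-pass, clipped at zero.

    Enhances spot-like aMTOC signal while removing the diffuse background:
    a constant volume maps to all zeros.
    """
    if not (0 < sigma_small_vox < sigma_large_vox):
        raise ParameterError("need 0 < sigma_small_vox < sigma_large_vox")
    small = ndimage.gaussian_filter(v.data, sigma=sigma_small_vox, mode="reflect")
    large = ndimage.gaussian_filter(v.data, sigma=sigma_large_vox, mode="reflect")
    return v.with_data(np.clip(small - large, 0, None), channel_name=f"{v.channel_name}:dog")


# ---------------------------------------------------------------------------
# Labeled objects
# ---------------------------------------------------------------------------

@dataclass
class LabeledObjects:
    """3D connected components with per-object physical measurements."""

    label_grid: np.ndarray  # int, 0 = background, labels 1..n contiguous
    voxel_counts: np.ndarray  # (n,)
    volumes_um3: np.ndarray  # (n,)
    centroids_um: np.ndarray  # (n, 3) in (z, y, x) µm
    bounding_boxes: list[tuple[slice, slice, slice]]
    voxel_size: tuple[float, float, float]

    @property
    def n_objects(self) -> int:
        return int(self.voxel_counts.size)

    def mask(self, label: int) -> np.ndarray:
        return self.label_grid == label


def label_objects(
    mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    weights: np.ndarray | None = None,
) -> LabeledObjects:
    """26-connected labeling of a binary mask with physical measurements.

    Centroids are intensity-weighted when ``weights`` is given, otherwise
    geometric; both are voxel-centre based, in µm.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=STRUCT_26)
    voxel_volume = float(np.prod(voxel_size))
    if n == 0:
        return LabeledObjects(
            label_grid=labels,
            voxel_counts=np.zeros(0, dtype=np.int64),
            volumes_um3=np.zeros(0),
            centroids_um=np.zeros((0, 3)),
            bounding_boxes=[],
            voxel_size=tuple(voxel_size),
        )
    index = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(labels), labels, index).astype(np.int64)
    if weights is None:
        centroids_vox = np.array(ndimage.center_of_mass(mask, labels, index))
    else:
        centroids_vox = np.array(ndimage.center_of_mass(np.asarray(weights), labels, index))
    centroids_um = indices_to_um(centroids_vox, voxel_size)
    bboxes = ndimage.find_objects(labels)
    return LabeledObjects(
        label_grid=labels,
        voxel_counts=counts,
        volumes_um3=counts * voxel_volume,
        centroids_um=centroids_um,
        bounding_boxes=bboxes,
        voxel_size=tuple(voxel_size),
    )


def _keep_largest(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=STRUCT_26)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


# ---------------------------------------------------------------------------
# Stage segmentations
# ---------------------------------------------------------------------------

def extract_oocyte_mask(bright_field: MicroscopyVolume, radius_vox: int = 3) -> np.ndarray:
    """Oocyte boundary from the bright-field channel.

    variance filter -> 256-bin histogram -> triangle threshold -> binarize ->
    keep the largest 26-connected component -> fill internal holes. The
    resulting single-component mask crops the fluorescence channels. The
    variance window is scaled per axis (radius in units of the finest voxel
    edge) so the boundary dilation it causes is physically isotropic.
    """
    finest = min(bright_field.voxel_size)
    radii = tuple(
        max(1, round(radius_vox * finest / v)) for v in bright_field.voxel_size
    )
    var = variance_filter(bright_field, radius_vox=radii)
    try:
        h = histogram256(var.data)
        t = triangle_threshold(h)
    except DegenerateHistogramError as exc:
        raise NoOocyteFoundError(f"bright-field has no texture contrast: {exc}") from exc
    mask = binarize(var.data, h, t)
    if not mask.any():
        raise NoOocyteFoundError("empty foreground after triangle thresholding")
    mask = _keep_largest(mask)
    mask = ndimage.binary_fill_holes(mask)
    return mask


def segment_spindle(
    mt: MicroscopyVolume,
    oocyte_mask: np.ndarray,
    gaussian_radius_vox: float = 2.0,
) -> LabeledObjects:
    """Spindle body from the microtubule channel (single largest object).

    3D Gaussian smoothing (radius 2 in-plane pixels by default, scaled per
    axis so the blur is physically isotropic), max-entropy threshold of the
    in-mask histogram, then the largest 26-connected component is kept as
    the spindle.
    """
    oocyte_mask = np.asarray(oocyte_mask, dtype=bool)
    if not oocyte_mask.any():
        raise ParameterError("oocyte mask is empty")
    if gaussian_radius_vox <= 0:
        raise ParameterError("gaussian_radius_vox must be > 0")
    sigma = physical_sigma_vox(gaussian_radius_vox, mt.voxel_size)
    smoothed = mt.with_data(
        ndimage.gaussian_filter(mt.data, sigma=sigma, mode="reflect"),
        channel_name=f"{mt.channel_name}:gauss",
    )
    try:
        h = histogram256(smoothed.data[oocyte_mask])
        t = max_entropy_threshold(h)
    except DegenerateHistogramError as exc:
        raise NoSpindleFoundError(f"no intensity contrast in the oocyte: {exc}") from exc
    mask = binarize(smoothed.data, h, t) & oocyte_mask
    if not mask.any():
        raise NoSpindleFoundError("empty foreground after max-entropy thresholding")
    mask = _keep_largest(mask)
    return label_objects(mask, mt.voxel_size, weights=smoothed.data)


def detect_mtocs(
    spot: MicroscopyVolume,
    oocyte_mask: np.ndarray,
    min_volume_um3: float = 0.1,
    sigma_small_vox: float = 1.5,
    sigma_large_vox: float = 3.0,
) -> LabeledObjects:
    """aMTOC spots from the spot channel.

    DoG band-pass, max-entropy threshold of the in-mask histogram,
    26-connected labeling, then objects below ``min_volume_um3`` are
    discarded (suppresses single-voxel noise). Centroids are
    intensity-weighted on the DoG response. Zero objects is a valid result.
    """
    oocyte_mask = np.asarray(oocyte_mask, dtype=bool)
    if not oocyte_mask.any():
        raise ParameterError("oocyte mask is empty")
    dog = dog_filter(spot, sigma_small_vox=sigma_small_vox, sigma_large_vox=sigma_large_vox)
    try:
        h = histogram256(dog.data[oocyte_mask])
        t = max_entropy_threshold(h)
    except DegenerateHistogramError:
        return label_objects(np.zeros(spot.shape, dtype=bool), spot.voxel_size)
    mask = binarize(dog.data, h, t) & oocyte_mask
    objects = label_objects(mask, spot.voxel_size, weights=dog.data)
    keep = objects.volumes_um3 >= min_volume_um3
    if keep.all():
        return objects
    relabeled = np.zeros_like(objects.label_grid)
    new_label = 0
    for old_label, keep_it in enumerate(keep, start=1):
        if keep_it:
            new_label += 1
            relabeled[objects.label_grid == old_label] = new_label
    return label_objects(relabeled > 0, spot.voxel_size, weights=dog.data)
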