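"""Spindle-pole detection and 3D morphometrics.

The spindle poles are defined as the extremities of the object's largest
caliper (Feret) diameter, so spindle length is the pole-to-pole distance.
Widths are measured as the maximal perpendicular extent of the segmented
body within thin slabs along the pole axis — a slab around the midpoint for
the central width, a slab at each end for the pole widths. Per-aMTOC
positional metrics (minimum pole distance, length-normalized position,
signed border distance to the spindle surface) and per-oocyte summaries
(count, total volume, sorting SD) are the quantities used to follow aMTOC
sorting and clustering during meiosis I: scattered aMTOCs give a high SD of
normalized positions, pole-sorted aMTOCs a low one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .errors import DegenerateSpindleError, ParameterError, SlabFractionError
from .segment import STRUCT_26, LabeledObjects
from .volume import indices_to_um


@dataclass
class SpindleModel:
    """Segmented spindle with poles and shape metrics (all physical µm)."""

    pole_a: tuple[float, float, float]
    pole_b: tuple[float, float, float]
    length_um: float
    central_width_um: float
    pole_width_a_um: float
    pole_width_b_um: float
    axis_unit_vector: tuple[float, float, float]
    degenerate: bool = False

    @property
    def pole_width_um(self) -> float:
        """Reported pole width: mean of the two per-pole widths."""
        return 0.5 * (self.pole_width_a_um + self.pole_width_b_um)


@dataclass
class MTOCRecord:
    """Positional and size metrics of one detected aMTOC."""

    centroid_um: tuple[float, float, float]
    volume_um3: float
    dist_pole_min_um: float
    normalized_position: float  # dist_pole_min / spindle length, ~[0, 0.5+eps]
    border_distance_um: float  # signed; negative inside the spindle


@dataclass
class OocyteSummary:
    """One row per analyzed oocyte: clustering, sorting and shape metrics."""

    n_mtocs: int
    total_mtoc_volume_um3: float
    sorting_sd: float  # NaN when n_mtocs < 2
    spindle_length_um: float
    central_width_um: float
    pole_width_um: float
    pole_width_a_um: float
    pole_width_b_um: float


# ---------------------------------------------------------------------------
# Feret extremities
# ---------------------------------------------------------------------------

def boundary_voxel_coords_um(
    mask: np.ndarray, voxel_size: tuple[float, float, float]
) -> np.ndarray:
    """Physical coordinates of the object's boundary voxel centres."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=STRUCT_26, border_value=0)
    boundary = mask & ~eroded
    return indices_to_um(np.argwhere(boundary), voxel_size)


def feret_extremities(
    mask: np.ndarray, voxel_size: tuple[float, float, float]
) -> tuple[tuple[float, float, float], tuple[float, float, float], float, bool]:
    """Endpoints and length of the largest caliper (Feret) diameter.

    Works on boundary voxel centres in physical µm; the extreme pair is
    found exactly via the convex hull (the diameter of a finite point set is
    attained on its hull) with an all-pairs fallback for tiny or flat
    objects. Tie-break is the lexicographically smallest ordered pair and
    ``pole_a`` is the lexicographically smaller endpoint. A single-voxel
    object returns coincident poles, zero length, and a degenerate flag.
    """
    pts = boundary_voxel_coords_um(mask, voxel_size)
    if pts.shape[0] == 0:
        raise ParameterError("empty object")
    if pts.shape[0] == 1:
        p = tuple(float(v) for v in pts[0])
        return p, p, 0.0, True
    candidates = pts
    if pts.shape[0] > 400:
        try:
            hull = ConvexHull(pts)
            candidates = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) sets: brute-force instead
    diff = candidates[:, None, :] - candidates[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    dmax = d2.max()
    if dmax == 0.0:
        p = tuple(float(v) for v in candidates[0])
        return p, p, 0.0, True
    ii, jj = np.nonzero(d2 == dmax)
    pairs = []
    for i, j in zip(ii, jj):
        a, b = candidates[i], candidates[j]
        if tuple(a) > tuple(b):
            a, b = b, a
        pairs.append((tuple(float(v) for v in a), tuple(float(v) for v in b)))
    pole_a, pole_b = min(pairs)
    return pole_a, pole_b, float(math.sqrt(dmax)), False


# ---------------------------------------------------------------------------
# Spindle shape metrics
# ---------------------------------------------------------------------------

def spindle_metrics(
    mask: np.ndarray,
    poles: tuple[tuple[float, float, float], tuple[float, float, float]],
    voxel_size: tuple[float, float, float],
    pole_slab_fraction: float = 0.1,
    central_slab_fraction: float = 0.1,
) -> SpindleModel:
    """Spindle length and slab-based widths from the segmented body.

    Voxel centres are projected onto the pole axis (coordinate ``s`` in
    [0, L]); the central width is twice the maximal radial distance among
    voxels with ``|s - L/2| <= central_slab_fraction * L/2``, and each pole
    width twice the maximal radial distance among voxels within
    ``pole_slab_fraction * L`` of that pole.
    """
    pole_a = np.asarray(poles[0], dtype=np.float64)
    pole_b = np.asarray(poles[1], dtype=np.float64)
    length = float(np.linalg.norm(pole_b - pole_a))
    if length == 0.0:
        raise DegenerateSpindleError("coincident poles: spindle length is zero")
    if not (0 < pole_slab_fraction <= 0.5) or not (0 < central_slab_fraction <= 1):
        raise ParameterError("slab fractions out of range")
    axis = (pole_b - pole_a) / length
    pts = indices_to_um(np.argwhere(np.asarray(mask, dtype=bool)), voxel_size)
    if pts.shape[0] == 0:
        raise ParameterError("empty object")
    rel = pts - pole_a
    s = rel @ axis
    radial = np.linalg.norm(rel - np.outer(s, axis), axis=1)

    central = np.abs(s - length / 2.0) <= central_slab_fraction * length / 2.0
    near_a = s <= pole_slab_fraction * length
    near_b = s >= length * (1.0 - pole_slab_fraction)
    for name, sel in (("central", central), ("pole_a", near_a), ("pole_b", near_b)):
        if not sel.any():
            raise SlabFractionError(f"{name} slab contains no voxels")
    return SpindleModel(
        pole_a=tuple(float(v) for v in pole_a),
        pole_b=tuple(float(v) for v in pole_b),
        length_um=length,
        central_width_um=float(2.0 * radial[central].max()),
        pole_width_a_um=float(2.0 * radial[near_a].max()),
        pole_width_b_um=float(2.0 * radial[near_b].max()),
        axis_unit_vector=tuple(float(v) for v in axis),
    )


def spindle_model_from_mask(
    mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    pole_slab_fraction: float = 0.1,
    central_slab_fraction: float = 0.1,
) -> SpindleModel:
    """Convenience: Feret poles then slab metrics in one call."""
    pole_a, pole_b, length, degenerate = feret_extremities(mask, voxel_size)
    if degenerate:
        return SpindleModel(
            pole_a=pole_a,
            pole_b=pole_b,
            length_um=0.0,
            central_width_um=0.0,
            pole_width_a_um=0.0,
            pole_width_b_um=0.0,
            axis_unit_vector=(0.0, 0.0, 0.0),
            degenerate=True,
        )
    return spindle_metrics(
        mask,
        (pole_a, pole_b),
        voxel_size,
        pole_slab_fraction=pole_slab_fraction,
        central_slab_fraction=central_slab_fraction,
    )


# ---------------------------------------------------------------------------
# aMTOC positional metrics
# ---------------------------------------------------------------------------

def mtoc_position_metrics(
    centroid_um: tuple[float, float, float],
    volume_um3: float,
    spindle: SpindleModel,
    spindle_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
) -> MTOCRecord:
    """Distances of one aMTOC to the spindle poles and surface.

    ``normalized_position`` is the Euclidean distance to the nearest pole
    divided by spindle length (0 at a pole, 0.5 at the equator; slightly
    above 0.5 is possible for off-axis aMTOCs and is kept). The border
    distance is to the nearest spindle surface voxel, negated when the
    centroid lies inside the segmented spindle.
    """
    if spindle.degenerate or spindle.length_um == 0.0:
        raise DegenerateSpindleError("positional metrics need a non-degenerate spindle")
    c = np.asarray(centroid_um, dtype=np.float64)
    d_a = float(np.linalg.norm(c - np.asarray(spindle.pole_a)))
    d_b = float(np.linalg.norm(c - np.asarray(spindle.pole_b)))
    dist_min = min(d_a, d_b)
    boundary = boundary_voxel_coords_um(spindle_mask, voxel_size)
    border = float(cKDTree(boundary).query(c)[0])
    idx = tuple(int(v) for v in np.floor(c / np.asarray(voxel_size)))
    inside = all(0 <= i < n for i, n in zip(idx, spindle_mask.shape)) and bool(
        spindle_mask[idx]
    )
    return MTOCRecord(
        centroid_um=tuple(float(v) for v in c),
        volume_um3=float(volume_um3),
        dist_pole_min_um=dist_min,
        normalized_position=dist_min / spindle.length_um,
        border_distance_um=-border if inside else border,
    )


def mtoc_records(
    objects: LabeledObjects, spindle: SpindleModel, spindle_mask: np.ndarray
) -> list[MTOCRecord]:
    """Positional metrics for every detected aMTOC."""
    return [
        mtoc_position_metrics(
            tuple(objects.centroids_um[i]),
            float(objects.volumes_um3[i]),
            spindle,
            spindle_mask,
            objects.voxel_size,
        )
        for i in range(objects.n_objects)
    ]


# ---------------------------------------------------------------------------
# Per-oocyte summaries
# ---------------------------------------------------------------------------

def sorting_sd(records: list[MTOCRecord]) -> float:
    """Sample SD (n-1 denominator) of the length-normalized aMTOC positions.

    The per-oocyte sorting statistic: high when aMTOCs are scattered along
    the hemi-spindle, low once they are sorted to the poles. Returns NaN
    (missing, not an error) for fewer than two aMTOCs.
    """
    if len(records) < 2:
        return float("nan")
    positions = np.array([r.normalized_position for r in records])
    return float(positions.std(ddof=1))


def summarize_oocyte(spindle: SpindleModel, records: list[MTOCRecord]) -> OocyteSummary:
    """Bundle clustering (count, total volume), sorting SD and spindle shape."""
    return OocyteSummary(
        n_mtocs=len(records),
        total_mtoc_volume_um3=float(sum(r.volume_um3 for r in records)),
        sorting_sd=sorting_sd(records),
        spindle_length_um=spindle.length_um,
        central_width_um=spindle.central_width_um,
        pole_width_um=spindle.pole_width_um,
        pole_width_a_um=spindle.pole_width_a_um,
        pole_width_b_um=spindle.pole_width_b_um,
    )
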