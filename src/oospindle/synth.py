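"""Synthetic oocyte z-stacks with known ground truth.

The generator emulates the three-channel spinning-disk configuration used to
follow meiotic spindle morphogenesis in mouse oocytes: a bright-field channel
showing the oocyte as a textured disc, a microtubule channel (GFP-EB3 /
SiR-Tubulin analog) showing either a microtubule ball or a bipolar spindle,
and an aMTOC channel (mCherry-Plk4 analog) showing 0-40 compact blobs whose
positions along the spindle axis are controlled — scattered along the
hemi-spindle or sorted to the poles.

Geometry is specified in physical µm (axis order z,y,x, voxel centres at
``(index + 0.5) * voxel_size``); rendering applies a Gaussian PSF, Poisson
shot noise and additive Gaussian read noise, all driven by a single seed so
a scene is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import InvalidGeometryError, OutOfBoundsError, ParameterError
from .photometry import FrapTrace, normalize_frap
from .volume import MicroscopyVolume, voxel_centers_um, write_volume

CHANNEL_ROLES = ("bright_field", "microtubule", "mtoc")


@dataclass
class SceneTruth:
    """Complete ground-truth description of one synthetic scene.

    All coordinates in µm, axis order (z, y, x). ``mtoc_axial_fractions``
    are the intended distances of each aMTOC to its nearest pole, as a
    fraction of spindle length (0 = at a pole, 0.5 = spindle centre).
    """

    seed: int
    voxel_size: tuple[float, float, float]
    shape: tuple[int, int, int]
    oocyte_center: tuple[float, float, float]
    oocyte_radius: float
    spindle_pole_a: tuple[float, float, float]
    spindle_pole_b: tuple[float, float, float]
    spindle_radius: float
    stage: str  # "ball" or "bipolar"
    mtoc_centers: list[tuple[float, float, float]]
    mtoc_radii: list[float]
    mtoc_axial_fractions: list[float]
    background_level: float
    signal_level: float
    gaussian_noise_sd: float
    psf_sigma: tuple[float, float, float]
    bright_field_level: float = 500.0
    bright_field_texture: float = 400.0
    cytoplasm_fraction: float = 0.15  # diffuse reporter signal in the oocyte
    cytoplasm_texture: float = 0.1  # relative SD of the cytoplasmic mottling

    def __post_init__(self) -> None:
        if self.stage not in ("ball", "bipolar"):
            raise ParameterError(f"unknown stage {self.stage!r}")
        if tuple(self.shape) < (16, 64, 64):
            raise ParameterError(f"shape must be at least (16, 64, 64), got {self.shape}")
        if self.stage == "bipolar" and self.spindle_length == 0.0:
            raise InvalidGeometryError("bipolar stage requires distinct spindle poles")
        if any(r <= 0 for r in self.mtoc_radii):
            raise ParameterError("mtoc_radii must be > 0")
        if len(self.mtoc_centers) != len(self.mtoc_radii):
            raise ParameterError("mtoc_centers and mtoc_radii length mismatch")
        c = np.asarray(self.oocyte_center)
        for p in self.mtoc_centers:
            if np.linalg.norm(np.asarray(p) - c) > self.oocyte_radius:
                raise InvalidGeometryError(f"aMTOC at {p} lies outside the oocyte sphere")

    @property
    def spindle_length(self) -> float:
        a = np.asarray(self.spindle_pole_a)
        b = np.asarray(self.spindle_pole_b)
        return float(np.linalg.norm(b - a))

    @property
    def spindle_center(self) -> tuple[float, float, float]:
        a = np.asarray(self.spindle_pole_a)
        b = np.asarray(self.spindle_pole_b)
        return tuple((a + b) / 2.0)

    @property
    def ball_radius(self) -> float:
        """Radius of the equal-volume sphere used at the ball stage.

        The bipolar body (solid of revolution with radius profile
        ``R·sin(pi·s/L)``) has volume ``pi R^2 L / 2``; equating with
        ``4/3 pi r^3`` gives ``r = (3 R^2 L / 8)^(1/3)``.
        """
        return float((3.0 * self.spindle_radius**2 * self.spindle_length / 8.0) ** (1.0 / 3.0))

    def spindle_body_mask(self) -> np.ndarray:
        """Boolean ground-truth mask of the spindle body on the voxel grid."""
        z, y, x = voxel_centers_um(self.shape, self.voxel_size)
        if self.stage == "ball":
            cz, cy, cx = self.spindle_center
            r = self.ball_radius
            return (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= r**2
        a = np.asarray(self.spindle_pole_a)
        u = (np.asarray(self.spindle_pole_b) - a) / self.spindle_length
        dz, dy, dx = z - a[0], y - a[1], x - a[2]
        s = dz * u[0] + dy * u[1] + dx * u[2]
        rad2 = (dz - s * u[0]) ** 2 + (dy - s * u[1]) ** 2 + (dx - s * u[2]) ** 2
        L = self.spindle_length
        inside = (s >= 0) & (s <= L)
        profile = self.spindle_radius * np.sin(np.pi * np.clip(s, 0, L) / L)
        return inside & (rad2 <= profile**2)

    def oocyte_mask(self) -> np.ndarray:
        """Boolean ground-truth mask of the oocyte sphere (clipped to the grid)."""
        z, y, x = voxel_centers_um(self.shape, self.voxel_size)
        cz, cy, cx = self.oocyte_center
        return (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= self.oocyte_radius**2

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SceneTruth":
        d = json.loads(text)
        for key in ("voxel_size", "shape", "oocyte_center", "spindle_pole_a",
                    "spindle_pole_b", "psf_sigma"):
            d[key] = tuple(d[key])
        d["mtoc_centers"] = [tuple(p) for p in d["mtoc_centers"]]
        return cls(**d)


@dataclass
class SceneParams:
    """Generation settings for :func:`generate_scene`.

    Defaults describe a mid-meiosis-I mouse oocyte: a ~40 µm-diameter cell
    (scaled so the grid stays small), a 32 µm bipolar spindle of half-width
    8 µm, and aMTOC blobs of radius 0.6-1.0 µm. ``axial_distribution``
    selects scattered (uniform on [0, 0.5] of the hemi-spindle) vs
    pole-sorted (uniform on [0, 0.05]) placements; an explicit list of
    fractions overrides it.
    """

    n_mtocs: int = 10
    stage: str = "bipolar"
    shape: tuple[int, int, int] = (40, 192, 192)
    voxel_size: tuple[float, float, float] = (1.0, 0.25, 0.25)
    oocyte_radius: float = 20.0
    spindle_length: float = 32.0
    spindle_radius: float = 8.0
    axial_distribution: str = "scattered"  # "scattered" | "sorted"
    axial_fractions: list[float] | None = None
    mtoc_radius_range: tuple[float, float] = (0.6, 1.0)
    radial_jitter: float = 0.5
    min_mtoc_separation: float = 0.0  # µm; 0 disables the constraint
    max_axis_tilt_z: float = 0.25  # |z| component bound of the spindle axis
    background_level: float = 40.0
    signal_level: float = 500.0
    cytoplasm_fraction: float = 0.15
    cytoplasm_texture: float = 0.1
    gaussian_noise_sd: float = 10.0
    psf_sigma: tuple[float, float, float] = (0.8, 0.3, 0.3)

    def __post_init__(self) -> None:
        if self.n_mtocs < 0:
            raise ParameterError("n_mtocs must be >= 0")
        if self.stage not in ("ball", "bipolar"):
            raise ParameterError(f"unknown stage {self.stage!r}")
        if self.axial_distribution not in ("scattered", "sorted"):
            raise ParameterError(f"unknown axial_distribution {self.axial_distribution!r}")


def generate_scene(params: SceneParams, seed: int) -> SceneTruth:
    """Draw a fully specified scene from the generation settings.

    aMTOC centres are placed along the pole-pole axis at the requested axial
    fractions (distance to the nearest pole / spindle length) plus a bounded
    radial jitter perpendicular to the axis. Identical ``(params, seed)``
    yield an identical :class:`SceneTruth`.
    """
    if params.stage == "bipolar" and params.spindle_length <= 0 and params.n_mtocs > 0:
        raise InvalidGeometryError("cannot place aMTOCs on a zero-length bipolar spindle")
    rng = np.random.default_rng(seed)
    vz, vy, vx = params.voxel_size
    nz, ny, nx = params.shape
    extent = np.array([nz * vz, ny * vy, nx * vx])
    center = extent / 2.0

    if params.spindle_length / 2.0 > params.oocyte_radius:
        raise InvalidGeometryError("spindle poles would fall outside the oocyte")

    # Spindle axis: mostly in-plane, mild z tilt so the body stays in the stack.
    axis = rng.normal(size=3)
    axis[0] *= params.max_axis_tilt_z
    axis /= np.linalg.norm(axis)
    half = axis * params.spindle_length / 2.0
    pole_a = center - half
    pole_b = center + half

    explicit = params.axial_fractions is not None
    if explicit:
        requested = [float(f) for f in params.axial_fractions]
        if len(requested) != params.n_mtocs:
            raise ParameterError("axial_fractions length must equal n_mtocs")
        if any(not (0.0 <= f <= 0.5) for f in requested):
            raise ParameterError("axial fractions must lie in [0, 0.5]")
    fraction_high = 0.05 if params.axial_distribution == "sorted" else 0.5

    L = params.spindle_length

    def _try_placement() -> tuple[list, list] | None:
        """One sequential packing attempt; None if it jams."""
        placed_centers: list[tuple[float, float, float]] = []
        placed_fractions: list[float] = []
        for i in range(params.n_mtocs):
            for _attempt in range(100):
                f = requested[i] if explicit else float(rng.uniform(0.0, fraction_high))
                pole, other = (pole_a, pole_b) if rng.random() < 0.5 else (pole_b, pole_a)
                direction = (other - pole) / L
                base = pole + f * L * direction
                # jitter perpendicular to the axis, bounded by radial_jitter
                perp = rng.normal(size=3)
                perp -= np.dot(perp, direction) * direction
                norm = np.linalg.norm(perp)
                if norm > 0:
                    perp = perp / norm * rng.uniform(0.0, params.radial_jitter)
                p = base + perp
                if np.linalg.norm(p - center) > params.oocyte_radius:
                    p = base  # fall back on the axis; always inside the oocyte
                if params.min_mtoc_separation > 0 and placed_centers:
                    dists = np.linalg.norm(np.asarray(placed_centers) - p, axis=1)
                    if dists.min() < params.min_mtoc_separation:
                        continue
                placed_centers.append(tuple(float(v) for v in p))
                placed_fractions.append(f)
                break
            else:
                return None
        return placed_centers, placed_fractions

    placement = None
    for _restart in range(50):
        placement = _try_placement()
        if placement is not None:
            break
    if placement is None:
        raise InvalidGeometryError(
            f"could not place {params.n_mtocs} aMTOCs at separation "
            f">= {params.min_mtoc_separation} µm"
        )
    centers, fractions = placement
    radii = [float(rng.uniform(*params.mtoc_radius_range)) for _ in range(params.n_mtocs)]

    return SceneTruth(
        seed=int(seed),
        voxel_size=(vz, vy, vx),
        shape=(nz, ny, nx),
        oocyte_center=tuple(float(v) for v in center),
        oocyte_radius=float(params.oocyte_radius),
        spindle_pole_a=tuple(float(v) for v in pole_a),
        spindle_pole_b=tuple(float(v) for v in pole_b),
        spindle_radius=float(params.spindle_radius),
        stage=params.stage,
        mtoc_centers=centers,
        mtoc_radii=radii,
        mtoc_axial_fractions=fractions,
        background_level=float(params.background_level),
        signal_level=float(params.signal_level),
        gaussian_noise_sd=float(params.gaussian_noise_sd),
        psf_sigma=tuple(float(v) for v in params.psf_sigma),
        cytoplasm_fraction=float(params.cytoplasm_fraction),
        cytoplasm_texture=float(params.cytoplasm_texture),
    )


def mtoc_blob_sigmas_um(truth: SceneTruth, radius: float) -> tuple[float, float, float]:
    """Effective per-axis Gaussian sigma of a rendered aMTOC blob.

    The blob is a Gaussian of sigma = its radius convolved (analytically)
    with the Gaussian PSF, so sigma_axis = sqrt(radius^2 + psf_axis^2).
    """
    return tuple(math.sqrt(radius**2 + p**2) for p in truth.psf_sigma)  # type: ignore[return-value]


def mtoc_blob_integral_um3(truth: SceneTruth, radius: float) -> float:
    """Closed-form integral (a.u.·µm³) of one rendered blob of given radius."""
    sz, sy, sx = mtoc_blob_sigmas_um(truth, radius)
    return truth.signal_level * (2.0 * math.pi) ** 1.5 * sz * sy * sx


def _check_bounds(truth: SceneTruth) -> None:
    extent = np.array(truth.shape) * np.array(truth.voxel_size)
    for name, point in (("pole_a", truth.spindle_pole_a), ("pole_b", truth.spindle_pole_b)):
        p = np.asarray(point)
        if np.any(p < 0) or np.any(p > extent):
            raise OutOfBoundsError(f"spindle {name} {point} outside volume extent {tuple(extent)}")
    for p in truth.mtoc_centers:
        q = np.asarray(p)
        if np.any(q < 0) or np.any(q > extent):
            raise OutOfBoundsError(f"aMTOC centre {p} outside volume extent {tuple(extent)}")


def render_volumes(
    truth: SceneTruth,
) -> tuple[MicroscopyVolume, MicroscopyVolume, MicroscopyVolume]:
    """Render (bright_field, microtubule, mtoc) channels from ground truth.

    Microtubule channel: background plus uniform signal on the spindle body
    (ball or tapered bipolar solid of revolution), blurred by the PSF.
    aMTOC channel: background plus Gaussian blobs (PSF folded in
    analytically, see :func:`mtoc_blob_sigmas_um`). Bright field: a textured
    disc over the oocyte sphere, flat outside. Poisson shot noise then
    additive Gaussian read noise are applied to every channel; the whole
    render is a pure function of ``truth`` (including its seed).
    """
    from scipy import ndimage

    _check_bounds(truth)
    rng = np.random.default_rng(truth.seed)
    vz, vy, vx = truth.voxel_size
    sigma_vox = tuple(s / v for s, v in zip(truth.psf_sigma, (vz, vy, vx)))

    # --- bright field: textured oocyte disc (texture drawn first, fixed order)
    texture = rng.uniform(-0.5, 0.5, size=truth.shape)
    oomask = truth.oocyte_mask()
    bf = np.full(truth.shape, truth.bright_field_level, dtype=np.float64)
    bf += oomask * texture * truth.bright_field_texture

    # --- microtubule channel: mottled cytoplasmic reporter plus spindle body.
    # Organelles exclude the soluble reporter, so real cytoplasm is not flat;
    # the mottling is a smooth multiplicative field with ~1.5 µm grain.
    mottle = np.ones(truth.shape)
    if truth.cytoplasm_fraction > 0 and truth.cytoplasm_texture > 0:
        grain_vox = tuple(1.5 / v for v in (vz, vy, vx))
        field = ndimage.gaussian_filter(
            rng.normal(size=truth.shape), sigma=grain_vox, mode="reflect"
        )
        sd = field.std()
        if sd > 0:
            mottle = np.clip(1.0 + truth.cytoplasm_texture * field / sd, 0.0, None)
    mt = np.full(truth.shape, truth.background_level, dtype=np.float64)
    mt += truth.cytoplasm_fraction * truth.signal_level * oomask * mottle
    mt += truth.signal_level * truth.spindle_body_mask()
    mt = ndimage.gaussian_filter(mt, sigma=sigma_vox, mode="reflect")

    # --- aMTOC channel: analytic Gaussian blobs in local windows
    spots = np.full(truth.shape, truth.background_level, dtype=np.float64)
    for p, r in zip(truth.mtoc_centers, truth.mtoc_radii):
        _add_blob(spots, truth, np.asarray(p), r)

    def _noisy(expected: np.ndarray) -> np.ndarray:
        # Camera model: Poisson shot noise on expected counts, then additive
        # Gaussian read noise. gaussian_noise_sd = 0 switches the whole noise
        # model off so analytic renders are available for oracle tests.
        if truth.gaussian_noise_sd == 0:
            return np.clip(expected, 0, None)
        counts = rng.poisson(np.clip(expected, 0, None)).astype(np.float64)
        counts += rng.normal(0.0, truth.gaussian_noise_sd, size=expected.shape)
        return np.clip(counts, 0, None)

    bf_out, mt_out, sp_out = _noisy(bf), _noisy(mt), _noisy(spots)
    vs = (vz, vy, vx)
    return (
        MicroscopyVolume(bf_out, vs, "bright_field"),
        MicroscopyVolume(mt_out, vs, "microtubule"),
        MicroscopyVolume(sp_out, vs, "mtoc"),
    )


def _add_blob(grid: np.ndarray, truth: SceneTruth, center_um: np.ndarray, radius: float) -> None:
    """Accumulate one PSF-blurred Gaussian blob into ``grid`` (in place)."""
    sigmas = mtoc_blob_sigmas_um(truth, radius)
    vs = truth.voxel_size
    slices = []
    axes_sq = []
    for ax in range(3):
        n = truth.shape[ax]
        half = 5.0 * sigmas[ax]
        lo = max(0, int((center_um[ax] - half) / vs[ax]) - 1)
        hi = min(n, int((center_um[ax] + half) / vs[ax]) + 2)
        slices.append(slice(lo, hi))
        coords = (np.arange(lo, hi) + 0.5) * vs[ax]
        axes_sq.append(((coords - center_um[ax]) / sigmas[ax]) ** 2)
    zz, yy, xx = axes_sq
    blob = truth.signal_level * np.exp(
        -0.5 * (zz[:, None, None] + yy[None, :, None] + xx[None, None, :])
    )
    grid[slices[0], slices[1], slices[2]] += blob


# ---------------------------------------------------------------------------
# FRAP trace simulation
# ---------------------------------------------------------------------------

def simulate_frap_trace(
    t_half: float,
    plateau: float = 1.0,
    interval: float = 5.0,
    duration: float = 125.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FrapTrace:
    """Simulate a bleach-and-recovery time series.

    One pre-bleach frame is followed by frames at 0, ``interval``, ...,
    ``duration`` seconds with expectation ``plateau * (1 - 2**(-t/t_half))``
    (so the signal at ``t = t_half`` has recovered half of the plateau).
    Gaussian noise of SD ``noise_sd`` (fraction of the pre-bleach level) is
    added, the trace is embedded into arbitrary raw units and re-normalized
    exactly as a measured trace would be.
    """
    if t_half <= 0:
        raise ParameterError("t_half must be > 0")
    if not (0 < plateau <= 1):
        raise ParameterError("plateau must be in (0, 1]")
    if interval <= 0:
        raise ParameterError("interval must be > 0")
    rng = np.random.default_rng(seed)
    t_post = np.arange(0.0, duration + 0.5 * interval, interval)
    expectation = plateau * (1.0 - 2.0 ** (-t_post / t_half))
    values = np.concatenate([[1.0], expectation])
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=values.shape)
        noise[:2] = 0.0  # anchors: pre-bleach and first post-bleach frames
        values = values + noise
    times = np.concatenate([[-interval], t_post])
    raw = 50.0 + 1000.0 * values  # arbitrary camera units
    return normalize_frap(times, raw, pre_bleach_index=0, first_post_index=1)


# ---------------------------------------------------------------------------
# Scene I/O
# ---------------------------------------------------------------------------

def write_scene(truth: SceneTruth, out_dir, prefix: str) -> dict[str, Path]:
    """Render a scene and write one TIFF per channel plus a truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    channels = render_volumes(truth)
    paths: dict[str, Path] = {}
    for role, vol in zip(CHANNEL_ROLES, channels):
        path = out_dir / f"{prefix}.{role}.tif"
        write_volume(path, vol)
        paths[role] = path
    truth_path = out_dir / f"{prefix}.truth.json"
    truth_path.write_text(truth.to_json())
    paths["truth"] = truth_path
    return paths


def read_truth(path) -> SceneTruth:
    return SceneTruth.from_json(Path(path).read_text())


def params_from_yaml(path) -> SceneParams:
    """Load generation settings from a YAML mapping; unknown keys rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(SceneParams)}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown generation settings: {sorted(unknown)}")
    for key in ("shape", "voxel_size", "mtoc_radius_range", "psf_sigma"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SceneParams(**raw)
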