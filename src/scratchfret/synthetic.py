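"""Ground-truthed synthetic scratch-assay scenes.

Renders two-channel (donor/acceptor) time-lapse stacks of a confluent
monolayer with a vertical scratch, an imposed activity gradient decaying
with distance from the scratch edge, acceptor-channel vignetting, bright
puncta ("speckles"), camera dark offset and Gaussian read noise.  Every
stack ships with the exact per-pixel truth it was rendered from, so each
downstream stage of the pipeline can be validated without external data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "generate_scene",
    "generate_support_frames",
    "write_scene",
    "write_support_frames",
]

_UINT16_MAX = 65535

SUPPORT_KINDS = ("dark", "empty_well", "flat_calibration")

#: Default number of empty-well frames collected per well.
DEFAULT_EMPTY_WELL_FRAMES = 8


@dataclass
class SceneParams:
    """Parameters controlling a synthetic scratch-assay scene.

    Distances are in micrometres unless stated otherwise; intensities are
    camera counts.
    """

    image_height: int = 256
    image_width: int = 384
    pixel_scale: float = 0.325  # µm per pixel (config default, not a constant)
    scratch_half_width: float = 20.0  # µm
    cell_diameter_mean: float = 22.0  # µm
    edge_ratio: float = 1.3
    baseline_ratio: float = 1.0
    gradient_length: float = 30.0  # µm
    donor_level: float = 600.0
    vignetting_amplitude: float = 0.2  # fractional top-to-bottom gradient
    n_speckles: int = 0
    speckle_diameter: int = 4  # pixels
    dark_offset: float = 100.0
    noise_sd: float = 5.0
    closure_speed: float = 10.0  # µm per hour
    frame_interval: float = 15.0  # minutes
    n_frames: int = 1
    seed: int = 0
    # Texture / nuisance knobs (defaults exercise the pipeline's filters).
    membrane_boost: float = 0.8  # fractional extra brightness of cell rims
    membrane_rim_width: float = 2.0  # pixels
    media_level: float = 30.0  # counts inside the scratch / empty wells
    speckle_gain: float = 10.0  # speckle amplitude as multiple of donor_level
    edge_wave_amplitude: float = 0.0  # µm, sinusoidal scratch-edge waviness
    edge_wave_period: float = 60.0  # µm
    calibration_margin_px: int = 24  # cell-free field margin in calibration frames
    optics_sigma: float = 0.8  # px, light Gaussian blur emulating finite resolution

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if not (self.edge_ratio >= self.baseline_ratio > 0):
            raise ValueError("require edge_ratio >= baseline_ratio > 0")
        if self.gradient_length <= 0:
            raise ValueError("gradient_length must be positive")
        if self.scratch_half_width < 0:
            raise ValueError("scratch_half_width must be non-negative")
        width_um = self.image_width * self.pixel_scale
        if 2.0 * self.scratch_half_width >= width_um:
            raise ValueError(
                f"scratch (width {2 * self.scratch_half_width:g} µm) is wider "
                f"than the image ({width_um:g} µm)"
            )
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sd < 0 or self.dark_offset < 0:
            raise ValueError("noise_sd and dark_offset must be non-negative")


@dataclass
class SyntheticScene:
    """A rendered scene plus the ground truth it was rendered from."""

    donor_frames: np.ndarray  # (T, H, W) uint16
    acceptor_frames: np.ndarray  # (T, H, W) uint16
    truth_ratio_field: np.ndarray  # (T, H, W) float32
    truth_cell_mask: np.ndarray  # (T, H, W) bool
    truth_scratch_mask: np.ndarray  # (T, H, W) bool
    truth_membrane_mask: np.ndarray  # (T, H, W) bool
    truth_speckle_centers: list[np.ndarray]  # per frame, (K, 2) row/col
    params: SceneParams

    @property
    def frame_times_min(self) -> np.ndarray:
        return np.arange(self.params.n_frames) * self.params.frame_interval


def _scratch_mask(params: SceneParams, half_width_um: float) -> np.ndarray:
    """Boolean scratch band spanning the full image height."""
    h, w = params.image_height, params.image_width
    if half_width_um <= 0:
        return np.zeros((h, w), dtype=bool)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    center = (w - 1) / 2.0
    wave = 0.0
    if params.edge_wave_amplitude > 0:
        amp_px = params.edge_wave_amplitude / params.pixel_scale
        period_px = max(params.edge_wave_period / params.pixel_scale, 1.0)
        wave = amp_px * np.sin(2.0 * np.pi * rows / period_px)
    half_px = half_width_um / params.pixel_scale
    band = (cols > center - half_px + wave) & (cols < center + half_px + wave)
    return np.broadcast_to(band, (h, w)).copy()


def _edge_distance_um(scratch: np.ndarray, params: SceneParams) -> np.ndarray:
    """Per-pixel distance (µm) to the nearest scratch pixel.

    When the scratch has fully closed the original centre line is used so
    the activity gradient persists at the wound site.
    """
    if scratch.any():
        return ndi.distance_transform_edt(~scratch, sampling=params.pixel_scale)
    w = params.image_width
    cols = np.arange(w, dtype=float)[None, :]
    d = np.abs(cols - (w - 1) / 2.0) * params.pixel_scale
    return np.broadcast_to(d, (params.image_height, w)).copy()


def _monolayer_texture(
    params: SceneParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative cell texture: jittered hexagonal cells, bright rims.

    The rim (membrane) band is the set of pixels roughly equidistant from
    their two nearest cell centres — a Voronoi-boundary band.
    """
    h, w = params.image_height, params.image_width
    spacing = max(params.cell_diameter_mean / params.pixel_scale, 4.0)
    dy = spacing * np.sqrt(3.0) / 2.0
    centers = []
    row_i = 0
    y = -spacing
    while y < h + spacing:
        offset = 0.0 if row_i % 2 == 0 else spacing / 2.0
        x = -spacing + offset
        while x < w + spacing:
            jitter = rng.uniform(-0.18 * spacing, 0.18 * spacing, size=2)
            centers.append((y + jitter[0], x + jitter[1]))
            x += spacing
        y += dy
        row_i += 1
    tree = cKDTree(np.asarray(centers))
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    dist, idx = tree.query(pts, k=3)
    rim = (dist[:, 1] - dist[:, 0]) < params.membrane_rim_width
    # Rim brightness varies from cell-cell boundary to boundary and is
    # bimodal: a dim majority plus a few fully bright borders, as in
    # membrane reporters where occasional borders light up strongly.  The
    # bright ones are straight tracings that the speckle filter's
    # eccentricity branch must reject.  Pixels near three-cell junctions
    # take the dim level so bright segments stay clean line segments.
    n = len(centers)
    edge_boost = np.where(
        rng.random((n, n)) < 0.08, 1.0, rng.uniform(0.2, 0.55, size=(n, n))
    )
    i = np.minimum(idx[rim, 0], idx[rim, 1])
    j = np.maximum(idx[rim, 0], idx[rim, 1])
    boost = edge_boost[i, j]
    junction = (dist[rim, 2] - dist[rim, 1]) < 2.0 * params.membrane_rim_width
    boost[junction] = 0.4
    texture = np.ones(h * w)
    texture[rim] += params.membrane_boost * boost
    return texture.reshape(h, w), rim.reshape(h, w)


def _speckle_stamp(diameter: int) -> np.ndarray:
    r = diameter / 2.0
    yy, xx = np.mgrid[0:diameter, 0:diameter]
    c = (diameter - 1) / 2.0
    return (yy - c) ** 2 + (xx - c) ** 2 <= r**2


def _add_speckles(
    donor: np.ndarray,
    acceptor: np.ndarray,
    cell: np.ndarray,
    params: SceneParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add bright circular puncta at random cell positions; return centers."""
    if params.n_speckles <= 0:
        return np.zeros((0, 2), dtype=int)
    h, w = donor.shape
    margin = params.speckle_diameter + 2
    valid = cell.copy()
    valid[:margin, :] = valid[-margin:, :] = False
    valid[:, :margin] = valid[:, -margin:] = False
    coords = np.argwhere(valid)
    if len(coords) == 0:
        return np.zeros((0, 2), dtype=int)
    # puncta are rare and isolated: enforce a minimum separation so two
    # stamps never merge into one (elongated) object
    min_sep = 4 * params.speckle_diameter
    order = rng.permutation(len(coords))
    chosen: list[np.ndarray] = []
    for k in order:
        cand = coords[k]
        if all(np.abs(cand - c).max() >= min_sep for c in chosen):
            chosen.append(cand)
        if len(chosen) == params.n_speckles:
            break
    centers = np.array(chosen, dtype=int).reshape(-1, 2)
    stamp = _speckle_stamp(params.speckle_diameter)
    amp = params.speckle_gain * params.donor_level
    off = params.speckle_diameter // 2
    for r, c in centers:
        sl = (slice(r - off, r - off + stamp.shape[0]), slice(c - off, c - off + stamp.shape[1]))
        donor[sl][stamp] += amp
        acceptor[sl][stamp] += amp
    return centers


def _vignette(params: SceneParams) -> np.ndarray:
    """Linear top-to-bottom multiplicative gradient (column vector)."""
    h = params.image_height
    frac = np.arange(h) / max(h - 1, 1)
    return (1.0 + params.vignetting_amplitude * (frac - 0.5))[:, None]


def _digitize(img: np.ndarray, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, _UINT16_MAX).astype(np.uint16)


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Render a deterministic synthetic scratch-assay time lapse.

    At cell pixels the noise-free, vignette-free acceptor/donor ratio equals
    ``baseline_ratio + (edge_ratio - baseline_ratio) * exp(-d / gradient_length)``
    where ``d`` is the distance (µm) to the nearest scratch pixel.  The
    scratch half-width shrinks by ``closure_speed`` µm per hour, floored at 0.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w, t_n = params.image_height, params.image_width, params.n_frames

    texture, rim = _monolayer_texture(params, rng)

    donor_st = np.empty((t_n, h, w), dtype=np.uint16)
    acceptor_st = np.empty((t_n, h, w), dtype=np.uint16)
    ratio_st = np.empty((t_n, h, w), dtype=np.float32)
    cell_st = np.empty((t_n, h, w), dtype=bool)
    scratch_st = np.empty((t_n, h, w), dtype=bool)
    rim_st = np.empty((t_n, h, w), dtype=bool)
    centers_per_frame: list[np.ndarray] = []

    vign = _vignette(params)

    for t in range(t_n):
        hours = t * params.frame_interval / 60.0
        half_w = max(0.0, params.scratch_half_width - params.closure_speed * hours)
        scratch = _scratch_mask(params, half_w)
        cell = ~scratch
        d_um = _edge_distance_um(scratch, params)
        ratio = params.baseline_ratio + (
            params.edge_ratio - params.baseline_ratio
        ) * np.exp(-d_um / params.gradient_length)

        donor = np.where(cell, params.donor_level * texture, params.media_level)
        acceptor = np.where(cell, donor * ratio, params.media_level)

        centers = _add_speckles(donor, acceptor, cell, params, rng)

        if params.optics_sigma > 0:
            donor = ndi.gaussian_filter(donor, params.optics_sigma, mode="nearest")
            acceptor = ndi.gaussian_filter(acceptor, params.optics_sigma, mode="nearest")

        acceptor = acceptor * vign
        donor = donor + params.dark_offset
        acceptor = acceptor + params.dark_offset

        donor_st[t] = _digitize(donor, rng, params.noise_sd)
        acceptor_st[t] = _digitize(acceptor, rng, params.noise_sd)
        ratio_st[t] = ratio.astype(np.float32)
        cell_st[t] = cell
        scratch_st[t] = scratch
        rim_st[t] = rim & cell
        centers_per_frame.append(centers)

    return SyntheticScene(
        donor_frames=donor_st,
        acceptor_frames=acceptor_st,
        truth_ratio_field=ratio_st,
        truth_cell_mask=cell_st,
        truth_scratch_mask=scratch_st,
        truth_membrane_mask=rim_st,
        truth_speckle_centers=centers_per_frame,
        params=params,
    )


def generate_support_frames(
    params: SceneParams,
    kind: str,
    n_frames: int | None = None,
) -> dict[str, np.ndarray]:
    """Generate calibration stacks for both channels.

    kind:
      ``dark``             — frames of dark offset plus read noise only.
      ``empty_well``       — media-level background (plus dark offset and
                             noise); 8 frames by default.
      ``flat_calibration`` — confluent monolayer without a scratch and with a
                             spatially constant true ratio, acceptor vignetting
                             applied; used to build the ratio correction.

    Returns a dict with ``donor`` and ``acceptor`` (T, H, W) uint16 stacks.
    """
    params.validate()
    if kind not in SUPPORT_KINDS:
        raise ValueError(f"unknown support-frame kind {kind!r}; expected one of {SUPPORT_KINDS}")
    rng = np.random.default_rng((params.seed, SUPPORT_KINDS.index(kind) + 1))
    h, w = params.image_height, params.image_width

    if n_frames is None:
        n_frames = {
            "dark": 10,
            "empty_well": DEFAULT_EMPTY_WELL_FRAMES,
            "flat_calibration": DEFAULT_EMPTY_WELL_FRAMES,
        }[kind]
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")

    if kind == "dark":
        base_d = np.full((h, w), params.dark_offset)
        base_a = base_d
        stacks = {"donor": [], "acceptor": []}
        for _ in range(n_frames):
            stacks["donor"].append(_digitize(base_d, rng, params.noise_sd))
            stacks["acceptor"].append(_digitize(base_a, rng, params.noise_sd))
        return {k: np.stack(v) for k, v in stacks.items()}

    if kind == "empty_well":
        base = np.full((h, w), params.media_level)
        vign = _vignette(params)
        stacks = {"donor": [], "acceptor": []}
        for _ in range(n_frames):
            stacks["donor"].append(_digitize(base + params.dark_offset, rng, params.noise_sd))
            stacks["acceptor"].append(
                _digitize(base * vign + params.dark_offset, rng, params.noise_sd)
            )
        return {k: np.stack(v) for k, v in stacks.items()}

    # flat_calibration: confluent monolayer, constant true ratio, plus a
    # narrow cell-free field margin so background scaling/segmentation of
    # the calibration frames stays well-posed
    texture, _ = _monolayer_texture(params, rng)
    vign = _vignette(params)
    cell = np.ones((h, w), dtype=bool)
    margin = int(min(params.calibration_margin_px, w // 4))
    if margin > 0:
        cell[:, :margin] = False
    donor0 = np.where(cell, params.donor_level * texture, params.media_level)
    if params.optics_sigma > 0:
        donor0 = ndi.gaussian_filter(donor0, params.optics_sigma, mode="nearest")
    acceptor0 = donor0 * params.baseline_ratio
    stacks = {"donor": [], "acceptor": []}
    for _ in range(n_frames):
        stacks["donor"].append(_digitize(donor0 + params.dark_offset, rng, params.noise_sd))
        stacks["acceptor"].append(
            _digitize(acceptor0 * vign + params.dark_offset, rng, params.noise_sd)
        )
    return {k: np.stack(v) for k, v in stacks.items()}


# ---------------------------------------------------------------------------
# Disk output (16-bit TIFF stacks + JSON ground-truth sidecar)

def write_scene(scene: SyntheticScene, out_dir: str | Path) -> dict[str, Path]:
    """Write a scene as multi-page TIFFs plus a ground-truth sidecar.

    Masks go out as 8-bit TIFF (0/255); parameters and speckle coordinates
    as JSON.  Returns the map of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "donor": out / "donor.tif",
        "acceptor": out / "acceptor.tif",
        "truth_cell_mask": out / "truth_cell_mask.tif",
        "truth_scratch_mask": out / "truth_scratch_mask.tif",
        "truth_ratio_field": out / "truth_ratio_field.tif",
        "truth": out / "truth.json",
    }
    tifffile.imwrite(paths["donor"], scene.donor_frames, photometric="minisblack")
    tifffile.imwrite(paths["acceptor"], scene.acceptor_frames, photometric="minisblack")
    tifffile.imwrite(
        paths["truth_cell_mask"],
        scene.truth_cell_mask.astype(np.uint8) * 255,
        photometric="minisblack",
    )
    tifffile.imwrite(
        paths["truth_scratch_mask"],
        scene.truth_scratch_mask.astype(np.uint8) * 255,
        photometric="minisblack",
    )
    tifffile.imwrite(
        paths["truth_ratio_field"],
        scene.truth_ratio_field.astype(np.float32),
        photometric="minisblack",
    )
    truth = {
        "params": dataclasses.asdict(scene.params),
        "speckle_centers": [c.tolist() for c in scene.truth_speckle_centers],
    }
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths


def write_support_frames(
    params: SceneParams, out_dir: str | Path, kinds: tuple[str, ...] = SUPPORT_KINDS
) -> dict[str, Path]:
    """Write calibration stacks (dark / empty-well / flat-calibration)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for kind in kinds:
        stacks = generate_support_frames(params, kind)
        for channel, stack in stacks.items():
            p = out / f"{kind}_{channel}.tif"
            tifffile.imwrite(p, stack, photometric="minisblack")
            paths[f"{kind}_{channel}"] = p
    return paths
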