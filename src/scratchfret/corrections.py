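"""Camera dark-state correction and ratio (flat-field) correction.

The dark image is the per-pixel median of a stack of frames captured with
no illumination; it is subtracted from every experimental frame.  The
ratio-correction image is built from ratio images of unstimulated confluent
monolayers: a per-pixel median restricted to cell pixels, block-median
coarsening, expansion back to full resolution and Gaussian smoothing.
Experimental ratio images are divided by it, exactly once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi

__all__ = [
    "DarkImage",
    "RatioCorrectionImage",
    "estimate_dark_image",
    "subtract_dark",
    "build_ratio_correction",
    "apply_ratio_correction",
]

DEFAULT_BLOCK_SIZE = 24
DEFAULT_SMOOTH_SIGMA = 5.0


@dataclass
class DarkImage:
    """Per-pixel dark-state (no illumination) camera signal."""

    image: np.ndarray
    camera_id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("dark image must be 2-D")
        if np.any(self.image < 0):
            raise ValueError("dark image must be non-negative")


@dataclass
class RatioCorrectionImage:
    """Multiplicative flat-field for ratio images (strictly positive)."""

    image: np.ndarray
    block_size: int = DEFAULT_BLOCK_SIZE
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("correction image must be 2-D")
        if not np.all(np.isfinite(self.image)) or np.any(self.image <= 0):
            raise ValueError("correction image must be finite and strictly positive")


def _as_stack(frames: np.ndarray | list[np.ndarray]) -> np.ndarray:
    if isinstance(frames, (list, tuple)):
        shapes = {np.asarray(f).shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"mixed frame shapes in stack: {sorted(shapes)}")
        frames = np.stack([np.asarray(f) for f in frames])
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("expected a non-empty stack of 2-D frames")
    return frames


def estimate_dark_image(dark_frames: np.ndarray | list[np.ndarray], camera_id: str = "") -> DarkImage:
    """Per-pixel median over a stack of dark frames."""
    stack = _as_stack(dark_frames)
    return DarkImage(image=np.median(stack, axis=0), camera_id=camera_id)


def subtract_dark(frame: np.ndarray, dark: DarkImage) -> np.ndarray:
    """Subtract the dark image; negative values are retained."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != dark.image.shape:
        raise ValueError(f"shape mismatch: frame {frame.shape} vs dark {dark.image.shape}")
    return frame - dark.image


def _block_medians(
    image: np.ndarray, block_size: int, min_valid_fraction: float = 0.1
) -> np.ndarray:
    """Median of each block (partial blocks at right/bottom included).

    NaNs are ignored inside a block; a block whose valid-pixel fraction is
    below ``min_valid_fraction`` yields NaN (to be filled from neighbours)
    rather than trusting a handful of stray pixels.
    """
    h, w = image.shape
    nby = -(-h // block_size)
    nbx = -(-w // block_size)
    out = np.full((nby, nbx), np.nan)
    for by in range(nby):
        for bx in range(nbx):
            blk = image[
                by * block_size : min((by + 1) * block_size, h),
                bx * block_size : min((bx + 1) * block_size, w),
            ]
            finite = np.isfinite(blk)
            if finite.sum() >= max(1, min_valid_fraction * blk.size):
                out[by, bx] = np.nanmedian(blk)
    return out


def _fill_nearest(grid: np.ndarray) -> np.ndarray:
    """Replace NaN entries by the value of the nearest finite entry."""
    invalid = ~np.isfinite(grid)
    if not invalid.any():
        return grid
    if invalid.all():
        raise ValueError("no valid blocks: cell mask covers no calibration pixels")
    _, idx = ndi.distance_transform_edt(invalid, return_indices=True)
    return grid[tuple(idx)]


def build_ratio_correction(
    calibration_ratio_frames: np.ndarray | list[np.ndarray],
    cell_masks: np.ndarray | list[np.ndarray],
    block_size: int = DEFAULT_BLOCK_SIZE,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
) -> RatioCorrectionImage:
    """Build the multiplicative ratio correction from calibration ratios.

    Steps: per-pixel median over the stack using only cell-mask pixels;
    block-median coarsening (``block_size`` square blocks, partial edge
    blocks use their own median, empty blocks filled from the nearest valid
    block); expansion back to the input shape; Gaussian smoothing with
    ``smooth_sigma`` pixels.
    """
    stack = _as_stack(calibration_ratio_frames)
    masks = _as_stack(cell_masks).astype(bool)
    if masks.shape != stack.shape:
        raise ValueError(f"mask stack shape {masks.shape} != frame stack shape {stack.shape}")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")

    vals = np.where(masks, stack, np.nan)
    with np.errstate(all="ignore"):
        med = np.nanmedian(vals, axis=0)

    blocks = _block_medians(med, block_size)
    blocks = _fill_nearest(blocks)
    if np.any(blocks <= 0):
        bad = int(np.sum(blocks <= 0))
        raise ValueError(
            f"{bad} block median(s) are non-positive; calibration ratios are not "
            "strictly positive — check background subtraction and masks"
        )
    # expand block medians back to full resolution, then smooth; smoothing at
    # full resolution (sigma in pixels, < block_size) softens block edges
    # without flattening genuine large-scale gradients
    full = np.repeat(np.repeat(blocks, block_size, axis=0), block_size, axis=1)
    full = full[: med.shape[0], : med.shape[1]]
    if smooth_sigma > 0:
        full = ndi.gaussian_filter(full, sigma=smooth_sigma, mode="nearest")
    return RatioCorrectionImage(image=full, block_size=block_size, smooth_sigma=smooth_sigma)


def apply_ratio_correction(ratio: np.ndarray, correction: RatioCorrectionImage) -> np.ndarray:
    """Divide a ratio image by the correction; NaNs propagate unchanged."""
    ratio = np.asarray(ratio, dtype=float)
    if ratio.shape != correction.image.shape:
        raise ValueError(
            f"shape mismatch: ratio {ratio.shape} vs correction {correction.image.shape}"
        )
    return ratio / correction.image


# ---------------------------------------------------------------------------
# Disk round-trip

def write_correction(correction: RatioCorrectionImage, path: str | Path, provenance: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, correction.image.astype(np.float32), photometric="minisblack")
    sidecar = {
        "block_size": correction.block_size,
        "smooth_sigma": correction.smooth_sigma,
        "provenance": provenance or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_correction(path: str | Path) -> RatioCorrectionImage:
    path = Path(path)
    image = tifffile.imread(path).astype(float)
    meta_path = path.with_suffix(".json")
    kwargs = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        kwargs = {"block_size": meta["block_size"], "smooth_sigma": meta["smooth_sigma"]}
    return RatioCorrectionImage(image=image, **kwargs)
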