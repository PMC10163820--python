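"""Corrected, masked, smoothed acceptor/donor ratio images.

Masked pixels (background, speckles) are set to NaN in both channels and
stay NaN through every later stage.  Smoothing is NaN-aware (normalised
convolution) so masked pixels do not erode a halo into their neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .corrections import RatioCorrectionImage, apply_ratio_correction
from .masks import MaskSet

__all__ = ["RatioImage", "nan_gaussian_smooth", "compute_ratio_image"]

DEFAULT_SMOOTH_SIGMA = 2.0


@dataclass
class RatioImage:
    """Per-pixel acceptor/donor ratio with explicit missing markers."""

    values: np.ndarray  # float, NaN where missing
    missing: np.ndarray  # bool
    frame_time: float = 0.0  # minutes
    well_id: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != self.missing.shape:
            raise ValueError("values and missing mask must share a shape")
        ok = self.values[~self.missing]
        if ok.size and (not np.all(np.isfinite(ok)) or np.any(ok <= 0)):
            raise ValueError("non-missing ratio values must be finite and positive")


def nan_gaussian_smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing that ignores NaNs (normalised convolution).

    NaN pixels remain NaN in the output; valid pixels are the weighted
    average of the valid part of their neighbourhood.  ``sigma == 0``
    returns the input unchanged.
    """
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return image.copy()
    valid = np.isfinite(image)
    filled = np.where(valid, image, 0.0)
    num = ndi.gaussian_filter(filled, sigma=sigma, mode="nearest")
    den = ndi.gaussian_filter(valid.astype(float), sigma=sigma, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~valid] = np.nan
    out[den == 0] = np.nan
    return out


def compute_ratio_image(
    donor: np.ndarray,
    acceptor: np.ndarray,
    masks: MaskSet,
    correction: RatioCorrectionImage | None = None,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
    frame_time: float = 0.0,
    well_id: str = "",
) -> RatioImage:
    """Masked, smoothed, corrected acceptor/donor ratio image.

    Background and speckle pixels become NaN in both channels before
    NaN-aware Gaussian smoothing; the ratio is acceptor/donor, divided by
    the ratio correction (if given) exactly once.  Pixels whose smoothed
    donor is non-positive become missing.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if donor.shape != acceptor.shape or donor.shape != masks.cell.shape:
        raise ValueError("channel and mask shapes must match")

    excluded = masks.background | masks.speckle
    if excluded.all():
        raise ValueError("all pixels masked; no ratio to compute")

    don = np.where(excluded, np.nan, donor)
    acc = np.where(excluded, np.nan, acceptor)
    don = nan_gaussian_smooth(don, smooth_sigma)
    acc = nan_gaussian_smooth(acc, smooth_sigma)

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = acc / don
    ratio[~np.isfinite(ratio)] = np.nan
    ratio[np.where(np.isfinite(don), don <= 0, False)] = np.nan

    if correction is not None:
        ratio = apply_ratio_correction(ratio, correction)

    missing = ~np.isfinite(ratio) | (ratio <= 0)
    ratio = np.where(missing, np.nan, ratio)
    if missing.all():
        raise ValueError("all pixels missing after ratio computation")
    return RatioImage(values=ratio, missing=missing, frame_time=frame_time, well_id=well_id)
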