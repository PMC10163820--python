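"""Background/cell segmentation and bright-speckle detection.

Segmentation operates on the sum of the two (aligned, background-subtracted)
channels: percentile baseline subtraction, an intensity floor, log
transformation, percentile rescaling, Otsu thresholding, then morphological
clean-up.  The cell mask is defined as the inverse of the background mask.

The speckle filter sharpens the sum image with an alpha-parameterised 3x3
Laplacian, thresholds the brightened tail of the histogram, and discards
large or elongated connected components so that membrane rims (linear
structures) survive while rare bright puncta are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

__all__ = [
    "SegmentationParams",
    "MaskSet",
    "otsu_threshold",
    "background_mask_from_image",
    "cell_scratch_masks",
    "speckle_mask",
    "object_eccentricity",
]


@dataclass
class SegmentationParams:
    """Printed constants of the segmentation and speckle-filter recipes."""

    dim_fraction: float = 0.005  # dimmest fraction subtracted from the sum image
    intensity_floor: float = 20.0  # counts; minimum before log transform
    rescale_lo: float = 1.0  # percentile
    rescale_hi: float = 90.0  # percentile
    min_object_area: int = 50  # px; small objects removed / holes filled
    speckle_alpha: float = 0.9  # Laplacian kernel shape parameter
    speckle_bin_count_threshold: int = 9  # first bin with <= this many pixels
    speckle_max_area: int = 300  # px; larger bright objects discarded
    eccentricity_cutoff: float = 0.6  # more elongated objects discarded
    # sharpened-intensity histogram bin count; the absolute "<= 9 pixels"
    # rarity rule only marks the extreme tail if bins are sized for the
    # image area, so the default suits sub-megapixel frames
    speckle_hist_bins: int = 64
    closing_size: int = 3  # square structuring element for closings
    connectivity: int = 2  # skimage connectivity (2 => 8-connected)

    def validate(self) -> None:
        if not (0 < self.dim_fraction < 1):
            raise ValueError("dim_fraction must be in (0, 1)")
        if not (0 <= self.rescale_lo < self.rescale_hi <= 100):
            raise ValueError("rescale percentiles must be ordered within [0, 100]")
        for name in (
            "intensity_floor",
            "min_object_area",
            "speckle_bin_count_threshold",
            "speckle_max_area",
            "speckle_hist_bins",
            "closing_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.eccentricity_cutoff <= 1):
            raise ValueError("eccentricity_cutoff must be in [0, 1]")


@dataclass
class MaskSet:
    """Boolean masks produced by segmentation; cell is the inverse of background."""

    cell: np.ndarray
    background: np.ndarray
    scratch: np.ndarray
    speckle: np.ndarray
    connectivity: int = 8

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.cell, self.background, self.scratch, self.speckle)}
        if len(shapes) != 1:
            raise ValueError("all masks must share a shape")
        if np.any(self.cell & self.background):
            raise ValueError("cell and background masks must be disjoint")


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Threshold maximising between-class variance of the value histogram.

    Integer-valued input with a modest range is binned one bin per integer,
    so the returned threshold induces exactly the split found by exhaustive
    search.  Ties break toward the lowest qualifying threshold.  The
    threshold separates classes as ``values <= t`` / ``values > t``.
    """
    values = np.asarray(values)
    values = values[np.isfinite(values)] if values.dtype.kind == "f" else values
    if values.size < 2:
        raise ValueError("need at least two values")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ValueError("constant input: Otsu threshold undefined")

    flat = values.ravel()
    integral = np.issubdtype(flat.dtype, np.integer) or np.allclose(flat, np.rint(flat))
    if integral and (vmax - vmin) <= 4096:
        lo, hi = int(round(vmin)), int(round(vmax))
        counts = np.bincount((flat - lo).astype(np.int64), minlength=hi - lo + 1)
        centers = np.arange(lo, hi + 1, dtype=float)
    else:
        counts, edges = np.histogram(flat, bins=nbins, range=(vmin, vmax))
        centers = (edges[:-1] + edges[1:]) / 2.0

    counts = counts.astype(float)
    total = counts.sum()
    w0 = np.cumsum(counts)
    w1 = total - w0
    m = np.cumsum(counts * centers)
    mt = m[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m / w0
        mu1 = (mt - m) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    # candidate cut after bin i -> threshold between centers[i] and centers[i+1]
    sigma_b = sigma_b[:-1]
    best = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximum
    return float((centers[best] + centers[best + 1]) / 2.0)


def background_mask_from_image(frame: np.ndarray) -> np.ndarray:
    """Background pixels of a dark-corrected frame.

    The frame is clipped to >= 1, log-transformed to lift dim cell pixels,
    Otsu-thresholded, and pixels below the threshold form the mask.
    """
    frame = np.asarray(frame, dtype=float)
    logged = np.log(np.clip(frame, 1.0, None))
    t = otsu_threshold(logged)
    return logged < t


def _square(size: int) -> np.ndarray:
    return np.ones((size, size), dtype=bool)


def cell_scratch_masks(
    donor: np.ndarray,
    acceptor: np.ndarray,
    params: SegmentationParams | None = None,
) -> MaskSet:
    """Segment cells vs background (scratch included) from a channel pair.

    Pipeline: sum the channels; subtract the ``dim_fraction`` quantile;
    clip below ``intensity_floor``; log; rescale between the
    ``rescale_lo``/``rescale_hi`` percentiles; Otsu; below-threshold pixels
    form the background mask, which is morphologically closed, stripped of
    objects smaller than ``min_object_area``, and hole-filled.  The cell
    mask is the inverse.  The scratch mask is the largest background
    component; the speckle mask is filled in separately by
    :func:`speckle_mask`.
    """
    params = params or SegmentationParams()
    params.validate()
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if donor.shape != acceptor.shape:
        raise ValueError("channel shapes must match")
    if min(donor.shape) < params.closing_size:
        raise ValueError("image smaller than the structuring element")

    summed = donor + acceptor
    summed = summed - np.quantile(summed, params.dim_fraction)
    summed = np.clip(summed, params.intensity_floor, None)
    logged = np.log(summed)
    lo, hi = np.percentile(logged, [params.rescale_lo, params.rescale_hi])
    if hi > lo:
        rescaled = np.clip((logged - lo) / (hi - lo), 0.0, 1.0)
    else:
        # degenerate spread (e.g. nearly uniform image): threshold the log
        # image directly rather than failing
        rescaled = logged

    t = otsu_threshold(rescaled)
    background = rescaled < t
    background = morphology.closing(background, _square(params.closing_size))
    # objects strictly below min_object_area removed; holes below it filled
    background = morphology.remove_small_objects(
        background, max_size=params.min_object_area - 1, connectivity=params.connectivity
    )
    background = morphology.remove_small_holes(
        background, max_size=params.min_object_area - 1, connectivity=params.connectivity
    )
    cell = ~background

    from .profile import scratch_mask_from_background  # local import: no cycle at load

    scratch = (
        scratch_mask_from_background(background, connectivity=params.connectivity)
        if background.any()
        else np.zeros_like(background)
    )
    return MaskSet(
        cell=cell,
        background=background,
        scratch=scratch,
        speckle=np.zeros_like(background),
        connectivity=8 if params.connectivity == 2 else 4,
    )


def _alpha_laplacian_kernel(alpha: float) -> np.ndarray:
    """3x3 alpha-parameterised discrete Laplacian (alpha blends diagonals).

    kernel = 4/(alpha+1) * [[a/4, (1-a)/4, a/4],
                            [(1-a)/4, -1, (1-a)/4],
                            [a/4, (1-a)/4, a/4]]
    """
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must be in [0, 1]")
    a = alpha
    k = np.array(
        [
            [a / 4, (1 - a) / 4, a / 4],
            [(1 - a) / 4, -1.0, (1 - a) / 4],
            [a / 4, (1 - a) / 4, a / 4],
        ]
    )
    return 4.0 / (a + 1.0) * k


def speckle_mask(
    donor: np.ndarray,
    acceptor: np.ndarray,
    params: SegmentationParams | None = None,
) -> np.ndarray:
    """Detect rare bright puncta to exclude from ratio statistics.

    The summed image is sharpened by subtracting its alpha-Laplacian
    filtering; a histogram of the positive sharpened intensities is scanned
    upward and the left edge of the first bin holding at most
    ``speckle_bin_count_threshold`` pixels becomes the threshold.  The
    above-threshold mask is closed, then components larger than
    ``speckle_max_area`` or with eccentricity above ``eccentricity_cutoff``
    (membrane rims traced as lines) are dropped.
    """
    params = params or SegmentationParams()
    params.validate()
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if donor.shape != acceptor.shape:
        raise ValueError("channel shapes must match")

    summed = donor + acceptor
    lap = ndi.convolve(summed, _alpha_laplacian_kernel(params.speckle_alpha), mode="nearest")
    sharpened = summed - lap

    positive = sharpened[sharpened > 0]
    if positive.size == 0:
        warnings.warn("no positive sharpened intensities; empty speckle mask")
        return np.zeros_like(summed, dtype=bool)
    counts, edges = np.histogram(positive, bins=params.speckle_hist_bins)
    # scan upward from the histogram mode: the sparse bin sought is in the
    # bright tail, not among empty bins below the intensity bulk
    start = int(np.argmax(counts))
    qualifying = start + np.nonzero(
        counts[start:] <= params.speckle_bin_count_threshold
    )[0]
    if qualifying.size == 0:
        warnings.warn("no sparse histogram bin found; empty speckle mask")
        return np.zeros_like(summed, dtype=bool)
    threshold = edges[qualifying[0]]

    mask = sharpened > threshold
    mask = morphology.closing(mask, _square(params.closing_size))
    labels = measure.label(mask, connectivity=params.connectivity)
    keep = np.zeros_like(mask)
    for prop in measure.regionprops(labels):
        if prop.area > params.speckle_max_area:
            continue
        if prop.eccentricity > params.eccentricity_cutoff:
            continue
        keep[labels == prop.label] = True
    return keep


def speckle_component_table(
    donor: np.ndarray,
    acceptor: np.ndarray,
    params: SegmentationParams | None = None,
):
    """Per-candidate-component table (area, eccentricity, kept/dropped reason).

    Runs the speckle filter's candidate stages and reports why each
    connected component was kept or dropped; useful for QC export.
    """
    import pandas as pd

    params = params or SegmentationParams()
    params.validate()
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)

    summed = donor + acceptor
    lap = ndi.convolve(summed, _alpha_laplacian_kernel(params.speckle_alpha), mode="nearest")
    sharpened = summed - lap
    positive = sharpened[sharpened > 0]
    rows = []
    if positive.size:
        counts, edges = np.histogram(positive, bins=params.speckle_hist_bins)
        start = int(np.argmax(counts))
        qualifying = start + np.nonzero(
            counts[start:] <= params.speckle_bin_count_threshold
        )[0]
        if qualifying.size:
            threshold = edges[qualifying[0]]
            mask = morphology.closing(sharpened > threshold, _square(params.closing_size))
            labels = measure.label(mask, connectivity=params.connectivity)
            for prop in measure.regionprops(labels):
                if prop.area > params.speckle_max_area:
                    reason = "area"
                elif prop.eccentricity > params.eccentricity_cutoff:
                    reason = "eccentricity"
                else:
                    reason = ""
                rows.append(
                    {
                        "label": prop.label,
                        "area": int(prop.area),
                        "eccentricity": float(prop.eccentricity),
                        "centroid_row": prop.centroid[0],
                        "centroid_col": prop.centroid[1],
                        "kept": reason == "",
                        "dropped_reason": reason,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "area",
            "eccentricity",
            "centroid_row",
            "centroid_col",
            "kept",
            "dropped_reason",
        ],
    )


def object_eccentricity(component: np.ndarray) -> float:
    """Eccentricity of the moment-equivalent ellipse of a component.

    0 for a circle, approaching 1 for a line.
    """
    component = np.asarray(component, dtype=bool)
    if not component.any():
        raise ValueError("empty component")
    props = measure.regionprops(component.astype(np.uint8))
    return float(props[0].eccentricity)
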