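"""Channel registration and scaled empty-well background subtraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

__all__ = [
    "AlignedPair",
    "BackgroundModel",
    "align_channel_pair",
    "estimate_well_background",
    "scale_subtract_background",
    "apply_shift_and_crop",
]

DEFAULT_MAX_SHIFT = 10


@dataclass
class AlignedPair:
    """Donor/acceptor frames registered by rigid integer translation.

    ``shift_applied`` is the (dy, dx) translation applied to the acceptor;
    both frames are cropped to the common overlap so shapes match.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    shift_applied: tuple[int, int]

    def __post_init__(self) -> None:
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("aligned channels must share a shape")


@dataclass
class BackgroundModel:
    """Per-pixel median background (one channel) from empty-well frames."""

    image: np.ndarray
    n_source_frames: int


def _overlap_slices(shape: tuple[int, int], dy: int, dx: int):
    """Slices of the reference and moving images for translation (dy, dx).

    ``moving[r - dy, c - dx]`` aligns with ``reference[r, c]``; the returned
    slice pair selects the common overlap of both.
    """
    h, w = shape
    ref_r = slice(max(0, dy), h + min(0, dy))
    ref_c = slice(max(0, dx), w + min(0, dx))
    mov_r = slice(max(0, -dy), h + min(0, -dy))
    mov_c = slice(max(0, -dx), w + min(0, -dx))
    return (ref_r, ref_c), (mov_r, mov_c)


def apply_shift_and_crop(
    reference: np.ndarray, moving: np.ndarray, shift: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Crop ``reference`` and translated ``moving`` to their overlap."""
    (ref_sl, mov_sl) = _overlap_slices(reference.shape, *shift)
    return reference[ref_sl], moving[mov_sl]


def align_channel_pair(
    donor: np.ndarray,
    acceptor: np.ndarray,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> AlignedPair:
    """Register the acceptor onto the donor by integer phase correlation.

    The estimated rigid translation is applied to the acceptor and both
    frames are cropped to the common overlap.  A shift larger than
    ``max_shift`` in either axis is rejected (misconfigured cameras).
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if donor.shape != acceptor.shape:
        raise ValueError(f"shape mismatch: donor {donor.shape} vs acceptor {acceptor.shape}")
    shift, _, _ = phase_cross_correlation(donor, acceptor, upsample_factor=1)
    dy, dx = int(round(shift[0])), int(round(shift[1]))
    if abs(dy) > max_shift or abs(dx) > max_shift:
        raise ValueError(
            f"estimated channel shift ({dy}, {dx}) exceeds max_shift={max_shift}; "
            "check camera configuration"
        )
    don_c, acc_c = apply_shift_and_crop(donor, acceptor, (dy, dx))
    return AlignedPair(donor=don_c, acceptor=acc_c, shift_applied=(dy, dx))


def estimate_well_background(empty_frames: np.ndarray | list[np.ndarray]) -> BackgroundModel:
    """Per-pixel median over a stack of (dark-corrected) empty-well frames."""
    if isinstance(empty_frames, (list, tuple)):
        if len(empty_frames) == 0:
            raise ValueError("empty-well stack is empty")
        empty_frames = np.stack([np.asarray(f, dtype=float) for f in empty_frames])
    empty_frames = np.asarray(empty_frames, dtype=float)
    if empty_frames.ndim == 2:
        empty_frames = empty_frames[None]
    if empty_frames.ndim != 3 or empty_frames.shape[0] < 1:
        raise ValueError("expected a non-empty stack of 2-D frames")
    return BackgroundModel(
        image=np.median(empty_frames, axis=0), n_source_frames=empty_frames.shape[0]
    )


def scale_subtract_background(
    frame: np.ndarray,
    background: BackgroundModel,
    background_mask: np.ndarray,
) -> np.ndarray:
    """Subtract the empty-well background scaled to the frame's background.

    The scale is the ratio of the median frame intensity to the median
    background-model intensity, both over ``background_mask``.  Negative
    pixels after subtraction are retained.
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(background_mask, dtype=bool)
    if frame.shape != background.image.shape or frame.shape != mask.shape:
        raise ValueError("frame, background and mask shapes must match")
    if not mask.any():
        raise ValueError("background mask is empty; cannot scale background")
    bg_med = np.median(background.image[mask])
    if bg_med == 0:
        raise ValueError("background model median is zero over the mask")
    s = np.median(frame[mask]) / bg_med
    return frame - s * background.image
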