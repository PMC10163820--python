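"""Scratch-edge geometry, geodesic distance fields, and binned profiles.

Distances are geodesic through the cell mask with axial step cost 1 and
diagonal step cost sqrt(2) ("quasi-euclidean"), scaled to micrometres.
Pixels are sorted into 5 µm half-open distance bins per scratch side;
per-bin channel means give the bin FRET ratio.  Wells are the replication
unit for group means, sems and significance tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.graph import MCP_Geometric

from .corrections import RatioCorrectionImage

__all__ = [
    "ScratchGeometry",
    "DistanceField",
    "BinnedProfile",
    "GroupProfile",
    "scratch_mask_from_background",
    "scratch_edge_masks",
    "side_split_cell_mask",
    "quasi_euclidean_distance",
    "bin_fret_profile",
    "aggregate_group_profile",
    "welch_ttest",
    "compare_profiles_at_distance",
]

DEFAULT_BIN_WIDTH_UM = 5.0
DEFAULT_EDGE_DILATE_PX = 2
SIDES = ("left", "right")


@dataclass
class ScratchGeometry:
    """Scratch mask, its left/right edge strips, and the side cell masks."""

    scratch_mask: np.ndarray
    left_edge: np.ndarray | None
    right_edge: np.ndarray | None
    left_cells: np.ndarray | None = None
    right_cells: np.ndarray | None = None

    def edge(self, side: str) -> np.ndarray | None:
        return self.left_edge if side == "left" else self.right_edge

    def cells(self, side: str) -> np.ndarray | None:
        return self.left_cells if side == "left" else self.right_cells


@dataclass
class DistanceField:
    """Geodesic distances (µm) from a scratch edge; NaN where undefined."""

    distance: np.ndarray
    side: str
    pixel_scale: float


@dataclass
class BinnedProfile:
    """Per-bin channel means and ratio for one side/frame/well."""

    bin_edges: np.ndarray  # (n_bins + 1,) µm
    mean_donor: np.ndarray
    mean_acceptor: np.ndarray
    mean_ratio: np.ndarray
    n_pixels: np.ndarray
    side: str = ""
    frame_time: float = 0.0
    well_id: str = ""
    group_label: str = ""

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well": self.well_id,
                "group": self.group_label,
                "side": self.side,
                "time_min": self.frame_time,
                "bin_lo_um": self.bin_edges[:-1],
                "bin_hi_um": self.bin_edges[1:],
                "n_pixels": self.n_pixels,
                "mean_donor": self.mean_donor,
                "mean_acceptor": self.mean_acceptor,
                "mean_ratio": self.mean_ratio,
            }
        )


@dataclass
class GroupProfile:
    """Across-well mean and sem of bin ratios for one experimental group."""

    bin_edges: np.ndarray
    mean_ratio: np.ndarray
    sem_ratio: np.ndarray  # NaN where fewer than 2 wells contribute
    n_wells: np.ndarray
    group_label: str = ""
    frame_time: float | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def scratch_mask_from_background(
    background_mask: np.ndarray, connectivity: int = 2
) -> np.ndarray:
    """Largest connected component of the background mask."""
    background_mask = np.asarray(background_mask, dtype=bool)
    if not background_mask.any():
        raise ValueError("background mask is empty; no scratch to find")
    labels = measure.label(background_mask, connectivity=connectivity)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def _perimeter(mask: np.ndarray) -> np.ndarray:
    # border_value=1 so pixels on the image border are perimeter only where
    # they face interior background, not the image edge
    eroded = ndi.binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=1)
    return mask & ~eroded


def scratch_edge_masks(
    scratch_mask: np.ndarray,
    dilate_px: int = DEFAULT_EDGE_DILATE_PX,
    connectivity: int = 2,
) -> ScratchGeometry:
    """Left and right scratch-edge strips from a north-south scratch.

    The scratch perimeter is taken, pixels in the top and bottom image rows
    are removed (the scratch spans the full height), and the remaining
    pixels are split into lateral components; each is dilated by
    ``dilate_px`` to guarantee overlap with the cell mask.  A scratch
    touching a lateral image border yields a single edge, with the other
    side absent (None).
    """
    scratch_mask = np.asarray(scratch_mask, dtype=bool)
    if not scratch_mask.any():
        raise ValueError("scratch mask is empty")
    perim = _perimeter(scratch_mask)
    perim[0, :] = False
    perim[-1, :] = False
    if not perim.any():
        raise ValueError("scratch perimeter vanished after pruning top/bottom rows")

    # assign perimeter pixels to the left/right strip by the scratch's
    # per-row midline; this is robust to jagged pixels near the pruned
    # border rows bridging the two strips in a connectivity labeling
    h, w = scratch_mask.shape
    any_row = scratch_mask.any(axis=1)
    lo = np.argmax(scratch_mask, axis=1).astype(float)
    hi = (w - 1 - np.argmax(scratch_mask[:, ::-1], axis=1)).astype(float)
    if not any_row.all():
        idx = np.arange(h)
        good = idx[any_row]
        nearest = good[np.argmin(np.abs(idx[:, None] - good[None, :]), axis=1)]
        lo, hi = lo[nearest], hi[nearest]
    mid = ((lo + hi) / 2.0)[:, None]
    cols = np.arange(w)[None, :]
    left_edge = perim & (cols <= mid)
    right_edge = perim & (cols > mid)

    # a scratch touching a lateral image border has no perimeter there
    # (the image edge is not a wound edge)
    if scratch_mask[:, 0].sum() > 0.5 * h:
        left_edge = np.zeros_like(perim)
    if scratch_mask[:, -1].sum() > 0.5 * h:
        right_edge = np.zeros_like(perim)

    labels = measure.label(perim, connectivity=connectivity)
    n_comp = int(labels.max())
    sides_found = int(left_edge.any()) + int(right_edge.any())
    if sides_found == 0:
        raise ValueError("no lateral scratch edge found; irregular scratch geometry")
    if sides_found == 1:
        warnings.warn("single scratch edge found; the other side is absent")
    if n_comp > 2 * sides_found:
        warnings.warn(
            f"scratch perimeter fragmented into {n_comp} components; "
            "edge strips taken by midline split"
        )

    if dilate_px > 0:
        selem = morphology.disk(dilate_px)
        if left_edge.any():
            left_edge = morphology.dilation(left_edge, selem)
        if right_edge.any():
            right_edge = morphology.dilation(right_edge, selem)
        overlap = left_edge & right_edge
        if overlap.any():  # dilation across a narrow scratch
            left_edge &= ~overlap
            right_edge &= ~overlap
    return ScratchGeometry(
        scratch_mask=scratch_mask,
        left_edge=left_edge if left_edge.any() else None,
        right_edge=right_edge if right_edge.any() else None,
    )


def side_split_cell_mask(
    cell_mask: np.ndarray, scratch_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split cell pixels into left/right of the scratch's per-row span.

    Cell pixels inside the span (possible after edge dilation) go to the
    nearer side.  Rows without scratch pixels inherit the span of the
    nearest row that has one.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    scratch_mask = np.asarray(scratch_mask, dtype=bool)
    if cell_mask.shape != scratch_mask.shape:
        raise ValueError("mask shapes must match")
    if not scratch_mask.any():
        raise ValueError("scratch mask is empty")
    h, w = cell_mask.shape
    cols = np.arange(w)[None, :]

    any_row = scratch_mask.any(axis=1)
    lo = np.where(any_row, np.argmax(scratch_mask, axis=1), -1).astype(float)
    rev = scratch_mask[:, ::-1]
    hi = np.where(any_row, w - 1 - np.argmax(rev, axis=1), -1).astype(float)
    if not any_row.all():  # fill gaps from the nearest populated row
        idx = np.arange(h)
        good = idx[any_row]
        nearest = good[np.argmin(np.abs(idx[:, None] - good[None, :]), axis=1)]
        lo, hi = lo[nearest], hi[nearest]

    left = cell_mask & (cols < lo[:, None])
    right = cell_mask & (cols > hi[:, None])
    inside = cell_mask & ~left & ~right
    if inside.any():
        mid = (lo + hi)[:, None] / 2.0
        left |= inside & (cols <= mid)
        right |= inside & (cols > mid)
    return left, right


def quasi_euclidean_distance(
    region: np.ndarray, sources: np.ndarray, pixel_scale: float
) -> DistanceField:
    """Geodesic distance through ``region`` from ``sources`` in µm.

    Steps between 8-neighbours cost 1 (axial) or sqrt(2) (diagonal) pixel
    units, scaled by ``pixel_scale``.  Region pixels unreachable from any
    source are NaN, as is everything outside the region.
    """
    region = np.asarray(region, dtype=bool)
    sources = np.asarray(sources, dtype=bool)
    if region.shape != sources.shape:
        raise ValueError("region and sources shapes must match")
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    starts = np.argwhere(sources & region)
    if len(starts) == 0:
        raise ValueError("no source pixel lies inside the region")

    costs = np.where(region, 1.0, np.inf)
    mcp = MCP_Geometric(costs, fully_connected=True)
    cum, _ = mcp.find_costs(starts)
    dist = np.where(region & np.isfinite(cum), cum, np.nan) * pixel_scale
    return DistanceField(distance=dist, side="", pixel_scale=pixel_scale)


def bin_fret_profile(
    distance: DistanceField,
    donor: np.ndarray,
    acceptor: np.ndarray,
    correction: RatioCorrectionImage | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH_UM,
    max_distance: float | None = None,
    ratio_of_means: bool = True,
    **labels,
) -> BinnedProfile:
    """Bin channel means by distance from the scratch edge.

    Half-open bins [0, w), [w, 2w), ... in µm.  Per bin, the mean of the
    non-missing donor and acceptor pixels is taken; the bin ratio is
    (mean acceptor)/(mean donor) — or the mean of pixel ratios when
    ``ratio_of_means`` is False.  The ratio correction, when given, is
    divided into the acceptor exactly once, here.  Empty bins carry NaN
    means and ``n_pixels`` 0.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    d = distance.distance
    if donor.shape != acceptor.shape or donor.shape != d.shape:
        raise ValueError("distance and channel shapes must match")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    if correction is not None:
        if correction.image.shape != acceptor.shape:
            raise ValueError("correction shape must match the channels")
        acceptor = acceptor / correction.image

    ok = np.isfinite(d) & np.isfinite(donor) & np.isfinite(acceptor)
    dv = d[ok]
    if max_distance is None:
        max_distance = float(dv.max()) if dv.size else bin_width
    n_bins = max(int(np.ceil((max_distance + 1e-9) / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width

    idx = np.floor(dv / bin_width).astype(int)
    keep = idx < n_bins
    idx = idx[keep]
    don_v = donor[ok][keep]
    acc_v = acceptor[ok][keep]

    n_pixels = np.bincount(idx, minlength=n_bins)
    sum_d = np.bincount(idx, weights=don_v, minlength=n_bins)
    sum_a = np.bincount(idx, weights=acc_v, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_d = np.where(n_pixels > 0, sum_d / n_pixels, np.nan)
        mean_a = np.where(n_pixels > 0, sum_a / n_pixels, np.nan)
        if ratio_of_means:
            mean_r = mean_a / mean_d
        else:
            sum_r = np.bincount(idx, weights=acc_v / don_v, minlength=n_bins)
            mean_r = np.where(n_pixels > 0, sum_r / n_pixels, np.nan)
    mean_r = np.where(n_pixels > 0, mean_r, np.nan)

    return BinnedProfile(
        bin_edges=edges,
        mean_donor=mean_d,
        mean_acceptor=mean_a,
        mean_ratio=mean_r,
        n_pixels=n_pixels,
        **labels,
    )


def _well_level_means(
    profiles: list[BinnedProfile], n_bins: int
) -> dict[str, np.ndarray]:
    """Average bin ratios over frames/sides within each well (NaN-aware)."""
    by_well: dict[str, list[np.ndarray]] = {}
    for p in profiles:
        r = p.mean_ratio[:n_bins]
        pad = np.full(n_bins, np.nan)
        pad[: len(r)] = r
        by_well.setdefault(p.well_id, []).append(pad)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return {w: np.nanmean(np.stack(v), axis=0) for w, v in by_well.items()}


def aggregate_group_profile(
    profiles: list[BinnedProfile], group_label: str = ""
) -> GroupProfile:
    """Across-well mean ± sem profile; wells are the replication unit.

    Frames (and sides) within a well are averaged first; the mean and sem
    per bin are then taken across wells.  Sem is NaN where fewer than two
    wells populate the bin.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    widths = {float(p.bin_edges[1] - p.bin_edges[0]) for p in profiles}
    if len(widths) != 1:
        raise ValueError(f"mismatched bin grids: widths {sorted(widths)}")
    n_bins = max(len(p.bin_edges) - 1 for p in profiles)
    edges = np.arange(n_bins + 1) * widths.pop()

    wells = _well_level_means(profiles, n_bins)
    mat = np.stack(list(wells.values()))  # (n_wells, n_bins)
    n = np.sum(np.isfinite(mat), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    sem = np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    mean = np.where(n >= 1, mean, np.nan)
    return GroupProfile(
        bin_edges=edges, mean_ratio=mean, sem_ratio=sem, n_wells=n, group_label=group_label
    )


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided unpaired t test with Welch's correction.

    Guards the zero-variance degenerate case with a machine-epsilon
    variance floor (with a warning) instead of failing.
    """
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two wells per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero within-group variance; applying epsilon-variance guard")
        eps = (np.finfo(float).eps * max(abs(a.mean()), abs(b.mean()), 1.0)) ** 2
        va = vb = eps
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def compare_profiles_at_distance(
    group_a: list[BinnedProfile],
    group_b: list[BinnedProfile],
    distance: float,
    bin_width: float = DEFAULT_BIN_WIDTH_UM,
) -> tuple[float, float]:
    """Welch t test on well-level bin means at the bin containing ``distance``."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    bin_idx = int(distance // bin_width)
    vals = []
    for grp in (group_a, group_b):
        if not grp:
            raise ValueError("empty group")
        wells = _well_level_means(grp, bin_idx + 1)
        v = np.array([w[bin_idx] for w in wells.values()])
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise ValueError(
                f"fewer than two wells populate the bin at {distance} µm"
            )
        vals.append(v)
    return welch_ttest(vals[0], vals[1])
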