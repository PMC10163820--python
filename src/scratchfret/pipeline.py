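"""Deterministic per-well orchestration of the full analysis.

Stage order: dark correction -> channel alignment/crop -> background mask ->
scaled empty-well background subtraction -> cell/scratch segmentation ->
speckle filtering -> masked, smoothed, corrected ratio image -> scratch-edge
geometry -> geodesic distances per side -> binned profiles at each analysis
time.  The ratio correction divides the signal exactly once along each
output path; a provenance counter asserts this.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import corrections, preprocess, ratiometrics
from .corrections import DarkImage, RatioCorrectionImage
from .masks import MaskSet, SegmentationParams, background_mask_from_image, cell_scratch_masks, speckle_mask
from .preprocess import _overlap_slices
from .profile import (
    BinnedProfile,
    DEFAULT_BIN_WIDTH_UM,
    DEFAULT_EDGE_DILATE_PX,
    quasi_euclidean_distance,
    scratch_edge_masks,
    side_split_cell_mask,
    bin_fret_profile,
)
from .ratiometrics import RatioImage, nan_gaussian_smooth

__all__ = ["PipelineConfig", "WellResult", "run_well_timelapse", "load_image_stack"]

CSV_FLOAT_FORMAT = "%.9g"


class PipelineError(RuntimeError):
    """Stage failure with stage name and frame index attached."""

    def __init__(self, stage: str, frame: int | None, message: str):
        self.stage = stage
        self.frame = frame
        at = f" (frame {frame})" if frame is not None else ""
        super().__init__(f"[{stage}{at}] {message}")


@dataclass
class PipelineConfig:
    """Every knob of the per-well analysis, with cited defaults.

    Numeric defaults: frame interval 15 min; analysis times 1/6/12 h;
    ratio-correction blocks 24 px, smoothing sigma 5; channel smoothing
    sigma 2; 5 µm bins; 2 px edge dilation; report distances 5 and 100 µm.
    """

    donor_path: str = ""
    acceptor_path: str = ""
    dark_donor_path: str = ""
    dark_acceptor_path: str = ""
    empty_donor_path: str = ""
    empty_acceptor_path: str = ""
    ratio_correction_path: str = ""
    calibration_donor_path: str = ""
    calibration_acceptor_path: str = ""

    well_id: str = "well"
    group_label: str = ""
    pixel_scale: float = 0.325  # µm per pixel
    frame_interval: float = 15.0  # minutes
    analysis_times: tuple[float, ...] = (60.0, 360.0, 720.0)  # minutes
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    correction_block_size: int = 24
    correction_smooth_sigma: float = 5.0
    ratio_smooth_sigma: float = 2.0
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM
    edge_dilate_px: int = DEFAULT_EDGE_DILATE_PX
    max_shift_px: int = 10
    max_profile_distance_um: float | None = None
    report_distances: tuple[float, ...] = (5.0, 100.0)
    ratio_of_means: bool = True
    save_images: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        seg = raw.pop("segmentation", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("analysis_times", "report_distances"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if seg:
            cfg.segmentation = SegmentationParams(**seg)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analysis_times"] = list(self.analysis_times)
        d["report_distances"] = list(self.report_distances)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class FrameResult:
    frame_index: int
    frame_time: float
    shift: tuple[int, int]
    masks: MaskSet
    ratio: RatioImage
    profiles: list[BinnedProfile]
    qc: dict


@dataclass
class WellResult:
    config: PipelineConfig
    frames: list[FrameResult]
    profiles: list[BinnedProfile]
    provenance: dict

    def profiles_dataframe(self) -> pd.DataFrame:
        if not self.profiles:
            return pd.DataFrame()
        df = pd.concat([p.to_dataframe() for p in self.profiles], ignore_index=True)
        return df.sort_values(
            ["well", "group", "time_min", "side", "bin_lo_um"], kind="mergesort"
        ).reset_index(drop=True)


def load_image_stack(path: str | Path, channel_role: str = "", frame_interval: float = 15.0):
    """Load a grayscale TIFF stack as (T, H, W) float with frame times.

    Single frames become one-frame stacks at t = 0; RGB data is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image stack not found: {path} (role={channel_role!r})")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D frame or 3-D stack, got shape {arr.shape}")
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        raise ValueError(f"{path}: RGB(A) TIFF not supported; grayscale required")
    times = np.arange(arr.shape[0]) * frame_interval
    return arr.astype(float), times


def _load_required(cfg: PipelineConfig, attr: str, role: str):
    path = getattr(cfg, attr)
    if not path:
        raise PipelineError("load", None, f"config is missing required path {attr!r}")
    try:
        return load_image_stack(path, role, cfg.frame_interval)
    except (FileNotFoundError, ValueError) as e:
        raise PipelineError("load", None, str(e)) from e


def _nearest_frame(times: np.ndarray, t: float) -> int:
    return int(np.argmin(np.abs(times - t)))


def run_well_timelapse(cfg: PipelineConfig, output_dir: str | Path | None = None) -> WellResult:
    """Run the full analysis for one well; deterministic given the config."""
    donor_stack, times = _load_required(cfg, "donor_path", "donor")
    acceptor_stack, _ = _load_required(cfg, "acceptor_path", "acceptor")
    if donor_stack.shape != acceptor_stack.shape:
        raise PipelineError(
            "load", None,
            f"donor stack {donor_stack.shape} vs acceptor stack {acceptor_stack.shape}",
        )

    dark_donor, _ = _load_required(cfg, "dark_donor_path", "dark/donor")
    dark_acceptor, _ = _load_required(cfg, "dark_acceptor_path", "dark/acceptor")
    dark_d = corrections.estimate_dark_image(dark_donor, camera_id="donor")
    dark_a = corrections.estimate_dark_image(dark_acceptor, camera_id="acceptor")

    empty_donor, _ = _load_required(cfg, "empty_donor_path", "empty/donor")
    empty_acceptor, _ = _load_required(cfg, "empty_acceptor_path", "empty/acceptor")
    empty_d = np.stack([corrections.subtract_dark(f, dark_d) for f in empty_donor])
    empty_a = np.stack([corrections.subtract_dark(f, dark_a) for f in empty_acceptor])

    correction = None
    if cfg.ratio_correction_path:
        try:
            correction = corrections.read_correction(cfg.ratio_correction_path)
        except FileNotFoundError as e:
            raise PipelineError("load", None, str(e)) from e

    result = analyze_stacks(
        cfg, donor_stack, acceptor_stack, times, dark_d, dark_a, empty_d, empty_a, correction
    )
    if output_dir is not None:
        _write_well_result(result, Path(output_dir))
    return result


def analyze_stacks(
    cfg: PipelineConfig,
    donor_stack: np.ndarray,
    acceptor_stack: np.ndarray,
    times: np.ndarray,
    dark_d: DarkImage,
    dark_a: DarkImage,
    empty_d: np.ndarray,
    empty_a: np.ndarray,
    correction: RatioCorrectionImage | None,
) -> WellResult:
    """Array-level per-well analysis (dark/empty stacks already dark-corrected)."""
    frame_results: list[FrameResult] = []
    all_profiles: list[BinnedProfile] = []
    correction_applications = {"ratio_image": 0, "binned_profile": 0}

    for t_req in cfg.analysis_times:
        fi = _nearest_frame(times, t_req)
        t_min = float(times[fi])
        try:
            fr = _process_frame(
                cfg,
                donor_stack[fi],
                acceptor_stack[fi],
                dark_d,
                dark_a,
                empty_d,
                empty_a,
                correction,
                fi,
                t_min,
                correction_applications,
            )
        except PipelineError:
            raise
        except ValueError as e:
            raise PipelineError("frame", fi, str(e)) from e
        frame_results.append(fr)
        all_profiles.extend(fr.profiles)

    provenance = {
        "config": cfg.to_dict(),
        "frame_shifts": {fr.frame_index: list(fr.shift) for fr in frame_results},
        "correction_applications_per_frame": correction_applications,
        "n_frames_analyzed": len(frame_results),
    }
    return WellResult(
        config=cfg, frames=frame_results, profiles=all_profiles, provenance=provenance
    )


def _process_frame(
    cfg: PipelineConfig,
    donor_raw: np.ndarray,
    acceptor_raw: np.ndarray,
    dark_d: DarkImage,
    dark_a: DarkImage,
    empty_d: np.ndarray,
    empty_a: np.ndarray,
    correction: RatioCorrectionImage | None,
    frame_index: int,
    t_min: float,
    correction_applications: dict,
) -> FrameResult:
    seg = cfg.segmentation

    donor = corrections.subtract_dark(donor_raw, dark_d)
    acceptor = corrections.subtract_dark(acceptor_raw, dark_a)

    pair = preprocess.align_channel_pair(donor, acceptor, max_shift=cfg.max_shift_px)
    shift = pair.shift_applied
    ref_sl, mov_sl = _overlap_slices(donor.shape, *shift)

    # empty-well background models, cropped like the experimental pair
    bg_d = preprocess.estimate_well_background(empty_d[(slice(None),) + ref_sl])
    bg_a = preprocess.estimate_well_background(empty_a[(slice(None),) + mov_sl])

    bg_mask = background_mask_from_image(pair.donor + pair.acceptor)
    don_bs = preprocess.scale_subtract_background(pair.donor, bg_d, bg_mask)
    acc_bs = preprocess.scale_subtract_background(pair.acceptor, bg_a, bg_mask)

    mask_set = cell_scratch_masks(don_bs, acc_bs, seg)
    spk = speckle_mask(don_bs, acc_bs, seg)
    mask_set = MaskSet(
        cell=mask_set.cell,
        background=mask_set.background,
        scratch=mask_set.scratch,
        speckle=spk,
        connectivity=mask_set.connectivity,
    )

    corr = None
    if correction is not None:
        img = correction.image
        if img.shape == donor.shape and img.shape != pair.donor.shape:
            img = img[ref_sl]
        if img.shape != pair.donor.shape:
            raise PipelineError(
                "correction", frame_index,
                f"correction shape {correction.image.shape} incompatible with "
                f"aligned frame shape {pair.donor.shape}",
            )
        corr = RatioCorrectionImage(
            image=img, block_size=correction.block_size, smooth_sigma=correction.smooth_sigma
        )

    ratio = ratiometrics.compute_ratio_image(
        don_bs,
        acc_bs,
        mask_set,
        correction=corr,
        smooth_sigma=cfg.ratio_smooth_sigma,
        frame_time=t_min,
        well_id=cfg.well_id,
    )
    if corr is not None:
        correction_applications["ratio_image"] += 1

    excluded = mask_set.background | mask_set.speckle
    don_s = nan_gaussian_smooth(np.where(excluded, np.nan, don_bs), cfg.ratio_smooth_sigma)
    acc_s = nan_gaussian_smooth(np.where(excluded, np.nan, acc_bs), cfg.ratio_smooth_sigma)

    geometry = scratch_edge_masks(
        mask_set.scratch, dilate_px=cfg.edge_dilate_px, connectivity=seg.connectivity
    )
    left_cells, right_cells = side_split_cell_mask(mask_set.cell, mask_set.scratch)
    geometry.left_cells, geometry.right_cells = left_cells, right_cells

    profiles: list[BinnedProfile] = []
    for side in ("left", "right"):
        edge = geometry.edge(side)
        cells = geometry.cells(side)
        if edge is None or cells is None or not cells.any():
            continue
        if not (edge & cells).any():
            continue
        dfield = quasi_euclidean_distance(cells, edge, cfg.pixel_scale)
        dfield.side = side
        prof = bin_fret_profile(
            dfield,
            don_s,
            acc_s,
            correction=corr,
            bin_width=cfg.bin_width_um,
            max_distance=cfg.max_profile_distance_um,
            ratio_of_means=cfg.ratio_of_means,
            side=side,
            frame_time=t_min,
            well_id=cfg.well_id,
            group_label=cfg.group_label,
        )
        if corr is not None:
            correction_applications["binned_profile"] += 1
        profiles.append(prof)

    qc = {
        "frame_index": frame_index,
        "time_min": t_min,
        "shift_dy": shift[0],
        "shift_dx": shift[1],
        "fraction_missing": float(np.mean(ratio.missing)),
        "ratio_median": float(np.nanmedian(ratio.values)),
        "cell_fraction": float(np.mean(mask_set.cell)),
        "speckle_pixels": int(mask_set.speckle.sum()),
    }
    return FrameResult(
        frame_index=frame_index,
        frame_time=t_min,
        shift=shift,
        masks=mask_set,
        ratio=ratio,
        profiles=profiles,
        qc=qc,
    )


def build_correction_from_calibration(cfg: PipelineConfig) -> RatioCorrectionImage:
    """Build the ratio-correction image from unstimulated-monolayer stacks.

    Each calibration frame pair runs through the standard pipeline (dark
    correction, alignment, scaled background subtraction, segmentation,
    speckle filtering, smoothing, ratio) with no correction applied; the
    resulting ratio stack and cell masks feed the block-median correction
    builder.
    """
    calib_d, _ = _load_required(cfg, "calibration_donor_path", "calibration/donor")
    calib_a, _ = _load_required(cfg, "calibration_acceptor_path", "calibration/acceptor")
    dark_donor, _ = _load_required(cfg, "dark_donor_path", "dark/donor")
    dark_acceptor, _ = _load_required(cfg, "dark_acceptor_path", "dark/acceptor")
    dark_d = corrections.estimate_dark_image(dark_donor, camera_id="donor")
    dark_a = corrections.estimate_dark_image(dark_acceptor, camera_id="acceptor")
    empty_donor, _ = _load_required(cfg, "empty_donor_path", "empty/donor")
    empty_acceptor, _ = _load_required(cfg, "empty_acceptor_path", "empty/acceptor")
    empty_d = np.stack([corrections.subtract_dark(f, dark_d) for f in empty_donor])
    empty_a = np.stack([corrections.subtract_dark(f, dark_a) for f in empty_acceptor])

    ratio_frames: list[np.ndarray] = []
    cell_masks: list[np.ndarray] = []
    shift = None
    for i in range(calib_d.shape[0]):
        donor = corrections.subtract_dark(calib_d[i], dark_d)
        acceptor = corrections.subtract_dark(calib_a[i], dark_a)
        if shift is None:  # one rigid camera offset for the whole stack
            pair = preprocess.align_channel_pair(donor, acceptor, max_shift=cfg.max_shift_px)
            shift = pair.shift_applied
        ref_sl, mov_sl = _overlap_slices(donor.shape, *shift)
        don_al, acc_al = donor[ref_sl], acceptor[mov_sl]

        bg_d = preprocess.estimate_well_background(empty_d[(slice(None),) + ref_sl])
        bg_a = preprocess.estimate_well_background(empty_a[(slice(None),) + mov_sl])
        bg_mask = background_mask_from_image(don_al + acc_al)
        if not bg_mask.any():
            raise PipelineError("calibrate", i, "empty background mask in calibration frame")
        don_bs = preprocess.scale_subtract_background(don_al, bg_d, bg_mask)
        acc_bs = preprocess.scale_subtract_background(acc_al, bg_a, bg_mask)

        mask_set = cell_scratch_masks_no_scratch(don_bs, acc_bs, cfg.segmentation)
        spk = speckle_mask(don_bs, acc_bs, cfg.segmentation)
        mask_set = MaskSet(
            cell=mask_set.cell,
            background=mask_set.background,
            scratch=mask_set.scratch,
            speckle=spk,
            connectivity=mask_set.connectivity,
        )
        ratio = ratiometrics.compute_ratio_image(
            don_bs, acc_bs, mask_set, correction=None, smooth_sigma=cfg.ratio_smooth_sigma
        )
        ratio_frames.append(ratio.values)
        cell_masks.append(mask_set.cell & ~mask_set.speckle)

    return corrections.build_ratio_correction(
        ratio_frames,
        cell_masks,
        block_size=cfg.correction_block_size,
        smooth_sigma=cfg.correction_smooth_sigma,
    )


def cell_scratch_masks_no_scratch(don_bs, acc_bs, seg: SegmentationParams) -> MaskSet:
    """Segment a confluent calibration frame, where no scratch may exist."""
    try:
        return cell_scratch_masks(don_bs, acc_bs, seg)
    except ValueError:
        # unscratched confluent frame: Otsu may degenerate — treat everything
        # above the intensity floor as cells
        cell = np.asarray(don_bs + acc_bs) > seg.intensity_floor
        empty = np.zeros_like(cell)
        return MaskSet(cell=cell, background=~cell, scratch=empty, speckle=empty)


def _write_well_result(result: WellResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    df = result.profiles_dataframe()
    df.to_csv(out / "profiles.csv", index=False, float_format=CSV_FLOAT_FORMAT)
    qc = pd.DataFrame([fr.qc for fr in result.frames])
    qc.to_csv(out / "qc.csv", index=False, float_format=CSV_FLOAT_FORMAT)
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=2, sort_keys=True))
    if result.config.save_images:
        for fr in result.frames:
            tag = f"t{int(fr.frame_time):04d}"
            tifffile.imwrite(
                out / f"ratio_{tag}.tif",
                fr.ratio.values.astype(np.float32),
                photometric="minisblack",
            )
            for name in ("cell", "background", "scratch", "speckle"):
                m = getattr(fr.masks, name)
                tifffile.imwrite(
                    out / f"mask_{name}_{tag}.tif",
                    m.astype(np.uint8) * 255,
                    photometric="minisblack",
                )
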