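"""Shared fixtures: small synthetic scenes and on-disk well datasets."""

from __future__ import annotations

import numpy as np
import pytest

from scratchfret.corrections import write_correction
from scratchfret.pipeline import PipelineConfig, build_correction_from_calibration
from scratchfret.synthetic import (
    SceneParams,
    generate_scene,
    write_scene,
    write_support_frames,
)


def small_scene_params(**overrides) -> SceneParams:
    """A fast-to-render scene exercising every pipeline stage."""
    base = dict(
        image_height=192,
        image_width=320,
        pixel_scale=1.0,
        scratch_half_width=20.0,
        edge_ratio=1.3,
        baseline_ratio=1.0,
        gradient_length=30.0,
        n_speckles=20,
        vignetting_amplitude=0.2,
        noise_sd=5.0,
        n_frames=1,
        seed=3,
    )
    base.update(overrides)
    return SceneParams(**base)


def make_well_dataset(tmp_path, params: SceneParams, with_correction: bool = True):
    """Write a scene plus its calibration stacks; return an analysis config."""
    scene = generate_scene(params)
    d = tmp_path
    write_scene(scene, d)
    write_support_frames(params, d)
    cfg = PipelineConfig(
        donor_path=str(d / "donor.tif"),
        acceptor_path=str(d / "acceptor.tif"),
        dark_donor_path=str(d / "dark_donor.tif"),
        dark_acceptor_path=str(d / "dark_acceptor.tif"),
        empty_donor_path=str(d / "empty_well_donor.tif"),
        empty_acceptor_path=str(d / "empty_well_acceptor.tif"),
        calibration_donor_path=str(d / "flat_calibration_donor.tif"),
        calibration_acceptor_path=str(d / "flat_calibration_acceptor.tif"),
        pixel_scale=params.pixel_scale,
        frame_interval=params.frame_interval,
        analysis_times=(0.0,),
        max_profile_distance_um=120.0,
        save_images=False,
        well_id="well0",
    )
    if with_correction:
        correction = build_correction_from_calibration(cfg)
        write_correction(correction, d / "correction.tif")
        cfg.ratio_correction_path = str(d / "correction.tif")
    return scene, cfg


@pytest.fixture(scope="session")
def default_scene():
    """One rendered default scene reused across read-only tests."""
    return generate_scene(small_scene_params())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
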