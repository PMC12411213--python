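"""End-to-end per-scan processing: the load -> crop -> smooth -> strip ->
register -> resample -> NWU chain used by the command line."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atlas_regions import RegionAtlas
from .nwu_core import DEFAULT_HU_WINDOW, NWUResult, compute_nwu
from .preprocess import (
    PreprocessReport,
    RegistrationConfig,
    default_smoothing_sigma_mm,
    register_to_atlas,
    resample,
    select_field_of_view,
    skull_strip,
    smooth,
)
from .volume_io import CTVolume, read_dicom_series, read_nifti


@dataclass
class RunConfig:
    """All pipeline defaults in one place; CLI flags override YAML values."""

    side: str = "auto"                     # left | right | auto
    hu_window: tuple = DEFAULT_HU_WINDOW
    smoothing_sigma_mm: float | None = None  # None -> 0.5 x in-plane voxel
    air_threshold: float = -500.0
    fov_margin: int = 2
    bone_threshold: float = 300.0
    brain_window: tuple = (0.0, 100.0)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        from .errors import ParameterError

        if self.side not in ("left", "right", "auto"):
            raise ParameterError(f"side must be left/right/auto, got {self.side!r}")
        if not self.hu_window[0] < self.hu_window[1]:
            raise ParameterError(f"inverted HU window {self.hu_window}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        reg = RegistrationConfig(**raw.pop("registration", {}))
        cfg = cls(**{k: v for k, v in raw.items()}, )
        cfg.registration = reg
        return cfg


def load_scan(path) -> CTVolume:
    """NIfTI file or classic DICOM series directory."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path)
    return read_nifti(path)


def process_scan(vol: CTVolume, atlas: RegionAtlas,
                 config: RunConfig | None = None
                 ) -> tuple[NWUResult, PreprocessReport, CTVolume]:
    """Run the full preprocessing + NWU chain on one loaded volume.

    Returns the NWU result, the preprocessing report, and the subject volume
    resampled onto the atlas grid.
    """
    cfg = config or RunConfig()
    cropped, bounds = select_field_of_view(vol, cfg.air_threshold, cfg.fov_margin)
    sigma = (cfg.smoothing_sigma_mm if cfg.smoothing_sigma_mm is not None
             else default_smoothing_sigma_mm(cropped))
    smoothed = smooth(cropped, sigma)
    brain = skull_strip(smoothed, cfg.bone_threshold, cfg.brain_window)
    transform, report = register_to_atlas(
        smoothed, brain, atlas.template, atlas.brain_mask, cfg.registration)
    report.crop_bounds = bounds
    aligned = resample(smoothed, transform, atlas.template)
    result = compute_nwu(aligned, atlas, side=cfg.side, window=cfg.hu_window)
    return result, report, aligned


def summary_row(subject_id: str, result: NWUResult) -> dict:
    """Flat per-subject record for the batch summary CSV."""
    row = {"subject_id": subject_id,
           "ipsilateral_side": result.ipsilateral_side,
           "average_nwu": result.average_nwu,
           "weighted_average_nwu": result.weighted_average_nwu}
    for region, value in result.per_region_nwu.items():
        row[f"nwu_{region}"] = value if np.isfinite(value) else ""
    return row
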