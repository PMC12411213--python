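"""Net water uptake from bilateral region densities.

For a region r with mean density D_ipsi over the stroke-side mask and D_contra
over its mirror mask, net water uptake is

    NWU_r (%) = (1 - D_ipsi / D_contra) * 100

Density means are taken over "valid" voxels only: those inside the 20-50 HU
window (inclusive), which automatically excludes encephalomalacia (< 20 HU),
and calcification or acute hemorrhage (> 50 HU).  A region whose valid-voxel
set is empty on either side carries no density information and is excluded
from both summary averages rather than imputed.

Two per-subject summaries are produced: the plain mean of the defined
regional NWU values (reflects both infarct extent and hypoattenuation depth)
and a volume-weighted mean with weights equal to each region's anatomical
mask volume in mm3 on the ipsilateral side.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atlas_regions import REGION_NAMES, RegionAtlas
from .errors import ComputationError, MaskError, ParameterError
from .volume_io import CTVolume, _as_bool_mask

DEFAULT_HU_WINDOW = (20.0, 50.0)


def filter_hu_window(vol: CTVolume, mask, window=DEFAULT_HU_WINDOW) -> np.ndarray:
    """Valid-voxel mask: ``mask`` restricted to window[0] <= HU <= window[1].

    Both endpoints are inclusive ("outside the range" is excluded).
    """
    lo, hi = float(window[0]), float(window[1])
    if lo >= hi:
        raise ParameterError(f"inverted HU window {window}")
    m = _as_bool_mask(mask)
    if m.shape != vol.shape:
        raise MaskError(f"mask shape {m.shape} does not match volume {vol.shape}")
    return m & (vol.data >= lo) & (vol.data <= hi)


@dataclass
class RegionDensity:
    """Mean HU over the valid voxels of one region mask on one side."""

    region: str
    side: str
    mean_hu: float  # NaN when undefined (no valid voxels)
    valid_voxels: int
    total_voxels: int

    @property
    def defined(self) -> bool:
        return self.valid_voxels > 0 and np.isfinite(self.mean_hu)


def region_density(vol: CTVolume, atlas: RegionAtlas, region: str, side: str,
                   window=DEFAULT_HU_WINDOW) -> RegionDensity:
    """Average the in-window voxel densities of one region mask.

    An all-filtered region is flagged undefined (``mean_hu`` NaN), never 0.
    """
    mask = atlas.mask(region, side)
    valid = filter_hu_window(vol, mask, window)
    n = int(valid.sum())
    mean = float(vol.data[valid].mean()) if n else float("nan")
    return RegionDensity(region=region, side=side, mean_hu=mean,
                         valid_voxels=n, total_voxels=int(mask.sum()))


@dataclass
class NWUResult:
    """Per-region and summary net water uptake for one subject."""

    per_region_nwu: dict            # region -> percent (NaN if undefined)
    per_region_density: dict        # region -> {"ipsilateral": RegionDensity, "contralateral": ...}
    ipsilateral_side: str
    average_nwu: float
    weighted_average_nwu: float
    regions_excluded: list = field(default_factory=list)
    window: tuple = DEFAULT_HU_WINDOW

    def to_dict(self) -> dict:
        d = {
            "ipsilateral_side": self.ipsilateral_side,
            "average_nwu": self.average_nwu,
            "weighted_average_nwu": self.weighted_average_nwu,
            "regions_excluded": list(self.regions_excluded),
            "hu_window": list(self.window),
            "regions": {},
        }
        for r in self.per_region_nwu:
            dens = self.per_region_density[r]
            d["regions"][r] = {
                "nwu_percent": self.per_region_nwu[r],
                "density_ipsilateral_hu": dens["ipsilateral"].mean_hu,
                "density_contralateral_hu": dens["contralateral"].mean_hu,
                "valid_voxels_ipsilateral": dens["ipsilateral"].valid_voxels,
                "valid_voxels_contralateral": dens["contralateral"].valid_voxels,
            }
        return d

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))

    def save_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["region", "nwu_percent", "density_ipsi_hu",
                        "density_contra_hu", "valid_ipsi", "valid_contra"])
            for r in self.per_region_nwu:
                dens = self.per_region_density[r]
                w.writerow([r, self.per_region_nwu[r],
                            dens["ipsilateral"].mean_hu,
                            dens["contralateral"].mean_hu,
                            dens["ipsilateral"].valid_voxels,
                            dens["contralateral"].valid_voxels])
            w.writerow(["average", self.average_nwu, "", "", "", ""])
            w.writerow(["weighted_average", self.weighted_average_nwu, "", "", "", ""])


def _nwu_percent(d_ipsi: float, d_contra: float) -> float:
    if not (np.isfinite(d_ipsi) and np.isfinite(d_contra)) or d_contra == 0:
        return float("nan")
    return (1.0 - d_ipsi / d_contra) * 100.0


def aggregate_nwu(per_region_nwu, volumes_mm3) -> tuple[float, float]:
    """Plain and volume-weighted averages over the defined regional values.

    ``per_region_nwu`` and ``volumes_mm3`` are aligned sequences; undefined
    regions are NaN and are dropped from both averages.
    """
    vals = np.asarray(list(per_region_nwu), dtype=float)
    vols = np.asarray(list(volumes_mm3), dtype=float)
    if vals.shape != vols.shape:
        raise ParameterError("per-region values and volumes must align")
    ok = np.isfinite(vals)
    if not ok.any():
        raise ComputationError("no region has a defined NWU value")
    if np.any(vols[ok] <= 0):
        raise ParameterError("region volumes must be positive")
    average = float(vals[ok].mean())
    weighted = float(np.average(vals[ok], weights=vols[ok]))
    return average, weighted


def compute_nwu(vol_in_atlas_space: CTVolume, atlas: RegionAtlas,
                side: str = "auto", window=DEFAULT_HU_WINDOW) -> NWUResult:
    """Compute the 10 regional NWU values and their averages.

    ``vol_in_atlas_space`` must already be registered and resampled onto the
    atlas grid.  ``side`` names the ipsilateral (stroke) hemisphere; with
    ``'auto'`` the hemisphere whose candidate average NWU is larger is chosen
    — a single laterality decision applied to all 10 regions, since
    per-region side picking would bias NWU upward under noise.  Values are
    not clamped; a denser ipsilateral region yields a negative NWU.
    """
    if side not in ("left", "right", "auto"):
        raise ParameterError(f"side must be left/right/auto, got {side!r}")
    if vol_in_atlas_space.shape != atlas.template.shape:
        raise MaskError("volume is not on the atlas grid; resample first")

    dens = {name: {s: region_density(vol_in_atlas_space, atlas, name, s, window)
                   for s in ("left", "right")}
            for name in REGION_NAMES}

    def candidate_values(ipsi: str):
        contra = "right" if ipsi == "left" else "left"
        return [_nwu_percent(dens[n][ipsi].mean_hu, dens[n][contra].mean_hu)
                for n in REGION_NAMES]

    if side == "auto":
        cand = {}
        for s in ("left", "right"):
            vals = np.asarray(candidate_values(s))
            cand[s] = np.nanmean(vals) if np.isfinite(vals).any() else -np.inf
        side = "left" if cand["left"] >= cand["right"] else "right"

    contra = "right" if side == "left" else "left"
    per_region = dict(zip(REGION_NAMES, candidate_values(side)))
    per_density = {n: {"ipsilateral": dens[n][side], "contralateral": dens[n][contra]}
                   for n in REGION_NAMES}
    excluded = [n for n in REGION_NAMES if not np.isfinite(per_region[n])]
    if len(excluded) == len(REGION_NAMES):
        raise ComputationError("NWU undefined in all 10 regions")

    vox_mm3 = atlas.template.voxel_volume_mm3
    volumes = [dens[n][side].total_voxels * vox_mm3 for n in REGION_NAMES]
    average, weighted = aggregate_nwu(per_region.values(), volumes)
    return NWUResult(per_region_nwu=per_region, per_region_density=per_density,
                     ipsilateral_side=side, average_nwu=average,
                     weighted_average_nwu=weighted, regions_excluded=excluded,
                     window=tuple(window))
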