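"""The 10 paired anterior-circulation ASPECTS regions in atlas space.

An atlas bundles a CT-like template, a label volume with 20 codes (the 10
regions x left/right), and a brain mask, all on a grid that is mirror
symmetric about the world plane x = 0 so that reflecting across the midline
is an exact voxel permutation.  The packaged synthetic atlas is anatomically
schematic — ellipsoidal brain in a bone shell, geometrically defined regions
— because exact ground truth and exact left/right symmetry matter more than
realism for validating bilateral density comparison.  Real atlas masks (e.g.
drawn in MNI-152 space) drop into the same directory layout.

Region masks are separated by buffer gaps of at least ~6 mm and keep at
least ~6 mm clearance from the midline plane, so partial-volume mixing at
parcel boundaries (smoothing, interpolation) cannot couple one region's
density to another's or across hemispheres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConstructionError, MaskError, SchemaError
from .volume_io import (
    CTVolume,
    LabelVolume,
    read_label_nifti,
    read_nifti,
    write_nifti,
)

#: Region names in the conventional ASPECTS order.
REGION_NAMES = (
    "caudate",
    "lentiform_nucleus",
    "internal_capsule",
    "insula",
    "M1",
    "M2",
    "M3",
    "M4",
    "M5",
    "M6",
)

#: Default tissue Hounsfield units used by the synthetic template.
DEFAULT_TISSUE_HU = {
    "white": 33.0,
    "gray": 38.0,
    "csf": 8.0,
    "bone": 1000.0,
    "air": -1000.0,
}

SIDES = ("right", "left")


def region_code(name: str, side: str) -> int:
    """Stable code scheme: right = 1..10, left = 11..20 in REGION_NAMES order."""
    if name not in REGION_NAMES:
        raise SchemaError(f"unknown region {name!r}")
    if side not in SIDES:
        raise SchemaError(f"unknown side {side!r}")
    return REGION_NAMES.index(name) + 1 + (10 if side == "left" else 0)


def build_code_map() -> dict:
    return {region_code(n, s): {"name": n, "hemisphere": s}
            for s in SIDES for n in REGION_NAMES}


@dataclass
class RegionAtlas:
    """Atlas-space template, region labels, and brain mask."""

    template: CTVolume
    region_labels: LabelVolume
    brain_mask: LabelVolume
    midline_axis: int = 0  # array axis crossing the x = 0 world plane

    def __post_init__(self) -> None:
        if (self.template.shape != self.region_labels.shape
                or self.template.shape != self.brain_mask.shape):
            raise SchemaError("template, labels and brain mask must share one grid")

    def code_for(self, name: str, side: str) -> int:
        return region_code(name, side)

    def mask(self, name: str, side: str) -> np.ndarray:
        return self.region_labels.labels == self.code_for(name, side)

    @property
    def region_names(self) -> tuple:
        return REGION_NAMES


@dataclass
class RegionPair:
    """One region's left/right codes and volumes."""

    name: str
    left_code: int
    right_code: int
    voxels_left: int
    voxels_right: int
    mm3_left: float
    mm3_right: float


def _symmetric_affine(shape, spacing) -> np.ndarray:
    """Diagonal affine centering the grid on the world origin.

    With an even first dimension no voxel sits on x = 0 and index flip
    i -> nx-1-i maps world x -> -x exactly.
    """
    shape = np.asarray(shape)
    spacing = np.asarray(spacing, dtype=float)
    affine = np.diag([*spacing, 1.0])
    affine[:3, 3] = -(shape - 1) / 2.0 * spacing
    return affine


def _ellipsoid(X, Y, Z, center, semi) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = semi
    return (((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2
            + ((Z - cz) / az) ** 2) <= 1.0


# Deep structures: (name, center (x>0 side), semi-axes), in fractions of the
# brain semi-axes so the geometry scales with the requested grid.  Surface
# gaps between neighbors are >= ~6 mm at the default 192 mm field.
_DEEP_SPEC = (
    ("caudate", (0.29, 0.41, 0.16), (0.080, 0.13, 0.16)),
    ("internal_capsule", (0.29, 0.08, 0.16), (0.080, 0.13, 0.16)),
    ("lentiform_nucleus", (0.29, -0.26, 0.16), (0.080, 0.13, 0.16)),
    ("insula", (0.55, 0.08, 0.00), (0.080, 0.18, 0.20)),
)
_VENTRICLE = ((0.145, 0.08, -0.12), (0.056, 0.18, 0.12))


def build_synthetic_atlas(shape=(96, 96, 64), spacing=(2.0, 2.0, 2.0),
                          seed: int = 0, tissue_hu: dict | None = None
                          ) -> RegionAtlas:
    """Construct the deterministic synthetic head atlas.

    Ellipsoidal brain (white core + gray cortical ribbon + CSF ventricles)
    inside a bone shell, with the four deep regions as separated ellipsoids
    and M1-M6 as cortical-ribbon sectors (anterior/middle/posterior x
    lower/upper), mirror symmetric about x = 0.  ``seed`` is accepted for
    interface symmetry with the other generators; construction is purely
    geometric, so the output is identical for any seed.
    """
    del seed
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in spacing)
    if min(shape) < 32:
        raise ConstructionError(f"shape {shape} too small; need >= 32 per axis")
    if shape[0] % 2:
        raise ConstructionError("first (left-right) dimension must be even for "
                                "exact midline symmetry")
    hu = dict(DEFAULT_TISSUE_HU)
    hu.update(tissue_hu or {})
    affine = _symmetric_affine(shape, spacing)
    ii = np.indices(shape, dtype=float)
    X = ii[0] * spacing[0] + affine[0, 3]
    Y = ii[1] * spacing[1] + affine[1, 3]
    Z = ii[2] * spacing[2] + affine[2, 3]

    half = np.asarray(shape) * np.asarray(spacing) / 2.0
    brain_semi = np.array([0.645, 0.81, 0.78]) * half
    r2 = (X / brain_semi[0]) ** 2 + (Y / brain_semi[1]) ** 2 + (Z / brain_semi[2]) ** 2
    brain = r2 <= 1.0
    skull = (r2 > 1.0) & (r2 <= 1.14 ** 2)
    ribbon = brain & (r2 > 0.66)

    template = np.full(shape, hu["air"], dtype=np.float32)
    template[brain] = hu["white"]
    template[ribbon] = hu["gray"]
    template[skull] = hu["bone"]

    bs = brain_semi
    vent = _ellipsoid(X, Y, Z, np.array(_VENTRICLE[0]) * bs, np.array(_VENTRICLE[1]) * bs)
    vent = (vent | vent[::-1]) & brain
    template[vent] = hu["csf"]

    labels = np.zeros(shape, dtype=np.int16)
    occupied = vent.copy()

    gray_regions = {"caudate", "lentiform_nucleus", "insula"}
    for name, center_f, semi_f in _DEEP_SPEC:
        right = _ellipsoid(X, Y, Z, np.array(center_f) * bs, np.array(semi_f) * bs)
        right &= brain & ~occupied & (X > 0)
        left = right[::-1]
        labels[right] = region_code(name, "right")
        labels[left] = region_code(name, "left")
        occupied |= right | left
        if name in gray_regions:
            template[right | left] = hu["gray"]

    # Cortical sectors on the ribbon.  Band thresholds in mm leave >= 6 mm
    # unassigned gaps between sectors and a >= 6 mm clearance from midline.
    # Sector labels stop at r2 <= 0.85 (~4.5 mm inside the brain surface):
    # smoothing plus two resampling passes blurs with sigma ~1.6 mm, and
    # skull HU blended into labeled voxels would be censored by the density
    # window asymmetrically between a lesioned and an intact hemisphere.
    gap = 3.0
    y_cut = 0.26 * bs[1]
    z_cut = 0.08 * bs[2]
    lateral = ribbon & (r2 <= 0.85) & ~occupied & (np.abs(X) >= 6.0)
    zones = {
        "M1": (Y >= y_cut + gap) & (Z <= z_cut - gap),
        "M2": (np.abs(Y) <= y_cut - gap) & (Z <= z_cut - gap),
        "M3": (Y <= -y_cut - gap) & (Z <= z_cut - gap),
        "M4": (Y >= y_cut + gap) & (Z >= z_cut + gap),
        "M5": (np.abs(Y) <= y_cut - gap) & (Z >= z_cut + gap),
        "M6": (Y <= -y_cut - gap) & (Z >= z_cut + gap),
    }
    for name, zone in zones.items():
        right = lateral & zone & (X > 0)
        left = right[::-1]
        labels[right] = region_code(name, "right")
        labels[left] = region_code(name, "left")

    code_map = build_code_map()
    present = set(np.unique(labels)) - {0}
    missing = set(code_map) - present
    if missing:
        names = sorted(f"{code_map[c]['name']}/{code_map[c]['hemisphere']}"
                       for c in missing)
        raise ConstructionError(
            f"grid {shape} @ {spacing} mm cannot fit regions: {names}")

    atlas = RegionAtlas(
        template=CTVolume(data=template, affine=affine),
        region_labels=LabelVolume(labels=labels, affine=affine, code_map=code_map),
        brain_mask=LabelVolume(labels=brain.astype(np.int16), affine=affine,
                               code_map={1: {"name": "brain", "hemisphere": None}}),
    )
    validate_atlas(atlas)
    return atlas


def validate_atlas(atlas: RegionAtlas, min_mirror_dice: float = 0.95) -> None:
    """Enforce the structural invariants; raise SchemaError on violation."""
    labels = atlas.region_labels.labels
    code_map = atlas.region_labels.code_map
    expected = build_code_map()
    if {int(k): v for k, v in code_map.items()} != expected:
        raise SchemaError("code map does not match the 10-region x 2-side scheme")
    x_world = _axis_world_coords(atlas)
    flipped = np.flip(labels, axis=atlas.midline_axis)
    for name in REGION_NAMES:
        for side, sign in (("right", 1), ("left", -1)):
            m = labels == region_code(name, side)
            if not m.any():
                raise SchemaError(f"region {name}/{side} is empty")
            if np.any(sign * x_world[m.any(axis=(1, 2))] <= 0):
                raise SchemaError(f"region {name}/{side} crosses the midline")
        right = labels == region_code(name, "right")
        mirrored_left = flipped == region_code(name, "left")
        inter = np.logical_and(right, mirrored_left).sum()
        dice = 2 * inter / (right.sum() + mirrored_left.sum())
        if dice < min_mirror_dice:
            raise SchemaError(
                f"mirror Dice for {name} is {dice:.3f} < {min_mirror_dice}")


def _axis_world_coords(atlas: RegionAtlas) -> np.ndarray:
    """World coordinate along the midline axis for each index on that axis."""
    ax = atlas.midline_axis
    n = atlas.template.shape[ax]
    ijk = np.zeros((n, 3))
    ijk[:, ax] = np.arange(n)
    return atlas.template.world_coords(ijk)[:, ax]


def region_volumes(atlas: RegionAtlas) -> list[RegionPair]:
    """Voxel counts and mm3 volumes for each left/right pair."""
    labels = atlas.region_labels.labels
    vox_mm3 = atlas.template.voxel_volume_mm3
    counts = np.bincount(labels.ravel(), minlength=21)
    pairs = []
    for name in REGION_NAMES:
        rc, lc = region_code(name, "right"), region_code(name, "left")
        nr, nl = int(counts[rc]), int(counts[lc])
        if nr == 0 or nl == 0:
            raise SchemaError(f"region {name} has an empty side")
        pairs.append(RegionPair(name=name, left_code=lc, right_code=rc,
                                voxels_left=nl, voxels_right=nr,
                                mm3_left=nl * vox_mm3, mm3_right=nr * vox_mm3))
    return pairs


def reflect_across_midline(vol, atlas: RegionAtlas):
    """Mirror a volume or mask across the atlas midline plane (x = 0).

    On the symmetric atlas grid this is an exact voxel permutation (an array
    flip), hence an involution.
    """
    ax = atlas.midline_axis
    x = _axis_world_coords(atlas)
    if not np.allclose(x + x[::-1], 0.0, atol=1e-6):
        raise MaskError("grid is not symmetric about the midline plane")
    if isinstance(vol, LabelVolume):
        return LabelVolume(labels=np.flip(vol.labels, axis=ax).copy(),
                           affine=vol.affine.copy(), code_map=dict(vol.code_map))
    return CTVolume(data=np.flip(vol.data, axis=ax).copy(),
                    affine=vol.affine.copy())


# ---------------------------------------------------------------------------
# Directory round trip: template.nii.gz, regions.nii.gz, brain_mask.nii.gz,
# codes.json
# ---------------------------------------------------------------------------

def save_atlas(atlas: RegionAtlas, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_nifti(atlas.template, directory / "template.nii.gz")
    write_nifti(atlas.region_labels, directory / "regions.nii.gz")
    write_nifti(atlas.brain_mask, directory / "brain_mask.nii.gz")
    codes = {str(c): v for c, v in atlas.region_labels.code_map.items()}
    (directory / "codes.json").write_text(json.dumps(
        {"codes": codes, "midline_axis": atlas.midline_axis}, indent=2))


def load_atlas(directory) -> RegionAtlas:
    directory = Path(directory)
    codes_path = directory / "codes.json"
    if not codes_path.exists():
        raise SchemaError(f"missing codes.json in {directory}")
    meta = json.loads(codes_path.read_text())
    code_map = {int(c): v for c, v in meta["codes"].items()}
    for code, expected in build_code_map().items():
        if code not in code_map:
            raise SchemaError(f"codes.json lacks code {code} ({expected['name']})")
    template = read_nifti(directory / "template.nii.gz")
    regions = read_label_nifti(directory / "regions.nii.gz", code_map=code_map)
    brain = read_label_nifti(directory / "brain_mask.nii.gz",
                             code_map={1: {"name": "brain", "hemisphere": None}})
    atlas = RegionAtlas(template=template, region_labels=regions,
                        brain_mask=brain,
                        midline_axis=int(meta.get("midline_axis", 0)))
    validate_atlas(atlas)
    return atlas
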