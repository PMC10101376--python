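"""Deterministic synthetic phantoms with ground truth.

Two families of phantoms supply every test and demo input, so no external
data is required:

* an abdominal-CT-like 3D volume — a spine cylinder at bone intensity, two
  kidney ellipsoids at soft-tissue intensity placed symmetrically about the
  spine at the same craniocaudal level, and an optional stray distractor
  blob at kidney-like intensity placed outside the anatomically plausible
  lateral band;
* a chest-radiograph-like 2D image — a dark trachea band that bifurcates at
  the carina into two main-stem branches, and a bright endotracheal-tube
  line whose tip sits a configurable distance above the carina.

Rasters are indexed (z, y, x) in 3D and (y, x) in 2D; physical position is
index * spacing in mm; "above" means smaller z (3D) or smaller y (2D);
"patient right" is smaller x (radiological orientation).  A given spec and
seed produce bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = ["AbdominalSpec", "TubeSpec", "Phantom",
           "make_abdominal_phantom", "make_tube_phantom", "write_phantom"]


@dataclass
class Phantom:
    """A synthetic image with its ground truth."""
    image: np.ndarray                    # float32 raster, (z,y,x) or (y,x)
    spacing: tuple[float, ...]           # mm per axis, same order as image
    masks: dict[str, np.ndarray]         # structure -> boolean mask
    points: dict[str, tuple[int, ...]]   # landmark -> voxel index
    spec: object = None

    def point_mm(self, name: str) -> tuple[float, ...]:
        return tuple(i * s for i, s in zip(self.points[name], self.spacing))


# ---------------------------------------------------------------------------
# abdominal CT-like volume

@dataclass(frozen=True)
class AbdominalSpec:
    """Geometry and intensities of the abdominal phantom.

    Lateral offsets are mm from the spine axis; positive = patient left
    (larger x).  Defaults place the kidneys 70 mm from the spine (inside the
    expected 50-100 mm band) at the same z level, and the stray blob at
    125 mm — outside the plausible band — to exercise candidate rejection.
    Intensities are HU-like: kidneys in the contrast-enhanced soft-tissue
    range, spine in the dense-bone range.
    """
    shape: tuple[int, int, int] = (32, 96, 112)        # (z, y, x) voxels
    spacing: tuple[float, float, float] = (3.0, 2.5, 2.5)  # mm
    spine_radius_mm: float = 12.0
    spine_intensity: float = 1200.0
    kidney_semiaxes_mm: tuple[float, float, float] = (20.0, 14.0, 11.0)
    kidney_offset_mm: float = 70.0       # lateral distance of each kidney
    kidney_dz_mm: float = 0.0            # z offset of left kidney vs right
    kidney_intensity: float = 400.0
    #: optional faint concentric shells around each kidney, as (semiaxis
    #: scale, intensity) pairs ordered inward-out; used to plant a unique
    #: optimal segmentation threshold for parameter-recovery studies
    kidney_shells: tuple[tuple[float, float], ...] = ()
    stray: bool = True
    stray_offset_mm: float = 125.0       # lateral, patient-left side
    stray_radius_mm: float = 10.0
    stray_intensity: float = 400.0
    background: float = 0.0
    noise_sigma: float = 20.0
    seed: int = 0


def _mm_grid(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(grid, center_mm, semiaxes_mm):
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grid, center_mm, semiaxes_mm))
    return q <= 1.0


def _check_inside(name, center_mm, extent_mm, shape, spacing):
    for c, e, n, s in zip(center_mm, extent_mm, shape, spacing):
        if c - e < -s / 2 or c + e > (n - 1) * s + s / 2:
            raise ValueError(f"{name} extends outside the image "
                             f"(center {center_mm} mm, extent {extent_mm} mm)")


def make_abdominal_phantom(spec: AbdominalSpec | None = None, **overrides) -> Phantom:
    """Build the abdominal volume and truth masks {spine, dense_bone,
    kidney_left, kidney_right[, stray]}."""
    if spec is None:
        spec = AbdominalSpec(**overrides)
    elif overrides:
        raise TypeError("pass either a spec or keyword overrides, not both")
    shape, spacing = spec.shape, spec.spacing
    grid = _mm_grid(shape, spacing)
    z_mm, y_mm, x_mm = grid
    extent = tuple((n - 1) * s for n, s in zip(shape, spacing))
    cz, cy, cx = (e / 2 for e in extent)

    spine = ((x_mm - cx) ** 2 + (y_mm - cy) ** 2) <= spec.spine_radius_mm ** 2

    az, ay, ax = spec.kidney_semiaxes_mm
    right_center = (cz, cy, cx - spec.kidney_offset_mm)   # patient right: smaller x
    left_center = (cz + spec.kidney_dz_mm, cy, cx + spec.kidney_offset_mm)
    _check_inside("kidney_right", right_center, (az, ay, ax), shape, spacing)
    _check_inside("kidney_left", left_center, (az, ay, ax), shape, spacing)
    kidney_right = _ellipsoid(grid, right_center, (az, ay, ax))
    kidney_left = _ellipsoid(grid, left_center, (az, ay, ax))

    masks = {
        "spine": spine,
        "dense_bone": spine.copy(),
        "kidney_right": kidney_right,
        "kidney_left": kidney_left,
    }
    image = np.full(shape, spec.background, dtype=np.float64)
    image[spine] = spec.spine_intensity
    for scale, intensity in sorted(spec.kidney_shells, key=lambda s: -s[0]):
        semis = (az * scale, ay * scale, ax * scale)
        _check_inside("kidney shell", right_center, semis, shape, spacing)
        _check_inside("kidney shell", left_center, semis, shape, spacing)
        image[_ellipsoid(grid, right_center, semis)] = intensity
        image[_ellipsoid(grid, left_center, semis)] = intensity
    image[kidney_right] = spec.kidney_intensity
    image[kidney_left] = spec.kidney_intensity
    if spec.stray:
        r = spec.stray_radius_mm
        stray_center = (cz, cy, cx + spec.stray_offset_mm)
        _check_inside("stray", stray_center, (r, r, r), shape, spacing)
        stray = _ellipsoid(grid, stray_center, (r, r, r))
        masks["stray"] = stray
        image[stray] = spec.stray_intensity

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sigma, size=shape)
    return Phantom(image=image.astype(np.float32), spacing=spacing,
                   masks=masks, points={}, spec=spec)


# ---------------------------------------------------------------------------
# chest-radiograph-like 2D image

@dataclass(frozen=True)
class TubeSpec:
    """Geometry of the tube phantom.

    ``tip_offset_mm`` is the distance of the tube tip above the carina
    (negative places it below).  The default 50 mm sits in the middle of the
    30-70 mm safe zone.
    """
    shape: tuple[int, int] = (256, 192)          # (y, x) pixels
    spacing: tuple[float, float] = (0.5, 0.5)    # mm
    background: float = 128.0
    trachea_intensity: float = 30.0
    trachea_halfwidth_mm: float = 6.0
    trachea_top_mm: float = 0.0
    carina_y_mm: float = 100.0
    branch_halfwidth_mm: float = 4.0
    branch_slope: float = 1.5                    # lateral mm per mm below carina
    branch_length_mm: float = 25.0
    tube_intensity: float = 250.0
    tube_halfwidth_mm: float = 0.5
    tube_lateral_offset_mm: float = -2.0         # tube line relative to trachea axis
    tip_offset_mm: float = 50.0
    noise_sigma: float = 5.0
    seed: int = 0


def make_tube_phantom(spec: TubeSpec | None = None, **overrides) -> Phantom:
    """Build the 2D image and truth {trachea, tube} masks plus {carina, tip}
    landmark points."""
    if spec is None:
        spec = TubeSpec(**overrides)
    elif overrides:
        raise TypeError("pass either a spec or keyword overrides, not both")
    shape, spacing = spec.shape, spec.spacing
    y_mm, x_mm = _mm_grid(shape, spacing)
    cx = (shape[1] - 1) * spacing[1] / 2

    # main band from trachea_top down to the carina
    band = ((np.abs(x_mm - cx) <= spec.trachea_halfwidth_mm)
            & (y_mm >= spec.trachea_top_mm) & (y_mm <= spec.carina_y_mm))
    # two diverging branches below the carina
    dy = y_mm - spec.carina_y_mm
    below = (dy > 0) & (dy <= spec.branch_length_mm)
    lateral = spec.branch_slope * dy
    branches = below & (
        (np.abs(x_mm - (cx - lateral)) <= spec.branch_halfwidth_mm)
        | (np.abs(x_mm - (cx + lateral)) <= spec.branch_halfwidth_mm))
    tip_y_mm = spec.carina_y_mm - spec.tip_offset_mm
    if not (0 <= tip_y_mm <= (shape[0] - 1) * spacing[0]):
        raise ValueError(f"tube tip at y={tip_y_mm} mm is outside the image")
    tube_x = cx + spec.tube_lateral_offset_mm
    tube = (np.abs(x_mm - tube_x) <= spec.tube_halfwidth_mm) & (y_mm <= tip_y_mm)
    # the tube occludes the air column, so the truth masks stay disjoint
    trachea = (band | branches) & ~tube

    image = np.full(shape, spec.background, dtype=np.float64)
    image[trachea] = spec.trachea_intensity
    image[tube] = spec.tube_intensity
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sigma, size=shape)

    carina_idx = (int(round(spec.carina_y_mm / spacing[0])),
                  int(round(cx / spacing[1])))
    tip_idx = (int(round(tip_y_mm / spacing[0])),
               int(round(tube_x / spacing[1])))
    return Phantom(image=image.astype(np.float32), spacing=spacing,
                   masks={"trachea": trachea, "tube": tube},
                   points={"carina": carina_idx, "tip": tip_idx}, spec=spec)


# ---------------------------------------------------------------------------
# writer

def write_phantom(phantom: Phantom, directory: str | Path, name: str = "phantom") -> Path:
    """Write image, truth masks and landmark coordinates to ``directory``.

    3D rasters are written as NIfTI with spacing in the affine; 2D as PNG
    with spacing recorded in the truth JSON.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    is3d = phantom.image.ndim == 3
    truth: dict = {"spacing_mm": list(phantom.spacing), "masks": {}, "points": {}}
    if is3d:
        affine = np.diag(list(phantom.spacing) + [1.0])
        img_path = directory / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(phantom.image, affine), img_path)
        for key, mask in phantom.masks.items():
            p = directory / f"{name}_{key}.nii.gz"
            nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), p)
            truth["masks"][key] = p.name
    else:
        img_path = directory / f"{name}.png"
        iio.imwrite(img_path, np.clip(phantom.image, 0, 255).astype(np.uint8))
        for key, mask in phantom.masks.items():
            p = directory / f"{name}_{key}.png"
            iio.imwrite(p, (mask.astype(np.uint8) * 255))
            truth["masks"][key] = p.name
    truth["image"] = img_path.name
    truth["points"] = {k: list(v) for k, v in phantom.points.items()}
    (directory / f"{name}_truth.json").write_text(json.dumps(truth, indent=2))
    return img_path
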