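"""Candidate-generating segmentation operations.

These are the low-level operations behind segmentation agents: intensity
thresholding, connected-component candidate extraction, morphological
refinement, derived box regions, multi-channel preprocessing, and the
external-predictor hook through which a trained model (e.g. a DNN) can be
plugged in.  All physical parameters are in mm and converted to voxels via
the image spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure

from .blackboard import CandidateRegion

__all__ = ["IntensityWindow", "PreprocessSpec", "threshold_segment",
           "extract_candidates", "refine_region", "derive_box", "preprocess",
           "external_predict"]


@dataclass(frozen=True)
class IntensityWindow:
    """Inclusive intensity range in image units (e.g. Hounsfield units)."""
    low: float
    high: float

    def __post_init__(self):
        if self.high < self.low:
            raise ValueError(f"window low {self.low} exceeds high {self.high}")


def _full_connectivity(ndim: int) -> np.ndarray:
    # 26-connectivity in 3D, 8-connectivity in 2D
    return np.ones((3,) * ndim, dtype=int)


def threshold_segment(image: np.ndarray, window: IntensityWindow,
                      search_area: np.ndarray | None = None) -> np.ndarray:
    """Label voxels with ``low <= value <= high`` (optionally restricted to a
    search area) into connected components.  An empty result is a valid
    all-zero labeling, not an error."""
    image = np.asarray(image)
    mask = (image >= window.low) & (image <= window.high)
    if search_area is not None:
        mask &= search_area.astype(bool)
    labels, _ = ndimage.label(mask, structure=_full_connectivity(image.ndim))
    return labels


def extract_candidates(labels: np.ndarray, min_size: int = 1) -> list[CandidateRegion]:
    """One candidate per connected component of at least ``min_size`` voxels,
    in label order."""
    labels = np.asarray(labels)
    n = int(labels.max())
    if n == 0:
        return []
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    out = []
    for lab in range(1, n + 1):
        if counts[lab] >= max(1, min_size):
            out.append(CandidateRegion(mask=labels == lab))
    return out


def _ball_structure(radius_mm: float, spacing) -> np.ndarray:
    """Ellipsoidal structuring element with a physical radius (anisotropic
    spacing aware); always at least one voxel across in each axis."""
    radii = [max(1, int(round(radius_mm / s))) for s in spacing]
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in radii], indexing="ij")
    q = sum((g / r) ** 2 for g, r in zip(grids, radii))
    return q <= 1.0


def refine_region(mask: np.ndarray, ops, spacing) -> np.ndarray:
    """Apply morphological refinements in order.

    ``ops`` is a sequence of ``("fill_holes",)``, ``("open", radius_mm)`` or
    ``("close", radius_mm)``.  Opening shrinks (output subset of input),
    closing and hole filling grow (output superset).
    """
    mask = np.asarray(mask).astype(bool)
    extent = min(n * s for n, s in zip(mask.shape, spacing))
    out = mask
    for op in ops:
        name = op[0]
        if name == "fill_holes":
            out = ndimage.binary_fill_holes(out)
        elif name in ("open", "close"):
            radius = float(op[1])
            if radius < 0:
                raise ValueError(f"negative structuring radius {radius}")
            if radius > extent:
                raise ValueError(f"structuring radius {radius} mm exceeds "
                                 f"image extent {extent} mm")
            structure = _ball_structure(radius, spacing)
            if name == "open":
                out = ndimage.binary_opening(out, structure=structure)
            else:
                # pad so closing is not clipped at the image border
                pad = [r for r in (np.array(structure.shape) // 2)]
                padded = np.pad(out, [(p, p) for p in pad])
                closed = ndimage.binary_closing(padded, structure=structure)
                out = closed[tuple(slice(p, n + p) for p, n in zip(pad, out.shape))]
        else:
            raise ValueError(f"unknown refinement op {name!r}")
    return out


def derive_box(shape, spacing, center_mm, vertical_center_mm: float,
               in_plane_mm: tuple[float, float],
               offset_range_mm: tuple[float, float],
               direction: str = "above") -> np.ndarray:
    """Axis-aligned box mask relative to a reference.

    The box is centred laterally on ``center_mm`` (the reference centroid in
    the non-vertical axes), spans ``in_plane_mm`` (width on x, height on y;
    the height is ignored in 2D), and occupies the slab from ``offset_low``
    to ``offset_high`` mm above (or below) ``vertical_center_mm`` along the
    vertical axis (axis 0; smaller coordinate = above).
    """
    d_low, d_high = offset_range_mm
    if d_high < d_low:
        raise ValueError(f"offset range out of order ({d_low}, {d_high})")
    if direction not in ("above", "below"):
        raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")
    ndim = len(shape)
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    vert = grids[0]
    if direction == "above":
        slab = (vert >= vertical_center_mm - d_high) & (vert <= vertical_center_mm - d_low)
    else:
        slab = (vert >= vertical_center_mm + d_low) & (vert <= vertical_center_mm + d_high)
    width, height = in_plane_mm
    box = slab
    # lateral axis (x) is always last; in-plane y exists only in 3D
    box = box & (np.abs(grids[-1] - center_mm[-1]) <= width / 2)
    if ndim == 3:
        box = box & (np.abs(grids[1] - center_mm[-2]) <= height / 2)
    return box


@dataclass(frozen=True)
class PreprocessSpec:
    """Up to three preprocessing channels, each an ordered step list.

    Steps: ``("bias_field",)`` (delegates to a registered hook, identity by
    default), ``("minmax",)``, ``("centile_clip", low, high)`` percentiles,
    ``("histeq",)``.  Histogram statistics are computed over the
    ``histogram_source`` region when given (a named box node resolved to a
    mask), otherwise over the whole image.
    """
    channels: tuple[tuple, ...] = ((("minmax",),),)
    histogram_source: str | None = None

    def __post_init__(self):
        if not 1 <= len(self.channels) <= 3:
            raise ValueError("preprocessing supports 1-3 channels")


def _minmax(image, region):
    lo, hi = float(image[region].min()), float(image[region].max())
    if hi <= lo:
        return np.zeros_like(image, dtype=float)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def preprocess(image: np.ndarray, spec: PreprocessSpec,
               source_mask: np.ndarray | None = None,
               bias_hook=None) -> np.ndarray:
    """Produce a (channels, ...) stack of preprocessed images in [0, 1]."""
    image = np.asarray(image, dtype=float)
    region = (source_mask.astype(bool) if source_mask is not None
              else np.ones(image.shape, dtype=bool))
    if not region.any():
        raise ValueError("histogram source region is empty")
    out = []
    for steps in spec.channels:
        chan = image
        for step in steps:
            name = step[0]
            if name == "bias_field":
                chan = bias_hook(chan) if bias_hook is not None else chan
            elif name == "minmax":
                chan = _minmax(chan, region)
            elif name == "centile_clip":
                lo, hi = np.percentile(chan[region], [step[1], step[2]])
                chan = np.clip(chan, lo, hi)
            elif name == "histeq":
                chan = exposure.equalize_hist(chan, nbins=256, mask=region)
            else:
                raise ValueError(f"unknown preprocessing step {name!r}")
        # guarantee the [0, 1] output contract whatever the final step was
        chan = _minmax(chan, region)
        out.append(chan)
    return np.stack(out, axis=0)


def external_predict(image: np.ndarray, hook, spacing=None) -> np.ndarray:
    """Run a registered predictor hook and label its output.

    The hook receives ``(image, spacing)`` and must return a binary or label
    raster of the same spatial shape; its components are treated exactly like
    threshold output.
    """
    image = np.asarray(image)
    pred = np.asarray(hook(image, spacing))
    if pred.shape != image.shape:
        raise ValueError(f"predictor output shape {pred.shape} does not match "
                         f"image shape {image.shape}")
    labels, _ = ndimage.label(pred > 0, structure=_full_connectivity(pred.ndim))
    return labels
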