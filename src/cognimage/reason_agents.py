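"""Machine reasoning over blackboard candidates.

Reasoning agents use knowledge-base expectations in two ways: before
segmentation, spatial relations to already-recognized objects are turned
into an image search area (the intersection of admissible coordinate bands);
after segmentation, each candidate's features are computed, matched against
fuzzy expectations, and aggregated into a confidence score.  The best-scoring
candidate is selected — or all candidates are rejected and the object is
reported not found, rather than outputting a wrong region.

Decision elements reduce recognized objects to an explained boolean (e.g.
"tube tip inside the safe zone"), and consistency elements cross-check two
independent estimates of the same landmark, flagging the result unreliable
when they disagree beyond a tolerance.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .blackboard import (NOT_FOUND, RECOGNIZED, Blackboard, CandidateRegion,
                         SolutionElement)

__all__ = ["derive_search_area", "compute_features", "score_candidate",
           "select_best", "evaluate_decision", "consistency_check"]


# ---------------------------------------------------------------------------
# geometry helpers

def _lat_sign(bb: Blackboard) -> float:
    # radiological: patient left = larger x; neurological flips the x axis
    return 1.0 if bb.orientation == "radiological" else -1.0


def centroid_mm(cand: CandidateRegion, spacing) -> tuple[float, ...]:
    if cand.point is not None:
        return tuple(float(i * s) for i, s in zip(cand.point, spacing))
    com = ndimage.center_of_mass(cand.mask)
    return tuple(float(c * s) for c, s in zip(com, spacing))


def _resolved_reference(bb: Blackboard, name: str):
    """Selected candidate of a reference element, or None when it is not
    recognized (missing references make relations non-informative)."""
    el = bb.elements.get(name)
    if el is None or el.status != RECOGNIZED or el.selected is None:
        return None
    return el.selected


# ---------------------------------------------------------------------------
# search-area inference

def derive_search_area(se: SolutionElement, bb: Blackboard) -> np.ndarray:
    """Intersection of admissible bands from spatial relations whose
    reference is recognized; the whole image when no relation applies.

    Each band is the support of the relation's fuzzy membership (the printed
    range widened by the soft shoulder), so the search area never clips a
    candidate that would score above zero.
    """
    shape, spacing = bb.image.shape, bb.spacing
    area = np.ones(shape, dtype=bool)
    grids = None
    sign = _lat_sign(bb)
    for exp in se.expectations:
        if exp.reference is None:
            continue
        ref = _resolved_reference(bb, exp.reference)
        if ref is None:
            continue
        if exp.kind == "part_of" and ref.mask is not None:
            area &= ref.mask
            continue
        if exp.kind not in ("left_of", "right_of", "above", "below", "same_level"):
            continue
        if grids is None:
            grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                                indexing="ij")
        rc = centroid_mm(ref, spacing)
        lo, hi = exp.fuzzy.support
        if exp.kind == "left_of":
            feat = (grids[-1] - rc[-1]) * sign
        elif exp.kind == "right_of":
            feat = (rc[-1] - grids[-1]) * sign
        elif exp.kind == "above":
            feat = rc[0] - grids[0]          # above = smaller vertical coordinate
        elif exp.kind == "below":
            feat = grids[0] - rc[0]
        else:  # same_level
            feat = np.abs(grids[0] - rc[0])
            lo = -np.inf
        area &= (feat >= lo) & (feat <= hi)
    return area


# ---------------------------------------------------------------------------
# feature computation and fuzzy scoring

def compute_features(cand: CandidateRegion, se: SolutionElement,
                     bb: Blackboard) -> dict:
    """Fill the candidate's feature map: unary size/position/intensity
    features plus one value per relational expectation (None when the
    reference is unresolved)."""
    spacing = bb.spacing
    ndim = len(spacing)
    voxel = float(np.prod(spacing))
    feats: dict = {}
    c = centroid_mm(cand, spacing)
    feats["centroid_mm"] = c
    if cand.mask is not None:
        nvox = int(cand.mask.sum())
        feats["volume_mm3" if ndim == 3 else "area_mm2"] = nvox * voxel
        if ndim == 3:
            # mean in-plane cross-sectional area over occupied slices, cm^2
            per_slice = cand.mask.sum(axis=(1, 2))
            occ = per_slice[per_slice > 0]
            pix = spacing[1] * spacing[2]
            feats["xsection_area_cm2"] = float(occ.mean() * pix / 100.0) if occ.size else 0.0
        else:
            feats["xsection_area_cm2"] = nvox * voxel / 100.0
        if bb.image is not None:
            feats["mean_intensity"] = float(bb.image[cand.mask].mean())
    else:
        feats["volume_mm3" if ndim == 3 else "area_mm2"] = voxel
        if bb.image is not None and cand.point is not None:
            feats["mean_intensity"] = float(bb.image[tuple(cand.point)])

    sign = _lat_sign(bb)
    for exp in se.expectations:
        if exp.reference is None:
            continue
        ref = _resolved_reference(bb, exp.reference)
        if ref is None:
            feats[exp.feature] = None
            continue
        if exp.kind in ("part_of", "not_part_of", "inside_of"):
            if ref.mask is None:
                feats[exp.feature] = None
            elif cand.mask is None:
                feats[exp.feature] = float(ref.mask[tuple(cand.point)])
            else:
                inter = np.logical_and(cand.mask, ref.mask).sum()
                feats[exp.feature] = float(inter / cand.mask.sum())
            continue
        rc = centroid_mm(ref, spacing)
        if exp.kind == "left_of":
            feats[exp.feature] = (c[-1] - rc[-1]) * sign
        elif exp.kind == "right_of":
            feats[exp.feature] = (rc[-1] - c[-1]) * sign
        elif exp.kind == "above":
            feats[exp.feature] = rc[0] - c[0]
        elif exp.kind == "below":
            feats[exp.feature] = c[0] - rc[0]
        elif exp.kind == "same_level":
            feats[exp.feature] = abs(c[0] - rc[0])
    cand.features.update(feats)
    return cand.features


_UNARY_FEATURE_VALUES = ("xsection_area_cm2", "volume_mm3", "area_mm2",
                         "mean_intensity")


def score_candidate(cand: CandidateRegion, expectations) -> float:
    """Aggregate confidence: product of per-expectation memberships.

    Fuzzy expectations evaluate their membership at the computed feature
    value; overlap kinds use the overlap fraction directly (NotPartOf
    contributes 1 - overlap).  Non-informative expectations (unresolved
    reference) contribute 1.  An empty expectation list scores 1.
    """
    memberships: dict = {}
    score = 1.0
    for exp in expectations:
        if exp.kind == "volume":
            key = "area_mm2" if "area_mm2" in cand.features else "volume_mm3"
            value = cand.features.get(key)
        else:
            value = cand.features.get(exp.feature)
        if value is None:
            m = 1.0
        elif exp.kind == "not_part_of":
            m = 1.0 - value
        elif exp.kind in ("part_of", "inside_of"):
            m = float(value)
        else:
            m = exp.fuzzy(value)
        memberships[f"{exp.kind}:{exp.feature}"] = float(m)
        score *= m
    cand.memberships.update(memberships)
    cand.score = float(score)
    return cand.score


def select_best(se: SolutionElement, threshold: float = 0.0) -> SolutionElement:
    """Select the highest-scoring candidate above the acceptance threshold;
    ties break toward the larger region, then the first found.  With no
    acceptable candidate the element becomes not_found and outputs nothing.
    """
    best = None
    for cand in se.candidates:
        if cand.score <= threshold:
            continue
        if best is None or cand.score > best.score or (
                cand.score == best.score and cand.size > best.size):
            best = cand
    if best is None:
        se.status = NOT_FOUND
        se.selected = None
    else:
        se.status = RECOGNIZED
        se.selected = best
    return se


# ---------------------------------------------------------------------------
# decisions and consistency

def _operand_ready(bb: Blackboard, name: str) -> tuple[bool, str | None]:
    el = bb.elements.get(name)
    if el is None:
        return False, f"{name} is missing"
    if el.status != RECOGNIZED:
        return False, f"{name} is {el.status}"
    return True, None


def evaluate_decision(se: SolutionElement, bb: Blackboard) -> tuple[bool | None, str]:
    """Evaluate a decision element; returns (decision, explanation).

    A decision is None ("indeterminate") whenever any operand is not_found
    or unreliable — the system reports that it cannot decide rather than
    guessing.
    """
    node = se.node
    if (attr := node.attr("DecisionInside")) is not None:
        tip_name, zone_name = attr.params
        for name in (tip_name, zone_name):
            ok, why = _operand_ready(bb, name)
            if not ok:
                return None, f"indeterminate: {why}"
        tip = bb.elements[tip_name].selected
        zone = bb.elements[zone_name].selected
        tip_idx = tip.point
        if tip_idx is None:
            tip_idx = tuple(int(round(c / s)) for c, s in
                            zip(centroid_mm(tip, bb.spacing), bb.spacing))
        if zone.mask is not None and zone.mask[tuple(tip_idx)]:
            return True, f"{tip_name} is inside {zone_name}"
        # explain which side of the zone the tip falls on (vertical axis)
        occupied = np.any(zone.mask, axis=tuple(range(1, zone.mask.ndim)))
        v_idx = np.nonzero(occupied)[0]
        tip_v = tip_idx[0]
        if v_idx.size and tip_v > v_idx.max():
            return False, f"{tip_name} is below {zone_name}: tip too low relative to the carina"
        if v_idx.size and tip_v < v_idx.min():
            return False, f"{tip_name} is above {zone_name}: tip too high relative to the carina"
        return False, f"{tip_name} is outside {zone_name}"

    if (attr := node.attr("DecisionPathWithin")) is not None:
        path_name, region_name, frac_required = attr.params
        for name in (path_name, region_name):
            ok, why = _operand_ready(bb, name)
            if not ok:
                return None, f"indeterminate: {why}"
        path = bb.elements[path_name].selected.mask
        region = bb.elements[region_name].selected.mask
        inside = float(np.logical_and(path, region).sum() / max(path.sum(), 1))
        if inside >= frac_required:
            return True, (f"{inside:.0%} of {path_name} lies within {region_name} "
                          f"(required {frac_required:.0%})")
        return False, (f"only {inside:.0%} of {path_name} lies within "
                       f"{region_name} (required {frac_required:.0%})")

    if (attr := node.attr("DecisionAnd")) is not None:
        (operands,) = attr.params
        parts, value = [], True
        for name in operands:
            el = bb.elements.get(name)
            if el is None or not el.terminal or el.decision is None:
                return None, f"indeterminate: {name} has no decision"
            parts.append(f"{name}={el.decision}")
            value = value and el.decision
        return value, "; ".join(parts)

    raise ValueError(f"{node.name} is not a decision element")


def consistency_check(a: CandidateRegion, b: CandidateRegion,
                      tolerance_mm: float, spacing):
    """Cross-check two estimates of the same object.

    Returns ``(True, refined)`` when the estimates agree within the
    tolerance — the refined estimate is the midpoint for points or the
    intersection centroid for regions — and ``(False, None)`` otherwise,
    in which case the fused element should be flagged unreliable.
    """
    if a is None or b is None:
        return False, None
    ca = np.array(centroid_mm(a, spacing))
    cb = np.array(centroid_mm(b, spacing))
    distance = float(np.linalg.norm(ca - cb))
    if distance > tolerance_mm:
        return False, None
    if a.mask is not None and b.mask is not None:
        inter = np.logical_and(a.mask, b.mask)
        if inter.any():
            com = ndimage.center_of_mass(inter)
            point = tuple(int(round(c)) for c in com)
            return True, CandidateRegion(mask=inter, point=point)
    mid = (ca + cb) / 2.0
    point = tuple(int(round(c / s)) for c, s in zip(mid, spacing))
    return True, CandidateRegion(point=point)
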