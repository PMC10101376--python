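"""The blackboard: shared working memory for the agent loop.

The blackboard holds one Solution Element per semantic-network node — the
working record of recognizing that object in the image: prior feature
expectations translated from knowledge-base attributes, the derived search
area, candidate regions with computed features and fuzzy memberships, the
selected result, and a terminal status.  Agents communicate exclusively
through this structure; an ordered activation history records every agent
action.

Coordinate convention: rasters are indexed (z, y, x) in 3D and (y, x) in 2D,
0-based; physical position = index * spacing in mm; "above" means smaller
z (3D) / smaller y (2D); "patient right" is smaller x under the default
radiological orientation tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .fuzzy import FuzzyFunction
from .kb import SemanticNetwork, SNNode

__all__ = ["PENDING", "RECOGNIZED", "NOT_FOUND", "UNRELIABLE",
           "FeatureExpectation", "CandidateRegion", "SolutionElement",
           "Blackboard", "build_blackboard", "serialize_blackboard",
           "deserialize_blackboard", "summary_report"]

PENDING = "pending"
RECOGNIZED = "recognized"
NOT_FOUND = "not_found"
UNRELIABLE = "unreliable"
TERMINAL = (RECOGNIZED, NOT_FOUND, UNRELIABLE)

# attribute groups that determine how an element gets its candidates
_BOX_ATTRS = ("BoxAbove", "BoxBelow")
_LANDMARK_ATTRS = ("InferiorTipOf", "SuperiorTipOf", "BifurcationOf")
_REFINE_ATTRS = ("FillHoles", "MorphOpen", "MorphClose")
_DECISION_ATTRS = ("DecisionInside", "DecisionPathWithin", "DecisionAnd")

#: expectation kinds whose reference sign convention depends on orientation
DIRECTIONAL_KINDS = ("left_of", "right_of", "above", "below")


@dataclass
class FeatureExpectation:
    """A prior expectation for one candidate feature.

    Relational expectations carry the reference node; unary ones do not.
    ``fuzzy`` is None for overlap-style kinds (part_of / not_part_of /
    inside_of) whose membership is the overlap fraction itself.
    """
    kind: str
    feature: str
    reference: str | None = None
    fuzzy: FuzzyFunction | None = None

    def __post_init__(self):
        relational = self.kind in DIRECTIONAL_KINDS + (
            "same_level", "part_of", "not_part_of", "inside_of")
        if relational and self.reference is None:
            raise ValueError(f"{self.kind} expectation needs a reference node")
        if not relational and self.reference is not None:
            raise ValueError(f"unary {self.kind} expectation cannot carry a reference")


@dataclass
class CandidateRegion:
    """One connected component (or landmark point) under consideration."""
    mask: np.ndarray | None = None          # boolean raster
    point: tuple[int, ...] | None = None    # voxel index, landmark nodes
    features: dict = field(default_factory=dict)
    memberships: dict = field(default_factory=dict)
    score: float = 1.0

    @property
    def size(self) -> int:
        return 1 if self.mask is None else int(self.mask.sum())


@dataclass
class SolutionElement:
    node: SNNode
    role: str                                   # segment|external|box|landmark|refine|decision|consistency|passive
    expectations: list[FeatureExpectation] = field(default_factory=list)
    requirements: list[str | None] = field(default_factory=list)
    search_area: np.ndarray | None = None
    candidates: list[CandidateRegion] = field(default_factory=list)
    selected: CandidateRegion | None = None
    status: str = PENDING
    decision: bool | None = None
    explanation: str | None = None
    # progress flags for the control loop
    search_area_done: bool = False
    candidates_done: bool = False
    scored: bool = False
    # populated on deserialization, where candidate masks are not kept
    candidate_count: int | None = None

    @property
    def name(self) -> str:
        return self.node.name

    @property
    def terminal(self) -> bool:
        return self.status in TERMINAL


@dataclass
class Blackboard:
    net: SemanticNetwork | None
    image: np.ndarray | None
    spacing: tuple[float, ...] | None
    orientation: str = "radiological"
    elements: dict[str, SolutionElement] = field(default_factory=dict)
    history: list[dict] = field(default_factory=list)
    focus: str | None = None

    @property
    def ndim(self) -> int:
        return self.image.ndim if self.image is not None else len(self.spacing)

    def element(self, name: str) -> SolutionElement:
        return self.elements[name]

    def pending(self) -> list[SolutionElement]:
        return [e for e in self.elements.values() if e.status == PENDING]

    def record(self, agent_id: str, element: str | None, score: float) -> None:
        self.history.append({"step": len(self.history), "agent": agent_id,
                             "element": element, "score": float(score)})


# ---------------------------------------------------------------------------
# translating attributes into expectations

def _element_role(node: SNNode) -> str:
    if node.attr("ConsistentWith"):
        return "consistency"
    if any(node.attr(a) for a in _DECISION_ATTRS):
        return "decision"
    if any(node.attr(a) for a in _BOX_ATTRS):
        return "box"
    if any(node.attr(a) for a in _LANDMARK_ATTRS):
        return "landmark"
    if node.attr("ExternalPredictor"):
        return "external"
    if node.attr("IntensityRange"):
        return "segment"
    if any(node.attr(a) for a in _REFINE_ATTRS) and node.attr("PartOf"):
        return "refine"
    return "passive"


_RANGE_KINDS = {"LeftOf": "left_of", "RightOf": "right_of",
                "Above": "above", "Below": "below"}
_OVERLAP_KINDS = {"PartOf": "part_of", "NotPartOf": "not_part_of",
                  "InsideOf": "inside_of"}
_UNARY_KINDS = {"XSectionAreaFuzzy": ("xsection_area", "xsection_area_cm2"),
                "VolumeFuzzy": ("volume", "volume_mm3"),
                "MeanIntensityFuzzy": ("mean_intensity", "mean_intensity")}


def build_expectations(node: SNNode) -> list[FeatureExpectation]:
    out = []
    for attr in node.attributes:
        if attr.name in _RANGE_KINDS:
            ref, low, high = attr.params
            kind = _RANGE_KINDS[attr.name]
            axis = "lateral" if kind in ("left_of", "right_of") else "vertical"
            out.append(FeatureExpectation(
                kind=kind, feature=f"{axis}_offset_to_{ref}", reference=ref,
                fuzzy=FuzzyFunction.from_range(low, high)))
        elif attr.name == "SameLevelAs":
            ref, tol = attr.params
            out.append(FeatureExpectation(
                kind="same_level", feature=f"abs_dz_to_{ref}", reference=ref,
                fuzzy=FuzzyFunction.from_tolerance(tol)))
        elif attr.name in _OVERLAP_KINDS:
            (ref,) = attr.params
            out.append(FeatureExpectation(
                kind=_OVERLAP_KINDS[attr.name],
                feature=f"overlap_with_{ref}", reference=ref))
        elif attr.name in _UNARY_KINDS:
            kind, feature = _UNARY_KINDS[attr.name]
            out.append(FeatureExpectation(kind=kind, feature=feature,
                                          fuzzy=attr.params[0]))
    return out


def _structural_refs(node: SNNode, role: str) -> list[str]:
    refs = []
    for attr in node.attributes:
        if attr.name in _BOX_ATTRS + _LANDMARK_ATTRS + ("HistogramSource",):
            refs.append(attr.params[0])
        elif attr.name in ("DecisionInside",):
            refs.extend(attr.params)
        elif attr.name == "DecisionPathWithin":
            refs.extend(attr.params[:2])
        elif attr.name == "DecisionAnd":
            refs.extend(attr.params[0])
        elif attr.name == "ConsistentWith":
            refs.extend(attr.params[:2])
    return refs


def build_blackboard(net: SemanticNetwork, image: np.ndarray,
                     spacing, orientation: str = "radiological") -> Blackboard:
    """Create one pending Solution Element per node, with attributes
    translated to feature expectations (the knowledge-mapping step)."""
    image = np.asarray(image)
    spacing = tuple(float(s) for s in spacing)
    if image.ndim not in (2, 3) or len(spacing) != image.ndim:
        raise ValueError(f"image must be 2D or 3D with matching spacing; got "
                         f"shape {image.shape}, spacing {spacing}")
    bb = Blackboard(net=net, image=image, spacing=spacing, orientation=orientation)
    for node in net.nodes:
        role = _element_role(node)
        expectations = build_expectations(node)
        requirements: list[str | None] = [e.reference for e in expectations]
        seen = {r for r in requirements if r is not None}
        for ref in _structural_refs(node, role):
            if ref not in seen:
                requirements.append(ref)
                seen.add(ref)
        bb.elements[node.name] = SolutionElement(
            node=node, role=role, expectations=expectations,
            requirements=requirements)
    return bb


# ---------------------------------------------------------------------------
# serialization

def _save_mask(mask: np.ndarray, spacing, path: Path) -> None:
    if mask.ndim == 3:
        affine = np.diag(list(spacing) + [1.0])
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), path)
    else:
        iio.imwrite(path, mask.astype(np.uint8) * 255)


def _load_mask(path: Path) -> np.ndarray:
    if path.suffix == ".png":
        return np.asarray(iio.imread(path)) > 0
    return np.asarray(nib.load(path).dataobj) > 0


def serialize_blackboard(bb: Blackboard, directory: str | Path) -> Path:
    """Write the blackboard index (JSON) plus one mask file per selected
    region.  Elements with no selected region produce no mask file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".nii.gz" if bb.ndim == 3 else ".png"
    index: dict = {
        "spacing_mm": list(bb.spacing) if bb.spacing else None,
        "orientation": bb.orientation,
        "history": bb.history,
        "elements": {},
    }
    for name, el in bb.elements.items():
        rec: dict = {"status": el.status, "role": el.role,
                     "decision": el.decision, "explanation": el.explanation,
                     "n_candidates": len(el.candidates)}
        if el.selected is not None:
            rec["score"] = el.selected.score
            rec["features"] = {k: (list(v) if isinstance(v, (tuple, list)) else v)
                               for k, v in el.selected.features.items()}
            rec["memberships"] = dict(el.selected.memberships)
            if el.selected.point is not None:
                rec["point"] = list(el.selected.point)
            if el.selected.mask is not None:
                mask_name = f"{name}{suffix}"
                _save_mask(el.selected.mask, bb.spacing, directory / mask_name)
                rec["mask_file"] = mask_name
        index["elements"][name] = rec
    (directory / "blackboard.json").write_text(json.dumps(index, indent=2))
    return directory


def deserialize_blackboard(directory: str | Path,
                           net: SemanticNetwork | None = None) -> Blackboard:
    """Rebuild a blackboard from its output directory.

    Scalar fields round-trip bit-exactly; masks round-trip voxel-exactly.
    Expectations are only rebuilt when the originating network is supplied.
    """
    directory = Path(directory)
    index = json.loads((directory / "blackboard.json").read_text())
    spacing = tuple(index["spacing_mm"]) if index["spacing_mm"] else None
    bb = Blackboard(net=net, image=None, spacing=spacing,
                    orientation=index["orientation"], history=index["history"])
    for name, rec in index["elements"].items():
        node = net.node(name) if net is not None else SNNode(name, ())
        el = SolutionElement(node=node, role=rec["role"], status=rec["status"],
                             decision=rec["decision"],
                             explanation=rec["explanation"],
                             candidate_count=rec.get("n_candidates"))
        if net is not None:
            el.expectations = build_expectations(node)
        if "score" in rec:
            mask = None
            if "mask_file" in rec:
                mask = _load_mask(directory / rec["mask_file"])
            features = {k: (tuple(v) if isinstance(v, list) else v)
                        for k, v in rec.get("features", {}).items()}
            el.selected = CandidateRegion(
                mask=mask,
                point=tuple(rec["point"]) if "point" in rec else None,
                features=features,
                memberships=rec.get("memberships", {}),
                score=rec["score"])
        bb.elements[name] = el
    return bb


def summary_report(bbs: list[Blackboard],
                   case_ids: list[str] | None = None) -> pd.DataFrame:
    """Tabular per-case per-node summary: status, score, key features."""
    if not bbs:
        raise ValueError("need at least one blackboard")
    if case_ids is None:
        case_ids = [f"case_{i}" for i in range(len(bbs))]
    rows = []
    for case, bb in zip(case_ids, bbs):
        for name, el in bb.elements.items():
            sel = el.selected
            rows.append({
                "case": case,
                "node": name,
                "status": el.status,
                "score": sel.score if sel else np.nan,
                "n_candidates": (el.candidate_count if el.candidate_count is not None
                                 else len(el.candidates)),
                "volume_mm3": sel.features.get("volume_mm3", np.nan) if sel else np.nan,
                "decision": el.decision,
                "explanation": el.explanation or "",
            })
    return pd.DataFrame(rows).sort_values(["case", "node"], kind="stable",
                                          ignore_index=True)
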