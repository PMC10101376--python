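"""Opportunistic agent activation loop.

Recognition proceeds by iteratively activating exactly one agent at a time:
every registered agent computes an activation score from the current
blackboard, the highest scorer acts, and the loop repeats until all scores
are zero.  A scheduling agent picks which Solution Element to focus on next —
the pending element with the highest fraction of computable features (i.e.
whose prerequisite objects have already reached a terminal status) — so the
processing order adapts to what has actually been found, and a missing object
changes the order without hard-coded exception rules.

The per-element pipeline is: search-area inference (reasoning) →
candidate generation (segmentation) → feature computation and fuzzy scoring
(reasoning) → best-candidate selection or rejection (reasoning).  Decision
and consistency elements are evaluated directly by reasoning agents once
their operands are terminal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from . import reason_agents as ra
from . import seg_agents as sa
from .blackboard import (NOT_FOUND, PENDING, RECOGNIZED, UNRELIABLE,
                         Blackboard, CandidateRegion, SolutionElement,
                         build_blackboard)
from .genome import apply_chromosome
from .kb import SemanticNetwork

__all__ = ["AgentRegistration", "computable_fraction",
           "next_solution_element", "run_think"]

#: hard cap on activations per node before the loop aborts with a diagnostic
MAX_ACTIVATIONS_PER_NODE = 100


@dataclass(frozen=True)
class AgentRegistration:
    """A registered agent: pure activation function plus an action."""
    agent_id: str
    family: str                      # knowledge | scheduling | segmentation | reasoning
    activation: Callable[[Blackboard], float]
    act: Callable[[Blackboard], None]
    priority_rank: int = 0           # tie-break: lower rank wins


# ---------------------------------------------------------------------------
# scheduling

def computable_fraction(se: SolutionElement, bb: Blackboard) -> float:
    """Fraction of the element's feature requirements that can be computed.

    A requirement is computable when it is unary (no reference) or its
    reference element has reached any terminal status — a not-found
    prerequisite counts as resolved, so recognition of dependents proceeds
    on their remaining knowledge.  An element with no requirements scores 1.
    """
    if not se.requirements:
        return 1.0
    ok = sum(1 for ref in se.requirements
             if ref is None or bb.elements[ref].terminal)
    return ok / len(se.requirements)


def next_solution_element(bb: Blackboard) -> str | None:
    """Pending element with the highest computable fraction; ties break by
    Node List order; None when nothing is pending."""
    best_name, best_frac = None, -1.0
    for node in bb.net.nodes:                      # Node List order
        el = bb.elements[node.name]
        if el.status != PENDING:
            continue
        frac = computable_fraction(el, bb)
        if frac > best_frac:
            best_name, best_frac = node.name, frac
    return best_name


# ---------------------------------------------------------------------------
# segmentation dispatch (candidate generation per element role)

def _threshold_candidates(el: SolutionElement, bb: Blackboard) -> list[CandidateRegion]:
    low, high = el.node.attr("IntensityRange").params
    min_size = el.node.attr("MinSize")
    labels = sa.threshold_segment(bb.image, sa.IntensityWindow(low, high),
                                  search_area=el.search_area)
    return sa.extract_candidates(labels, int(min_size.params[0]) if min_size else 1)


def _build_preprocess(el: SolutionElement, bb: Blackboard, plugins) -> np.ndarray | None:
    """Assemble the node's preprocessing channels, if any are declared."""
    node = el.node
    steps_by_channel: dict[int, list] = {}
    for attr in node.attributes:
        if attr.name == "NormMinMax":
            steps_by_channel.setdefault(int(attr.params[0]), []).append(("minmax",))
        elif attr.name == "NormCentileClip":
            ch, lo, hi = attr.params
            steps_by_channel.setdefault(int(ch), []).append(("centile_clip", lo, hi))
        elif attr.name == "NormHistEq":
            steps_by_channel.setdefault(int(attr.params[0]), []).append(("histeq",))
        elif attr.name == "NormBiasField":
            steps_by_channel.setdefault(int(attr.params[0]), []).append(("bias_field",))
    if not steps_by_channel:
        return None
    channels = tuple(tuple(steps_by_channel[k]) for k in sorted(steps_by_channel))
    source_mask = None
    if (src := node.attr("HistogramSource")) is not None:
        ref = bb.elements.get(src.params[0])
        if ref is None or ref.selected is None or ref.selected.mask is None:
            raise ValueError(f"{node.name}: histogram source {src.params[0]!r} "
                             "is not resolved to a region")
        source_mask = ref.selected.mask
    spec = sa.PreprocessSpec(channels=channels, histogram_source=None)
    return sa.preprocess(bb.image, spec, source_mask=source_mask,
                         bias_hook=(plugins or {}).get("bias_field"))


def _external_candidates(el: SolutionElement, bb: Blackboard,
                         plugins) -> list[CandidateRegion] | None:
    hook = (plugins or {}).get(el.name)
    if hook is None:
        return None                      # no predictor registered -> not_found
    channels = _build_preprocess(el, bb, plugins)
    image_in = channels if channels is not None else bb.image
    labels = sa.external_predict(bb.image, lambda img, sp: hook(image_in, sp),
                                 spacing=bb.spacing)
    if el.search_area is not None:
        labels = labels * el.search_area
        labels, _ = ndimage.label(labels > 0, structure=np.ones((3,) * labels.ndim))
    min_size = el.node.attr("MinSize")
    return sa.extract_candidates(labels, int(min_size.params[0]) if min_size else 1)


def _box_candidates(el: SolutionElement, bb: Blackboard) -> list[CandidateRegion]:
    attr = el.node.attr("BoxAbove") or el.node.attr("BoxBelow")
    direction = "above" if attr.name == "BoxAbove" else "below"
    ref_name, width, height, d_low, d_high = attr.params
    ref = ra._resolved_reference(bb, ref_name)
    if ref is None:
        return []
    center = ra.centroid_mm(ref, bb.spacing)
    box = sa.derive_box(bb.image.shape, bb.spacing, center, center[0],
                        (width, height), (d_low, d_high), direction)
    for pa in el.node.attrs("PartOf"):
        parent = ra._resolved_reference(bb, pa.params[0])
        if parent is not None and parent.mask is not None:
            box = box & parent.mask
    return [CandidateRegion(mask=box)] if box.any() else []


def _landmark_candidates(el: SolutionElement, bb: Blackboard) -> list[CandidateRegion]:
    node = el.node
    attr = (node.attr("InferiorTipOf") or node.attr("SuperiorTipOf")
            or node.attr("BifurcationOf"))
    ref = ra._resolved_reference(bb, attr.params[0])
    if ref is None or ref.mask is None:
        return []
    mask = ref.mask
    occupied = np.any(mask, axis=tuple(range(1, mask.ndim)))
    rows = np.nonzero(occupied)[0]
    if rows.size == 0:
        return []
    if attr.name in ("InferiorTipOf", "SuperiorTipOf"):
        v = rows.max() if attr.name == "InferiorTipOf" else rows.min()
        plane = mask[v]
        com = ndimage.center_of_mass(plane)
        point = (int(v), *(int(round(c)) for c in np.atleast_1d(com)))
        return [CandidateRegion(point=point)]
    # bifurcation: first vertical level (top-down) whose in-plane section
    # splits into >= 2 components and stays split over the next levels
    # (transient single-level splits are segmentation artifacts, not anatomy)
    structure = np.ones((3,) * (mask.ndim - 1), dtype=int)
    persistence = 3

    def n_parts(v):
        return ndimage.label(np.atleast_1d(mask[v]), structure=structure)[1]

    for v in rows:
        if all(v + k < mask.shape[0] and n_parts(v + k) >= 2
               for k in range(persistence)):
            labels, n = ndimage.label(np.atleast_1d(mask[v]), structure=structure)
            coms = ndimage.center_of_mass(mask[v], labels, range(1, n + 1))
            mid = np.mean(np.atleast_2d(coms), axis=0)
            point = (int(v), *(int(round(c)) for c in np.atleast_1d(mid)))
            return [CandidateRegion(point=point)]
    return []


def _refine_candidates(el: SolutionElement, bb: Blackboard) -> list[CandidateRegion]:
    parent = ra._resolved_reference(bb, el.node.attr("PartOf").params[0])
    if parent is None or parent.mask is None:
        return []
    ops = []
    for attr in el.node.attributes:
        if attr.name == "FillHoles":
            ops.append(("fill_holes",))
        elif attr.name == "MorphOpen":
            ops.append(("open", attr.params[0]))
        elif attr.name == "MorphClose":
            ops.append(("close", attr.params[0]))
    return [CandidateRegion(mask=sa.refine_region(parent.mask, ops, bb.spacing))]


def _generate_candidates(el: SolutionElement, bb: Blackboard, plugins) -> None:
    if el.role == "segment":
        el.candidates = _threshold_candidates(el, bb)
    elif el.role == "external":
        cands = _external_candidates(el, bb, plugins)
        if cands is None:
            el.status = NOT_FOUND
            el.explanation = "no external predictor registered"
            return
        el.candidates = cands
    elif el.role == "box":
        el.candidates = _box_candidates(el, bb)
    elif el.role == "landmark":
        el.candidates = _landmark_candidates(el, bb)
    elif el.role == "refine":
        el.candidates = _refine_candidates(el, bb)
    elif el.role == "passive":
        el.status = NOT_FOUND
        el.explanation = "no segmentation source for this element"
    el.candidates_done = True


# ---------------------------------------------------------------------------
# the agent set

def _focused(bb: Blackboard) -> SolutionElement | None:
    if bb.focus is None:
        return None
    el = bb.elements[bb.focus]
    return None if el.terminal else el


def _needs_search_area(el: SolutionElement) -> bool:
    return (el.role in ("segment", "external") and not el.search_area_done)


def _release(bb: Blackboard) -> None:
    el = bb.elements.get(bb.focus) if bb.focus else None
    if el is not None and el.terminal:
        bb.focus = None


def _make_agents(plugins) -> list[AgentRegistration]:
    def schedule_score(bb):
        return 0.9 if bb.focus is None and bb.pending() else 0.0

    def schedule(bb):
        bb.focus = next_solution_element(bb)

    def search_score(bb):
        el = _focused(bb)
        return 0.8 if el is not None and _needs_search_area(el) else 0.0

    def search(bb):
        el = _focused(bb)
        el.search_area = ra.derive_search_area(el, bb)
        el.search_area_done = True

    def segment_score(bb):
        el = _focused(bb)
        if el is None or el.candidates_done or _needs_search_area(el):
            return 0.0
        return 0.7 if el.role not in ("decision", "consistency") else 0.0

    def segment(bb):
        el = _focused(bb)
        _generate_candidates(el, bb, plugins)
        _release(bb)

    def score_score(bb):
        el = _focused(bb)
        return 0.6 if el is not None and el.candidates_done and not el.scored else 0.0

    def score(bb):
        el = _focused(bb)
        for cand in el.candidates:
            ra.compute_features(cand, el, bb)
            ra.score_candidate(cand, el.expectations)
        el.scored = True

    def select_score(bb):
        el = _focused(bb)
        return 0.5 if el is not None and el.scored else 0.0

    def select(bb):
        el = _focused(bb)
        thr = el.node.attr("AcceptanceThreshold")
        ra.select_best(el, thr.params[0] if thr else 0.0)
        _release(bb)

    def decision_score(bb):
        el = _focused(bb)
        return 0.6 if el is not None and el.role == "decision" else 0.0

    def decide(bb):
        el = _focused(bb)
        el.decision, el.explanation = ra.evaluate_decision(el, bb)
        el.status = RECOGNIZED
        _release(bb)

    def consistency_score(bb):
        el = _focused(bb)
        return 0.6 if el is not None and el.role == "consistency" else 0.0

    def check(bb):
        el = _focused(bb)
        a_name, b_name, tol = el.node.attr("ConsistentWith").params
        a = ra._resolved_reference(bb, a_name)
        b = ra._resolved_reference(bb, b_name)
        if a is None or b is None:
            el.status = UNRELIABLE
            missing = a_name if a is None else b_name
            el.explanation = (f"unable to reliably identify {el.name}: "
                              f"estimate {missing} is missing")
        else:
            consistent, refined = ra.consistency_check(a, b, tol, bb.spacing)
            if consistent:
                el.selected = refined
                el.candidates = [refined]
                el.status = RECOGNIZED
                el.explanation = (f"{a_name} and {b_name} agree within {tol} mm")
            else:
                el.status = UNRELIABLE
                el.explanation = (f"unable to reliably identify {el.name}: "
                                  f"{a_name} and {b_name} disagree beyond {tol} mm")
        _release(bb)

    return [
        AgentRegistration("scheduler", "scheduling", schedule_score, schedule, 1),
        AgentRegistration("search_area_reasoner", "reasoning", search_score, search, 2),
        AgentRegistration("segmenter", "segmentation", segment_score, segment, 3),
        AgentRegistration("candidate_scorer", "reasoning", score_score, score, 4),
        AgentRegistration("selector", "reasoning", select_score, select, 5),
        AgentRegistration("decision_maker", "reasoning", decision_score, decide, 6),
        AgentRegistration("consistency_checker", "reasoning", consistency_score, check, 7),
    ]


# ---------------------------------------------------------------------------
# the think loop

def run_think(net: SemanticNetwork, image: np.ndarray, spacing,
              chromosome=None, plugins: dict | None = None,
              orientation: str = "radiological") -> Blackboard:
    """Apply a knowledge base to an image and return the completed blackboard.

    When the network has tunable parameters a chromosome must be supplied to
    specify it.  ``plugins`` maps node names to external predictor hooks
    (``hook(image_or_channels, spacing) -> mask``); the key ``"bias_field"``
    registers the bias-field-correction hook used in preprocessing.
    """
    _, specified = apply_chromosome(net, chromosome)
    bb = build_blackboard(specified, image, spacing, orientation=orientation)
    bb.record("knowledge_mapper", None, 1.0)
    agents = _make_agents(plugins)
    cap = MAX_ACTIVATIONS_PER_NODE * max(1, len(specified.nodes))
    steps = 0
    while True:
        scored = [(a.activation(bb), -a.priority_rank, a.agent_id, a) for a in agents]
        best_score, _, _, best = max(scored, key=lambda t: (t[0], t[1], t[2]))
        if best_score <= 0.0:
            break
        focus_before = bb.focus
        best.act(bb)
        bb.record(best.agent_id, bb.focus or focus_before, best_score)
        steps += 1
        if steps > cap:
            stuck = bb.focus or next_solution_element(bb)
            raise RuntimeError(
                f"think loop exceeded {cap} activations; element {stuck!r} "
                "appears stuck (no state change is advancing it)")
    return bb
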