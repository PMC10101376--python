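import numpy as np
import pytest

from cognimage.blackboard import (NOT_FOUND, RECOGNIZED, Blackboard,
                                  CandidateRegion, FeatureExpectation,
                                  SolutionElement, build_blackboard)
from cognimage.control import run_think
from cognimage.fuzzy import FuzzyFunction
from cognimage.kb import SNNode
from cognimage.reason_agents import (compute_features, consistency_check,
                                     derive_search_area, score_candidate,
                                     select_best)


def bare_element(expectations=(), node_name="x"):
    return SolutionElement(node=SNNode(node_name, ()), role="segment",
                           expectations=list(expectations))


def bare_blackboard(shape=(40, 60), spacing=(1.0, 1.0)):
    return Blackboard(net=None, image=np.zeros(shape), spacing=spacing)


def add_reference(bb, name, point=None, mask=None):
    el = bare_element(node_name=name)
    el.status = RECOGNIZED
    el.selected = CandidateRegion(mask=mask, point=point)
    bb.elements[name] = el
    return el


class TestSearchArea:
    def test_no_relations_spans_whole_image(self):
        bb = bare_blackboard()
        area = derive_search_area(bare_element(), bb)
        assert area.all()

    def test_left_of_band_closed_form(self):
        # reference point at x = 100 mm; LeftOf range 50-100 mm with the
        # 20% soft shoulder admits lateral offsets in [40, 110] mm,
        # i.e. x in [140, 210] mm on the patient-left side
        bb = bare_blackboard(shape=(4, 300), spacing=(1.0, 1.0))
        add_reference(bb, "ref", point=(0, 100))
        exp = FeatureExpectation(kind="left_of", feature="dx", reference="ref",
                                 fuzzy=FuzzyFunction.from_range(50, 100))
        area = derive_search_area(bare_element([exp]), bb)
        xs = np.nonzero(area.any(axis=0))[0]
        assert xs.min() == 140 and xs.max() == 210

    def test_unresolved_reference_is_ignored(self):
        bb = bare_blackboard()
        el = add_reference(bb, "ref", point=(0, 0))
        el.status = NOT_FOUND
        el.selected = None
        exp = FeatureExpectation(kind="left_of", feature="dx", reference="ref",
                                 fuzzy=FuzzyFunction.from_range(50, 100))
        assert derive_search_area(bare_element([exp]), bb).all()

    def test_kidney_band_excludes_stray_blob(self, kidney_net, abdominal):
        bb = run_think(kidney_net, abdominal.image, abdominal.spacing)
        area = bb.element("kidney_left_init").search_area
        assert not area[abdominal.masks["stray"]].any()
        assert area[abdominal.masks["kidney_left"]].all()


class TestFeatures:
    def test_single_voxel_volume_and_centroid(self):
        bb = Blackboard(net=None, image=np.zeros((5, 5, 5)),
                        spacing=(1.0, 1.0, 1.0))
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 3, 4] = True
        cand = CandidateRegion(mask=mask)
        feats = compute_features(cand, bare_element(), bb)
        assert feats["volume_mm3"] == 1.0
        assert feats["centroid_mm"] == (2.0, 3.0, 4.0)

    def test_vertical_offset_between_bars(self):
        bb = Blackboard(net=None, image=np.zeros((50, 10, 10)),
                        spacing=(1.0, 1.0, 1.0))
        ref_mask = np.zeros((50, 10, 10), dtype=bool)
        ref_mask[10, 0, 0:10] = True
        add_reference(bb, "ref", mask=ref_mask)
        cand_mask = np.zeros((50, 10, 10), dtype=bool)
        cand_mask[40, 0, 0:10] = True
        exp = FeatureExpectation(kind="same_level", feature="dz", reference="ref",
                                 fuzzy=FuzzyFunction.from_tolerance(30))
        feats = compute_features(CandidateRegion(mask=cand_mask),
                                 bare_element([exp]), bb)
        assert feats["dz"] == pytest.approx(30.0)

    def test_full_containment_overlap_is_one(self):
        bb = bare_blackboard(shape=(10, 10))
        parent = np.zeros((10, 10), dtype=bool)
        parent[2:8, 2:8] = True
        add_reference(bb, "parent", mask=parent)
        child = np.zeros((10, 10), dtype=bool)
        child[3:5, 3:5] = True
        exp = FeatureExpectation(kind="part_of", feature="ov", reference="parent")
        feats = compute_features(CandidateRegion(mask=child),
                                 bare_element([exp]), bb)
        assert feats["ov"] == 1.0


class TestScoring:
    def test_empty_expectations_score_one(self):
        cand = CandidateRegion(mask=np.ones((2, 2), dtype=bool))
        assert score_candidate(cand, []) == 1.0

    def test_area_ramp_interpolates_half(self):
        exp = FeatureExpectation(kind="xsection_area", feature="xsection_area_cm2",
                                 fuzzy=FuzzyFunction(((100.0, 0.0), (500.0, 1.0))))
        cand = CandidateRegion(features={"xsection_area_cm2": 300.0})
        assert score_candidate(cand, [exp]) == pytest.approx(0.5)

    def test_score_is_product_of_memberships(self):
        e1 = FeatureExpectation(kind="xsection_area", feature="xsection_area_cm2",
                                fuzzy=FuzzyFunction(((0.0, 0.5),)))
        e2 = FeatureExpectation(kind="not_part_of", feature="ov", reference="bone")
        cand = CandidateRegion(features={"xsection_area_cm2": 1.0, "ov": 0.25})
        assert score_candidate(cand, [e1, e2]) == pytest.approx(0.5 * 0.75)

    def test_out_of_band_feature_zeroes_the_score(self):
        exp = FeatureExpectation(kind="left_of", feature="dx", reference="spine",
                                 fuzzy=FuzzyFunction.from_range(50, 100))
        cand = CandidateRegion(features={"dx": 125.0})
        assert score_candidate(cand, [exp]) == 0.0

    def test_unresolved_reference_is_non_informative(self):
        exp = FeatureExpectation(kind="not_part_of", feature="ov", reference="bone")
        cand = CandidateRegion(features={"ov": None})
        assert score_candidate(cand, [exp]) == 1.0

    def test_narrower_support_never_raises_score(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a = rng.uniform(0, 100)
            b = a + rng.uniform(1, 100)
            a2 = rng.uniform(a, b)
            b2 = rng.uniform(a2, b)
            wide = FuzzyFunction.from_range(a, b)
            narrow = FuzzyFunction.from_range(a2, b2)
            for x in rng.uniform(a - 50, b + 50, size=20):
                assert narrow(x) <= wide(x) + 1e-12


class TestSelection:
    def test_single_positive_candidate_selected(self):
        el = bare_element()
        el.candidates = [CandidateRegion(mask=np.ones((2, 2), bool), score=0.8)]
        select_best(el)
        assert el.status == RECOGNIZED and el.selected is el.candidates[0]

    def test_all_zero_scores_yield_not_found(self):
        el = bare_element()
        el.candidates = [CandidateRegion(mask=np.ones((2, 2), bool), score=0.0)]
        select_best(el)
        assert el.status == NOT_FOUND and el.selected is None

    def test_score_tie_breaks_toward_larger_region(self):
        small = np.zeros((4, 4), bool); small[0, 0] = True
        big = np.zeros((4, 4), bool); big[1:3, 1:3] = True
        el = bare_element()
        el.candidates = [CandidateRegion(mask=small, score=0.5),
                         CandidateRegion(mask=big, score=0.5)]
        select_best(el)
        assert el.selected.size == 4

    def test_selection_invariant_to_candidate_order(self):
        rng = np.random.default_rng(5)
        masks, scores = [], []
        for i in range(5):
            m = np.zeros((6, 6), bool)
            m.ravel()[: i + 1] = True
            masks.append(m)
            scores.append(float(rng.random()))
        def run(order):
            el = bare_element()
            el.candidates = [CandidateRegion(mask=masks[i], score=scores[i])
                             for i in order]
            select_best(el)
            return el.selected.score, el.selected.size
        assert run(range(5)) == run(reversed(range(5)))


class TestConsistency:
    def test_identical_points_refine_to_the_point(self):
        a = CandidateRegion(point=(10, 10))
        ok, refined = consistency_check(a, CandidateRegion(point=(10, 10)),
                                        10.0, (1.0, 1.0))
        assert ok and refined.point == (10, 10)

    def test_points_beyond_tolerance_are_inconsistent(self):
        a = CandidateRegion(point=(0, 0))
        b = CandidateRegion(point=(0, 25))
        ok, refined = consistency_check(a, b, 10.0, (1.0, 1.0))
        assert not ok and refined is None

    def test_nearby_points_fuse_to_midpoint(self):
        a = CandidateRegion(point=(0, 10))
        b = CandidateRegion(point=(0, 16))
        ok, refined = consistency_check(a, b, 10.0, (1.0, 1.0))
        assert ok and refined.point == (0, 13)

    def test_missing_estimate_is_unreliable(self):
        assert consistency_check(None, CandidateRegion(point=(0, 0)),
                                 10.0, (1, 1)) == (False, None)
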