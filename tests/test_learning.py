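import numpy as np
import pytest

from cognimage import apps, make_abdominal_phantom
from cognimage.genome import decode_gene
from cognimage.kb import list_tunable_parameters, parse_network
from cognimage.learning import (FitnessSpec, GAConfig, TuningCase, dice,
                             distribute, evaluate_fitness, ga_optimize,
                             hausdorff_distance, precision, sensitivity,
                             specificity, status_summary)

SHELLS = ((1.15, 250.0), (1.3, 150.0))


@pytest.fixture(scope="module")
def tuning_setup(tmp_path_factory):
    net = apps.kidney_tuning_kb(tmp_path_factory.mktemp("tuning_kb"))
    ph = make_abdominal_phantom(kidney_shells=SHELLS, seed=11)
    case = TuningCase(image=ph.image, spacing=ph.spacing,
                      references={"kidney_left_init": ph.masks["kidney_left"]})
    spec = FitnessSpec(metrics={"kidney_left_init": "dice"})
    return net, [case], spec


class TestMetrics:
    def test_dice_of_half_overlap(self):
        a = np.zeros(300, dtype=bool); a[:100] = True
        b = np.zeros(300, dtype=bool); b[50:150] = True
        assert dice(a, b) == pytest.approx(2 * 50 / (100 + 100))

    def test_identical_masks_have_unit_dice(self):
        m = np.random.default_rng(0).random((5, 5)) > 0.5
        assert dice(m, m) == 1.0

    def test_confusion_metrics_by_hand_count(self):
        pred = np.array([1, 1, 0, 0, 1, 0], dtype=bool)
        ref = np.array([1, 0, 0, 1, 1, 0], dtype=bool)
        # tp=2 fp=1 fn=1 tn=2
        assert sensitivity(pred, ref) == pytest.approx(2 / 3)
        assert specificity(pred, ref) == pytest.approx(2 / 3)
        assert precision(pred, ref) == pytest.approx(2 / 3)

    def test_hausdorff_grows_with_a_stray_region(self):
        truth = np.zeros((20, 20), dtype=bool)
        truth[5:10, 5:10] = True
        with_stray = truth.copy()
        with_stray[18, 18] = True
        clean = hausdorff_distance(truth, truth, (1.0, 1.0))
        stray = hausdorff_distance(with_stray, truth, (1.0, 1.0))
        assert clean == 0.0 and stray > 10.0


class TestEvaluateFitness:
    def test_exact_recovery_scores_one(self, tuning_setup):
        net, cases, spec = tuning_setup
        # decoded 300 reproduces the kidney mask almost exactly
        assert evaluate_fitness("010", net, cases, spec) > 0.99

    def test_missing_reference_is_an_error(self, tuning_setup):
        net, cases, spec = tuning_setup
        bad = TuningCase(image=cases[0].image, spacing=cases[0].spacing,
                         references={})
        with pytest.raises(ValueError, match="kidney_left_init"):
            evaluate_fitness("010", net, [bad], spec)

    def test_weighted_average_of_node_metrics(self, tmp_path):
        net = apps.kidney_kb(tmp_path)
        ph = make_abdominal_phantom(seed=2)
        refs = {"kidney_left": ph.masks["kidney_left"],
                "kidney_right": ph.masks["kidney_right"]}
        case = TuningCase(image=ph.image, spacing=ph.spacing, references=refs)
        per_node = {}
        for node in refs:
            spec = FitnessSpec(metrics={node: "dice"})
            per_node[node] = evaluate_fitness(None, net, [case], spec)
        combo = FitnessSpec(metrics={n: "dice" for n in refs},
                            weights={"kidney_left": 0.7, "kidney_right": 0.3})
        expected = 0.7 * per_node["kidney_left"] + 0.3 * per_node["kidney_right"]
        assert evaluate_fitness(None, net, [case], combo) == pytest.approx(expected)


class TestDistribute:
    def test_no_jobs_yield_empty_map(self):
        assert distribute([]) == {}

    def test_aggregation_is_order_invariant(self):
        jobs = [(f"j{i}", (lambda v=i: v * 0.1)) for i in range(20)]
        sequential = distribute(jobs)
        rng = np.random.default_rng(0)
        shuffled = list(jobs)
        rng.shuffle(shuffled)
        assert distribute(shuffled) == sequential

    def test_failing_job_retried_then_zero(self):
        calls = {"n": 0}
        def flaky():
            calls["n"] += 1
            raise RuntimeError("boom")
        out = distribute([("bad", flaky)])
        assert out == {"bad": 0.0}
        assert calls["n"] == 2                      # retried exactly once

    def test_population_times_cases_job_count(self, tuning_setup):
        net, cases, spec = tuning_setup
        seen = []
        def counting_backend(jobs):
            seen.extend(k for k, _ in jobs)
            return {k: fn() for k, fn in jobs}
        cfg = GAConfig(population_size=6, generations=1, seed=0)
        ga_optimize(net, cases, spec, cfg, distributor=counting_backend)
        assert len(seen) == len(set(seen)) <= 6     # one job per distinct chromosome


class TestGA:
    def test_two_bit_space_equals_exhaustive_search(self, tmp_path):
        # with crossover and mutation off and the full 2-bit population, the
        # GA must reproduce a brute-force enumeration of all 4 chromosomes
        apps.write_kb({"blob": "IntensityRange 2 {0, 1, 1, 7} 100\n"}, tmp_path)
        net = parse_network(tmp_path)
        img = np.zeros((6, 6))
        img[1:4, 1:4] = 5.0                          # in range iff low <= 5
        ref = img == 5.0
        case = TuningCase(image=img, spacing=(1.0, 1.0),
                          references={"blob": ref})
        spec = FitnessSpec(metrics={"blob": "dice"})
        exhaustive = {bits: evaluate_fitness(bits, net, [case], spec)
                      for bits in ("00", "01", "10", "11")}
        cfg = GAConfig(population_size=4, generations=2, elitism_count=1,
                       crossover_prob=0.0, mutation_prob_per_bit=0.0, seed=0)
        best, _, traj = ga_optimize(net, [case], spec, cfg,
                                    initial_population=list(exhaustive))
        assert best.bits == max(exhaustive, key=exhaustive.get)
        assert traj.best_so_far.iloc[-1] == max(exhaustive.values())

    def test_threshold_recovery_and_monotone_best(self, tuning_setup):
        net, cases, spec = tuning_setup
        cfg = GAConfig(population_size=30, generations=10, seed=3)
        best, specified, traj = ga_optimize(net, cases, spec, cfg)
        enc = list_tunable_parameters(net)[0].encoding
        assert decode_gene(best.bits, enc) == 300.0
        assert traj.best_so_far.is_monotonic_increasing
        assert specified.node("kidney_left_init").attr("IntensityRange").params[0] == 300.0

    def test_fixed_seed_reproduces_trajectory(self, tuning_setup):
        net, cases, spec = tuning_setup
        cfg = GAConfig(population_size=10, generations=4, seed=9)
        _, _, t1 = ga_optimize(net, cases, spec, cfg)
        _, _, t2 = ga_optimize(net, cases, spec, cfg)
        assert t1.equals(t2)

    def test_untuned_network_has_nothing_to_optimize(self, kidney_net, tuning_setup):
        _, cases, spec = tuning_setup
        with pytest.raises(ValueError, match="nothing to optimize"):
            ga_optimize(kidney_net, cases, spec, GAConfig(generations=1))


class TestStatusSummary:
    def test_one_row_per_generation(self, tuning_setup, tmp_path):
        net, cases, spec = tuning_setup
        cfg = GAConfig(population_size=8, generations=3, seed=1)
        _, _, traj = ga_optimize(net, cases, spec, cfg)
        table, report = status_summary(traj, tmp_path / "t.csv")
        assert len(table) == 3
        assert (tmp_path / "t.csv").exists()
        assert table.best_so_far.is_monotonic_increasing

    def test_baseline_crossing_reported(self, tuning_setup):
        net, cases, spec = tuning_setup
        cfg = GAConfig(population_size=10, generations=3, seed=2)
        _, _, traj = ga_optimize(net, cases, spec, cfg)
        _, report = status_summary(traj, baseline=0.5)
        assert "first exceeded at generation" in report
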