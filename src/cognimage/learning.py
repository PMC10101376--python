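"""Knowledge-network learning and optimization.

All tunable knowledge-base parameters are co-optimized at once: a binary
chromosome decodes to a full parameter set (see :mod:`cognimage.genome`),
the specified knowledge base is applied to every case of a tuning set, and
the per-node segmentation/landmark metrics against the references are
combined into a scalar fitness in [0, 1].  A seeded genetic algorithm —
elitism, tournament selection, single-point crossover, per-bit mutation —
searches the chromosome space; an optimizer/distributor split keeps fitness
evaluation pluggable (the reference distributor runs jobs sequentially, and
results are independent of job completion order).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .blackboard import RECOGNIZED, Blackboard
from .control import run_think
from .genome import Chromosome, random_chromosome
from .kb import SemanticNetwork, chromosome_span, list_tunable_parameters

__all__ = ["TuningCase", "FitnessSpec", "GAConfig", "dice", "sensitivity",
           "specificity", "precision", "recall", "point_fitness",
           "hausdorff_distance", "evaluate_fitness", "ga_optimize",
           "distribute", "status_summary"]


# ---------------------------------------------------------------------------
# overlap / distance metrics

def _counts(pred: np.ndarray, ref: np.ndarray):
    pred = np.asarray(pred).astype(bool)
    ref = np.asarray(ref).astype(bool)
    tp = float(np.logical_and(pred, ref).sum())
    fp = float(np.logical_and(pred, ~ref).sum())
    fn = float(np.logical_and(~pred, ref).sum())
    tn = float(np.logical_and(~pred, ~ref).sum())
    return tp, fp, fn, tn


def dice(pred, ref) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    tp, fp, fn, _ = _counts(pred, ref)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2 * tp / denom


def sensitivity(pred, ref) -> float:
    tp, _, fn, _ = _counts(pred, ref)
    return 1.0 if tp + fn == 0 else tp / (tp + fn)


recall = sensitivity


def specificity(pred, ref) -> float:
    _, fp, _, tn = _counts(pred, ref)
    return 1.0 if fp + tn == 0 else tn / (fp + tn)


def precision(pred, ref) -> float:
    tp, fp, _, _ = _counts(pred, ref)
    return 0.0 if tp + fp == 0 else tp / (tp + fp)


def point_fitness(pred_mm, ref_mm) -> float:
    """Distance metric mapped to [0, 1]: 1 / (1 + squared error in cm^2)."""
    d2 = float(np.sum((np.asarray(pred_mm, float) - np.asarray(ref_mm, float)) ** 2))
    return 1.0 / (1.0 + d2 / 100.0)


def hausdorff_distance(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """Symmetric Hausdorff distance between two masks in mm (inf when either
    is empty).  Sensitive to stray disconnected regions."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if not a.any() or not b.any():
        return float("inf")
    dt_b = ndimage.distance_transform_edt(~b, sampling=spacing)
    dt_a = ndimage.distance_transform_edt(~a, sampling=spacing)
    return float(max(dt_b[a].max(), dt_a[b].max()))


_METRICS = {"dice": dice, "sensitivity": sensitivity, "specificity": specificity,
            "precision": precision, "recall": recall, "point-mse": None}


# ---------------------------------------------------------------------------
# tuning configuration

@dataclass(frozen=True)
class TuningCase:
    """One tuning example: an image plus reference masks/points per node.

    ``image`` may be an in-memory array or a loader callable returning
    ``(image, spacing)``; references map node name -> boolean mask or
    landmark voxel index.
    """
    image: object
    spacing: tuple[float, ...] | None = None
    references: dict = field(default_factory=dict)
    plugins: dict | None = None

    def load(self):
        if callable(self.image):
            return self.image()
        return np.asarray(self.image), self.spacing


@dataclass(frozen=True)
class FitnessSpec:
    """Per-node metric names and non-negative weights (normalized to 1)."""
    metrics: dict            # node -> metric name in _METRICS
    weights: dict | None = None

    def __post_init__(self):
        for node, metric in self.metrics.items():
            if metric not in _METRICS:
                raise ValueError(f"unknown metric {metric!r} for node {node!r}")
        w = self.weights or {n: 1.0 for n in self.metrics}
        if set(w) != set(self.metrics):
            raise ValueError("weights must cover exactly the metric nodes")
        if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
            raise ValueError("weights must be non-negative with a positive sum")
        total = sum(w.values())
        object.__setattr__(self, "weights", {n: v / total for n, v in w.items()})


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 30
    generations: int = 10
    elitism_count: int = 2
    crossover_prob: float = 0.8
    mutation_prob_per_bit: float | None = None     # default 1/chromosome-length
    tournament_size: int = 2
    seed: int = 0
    baseline_fitness: float | None = None          # e.g. hand-tuned reference

    def __post_init__(self):
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be < population_size")


# ---------------------------------------------------------------------------
# fitness

def _node_score(bb: Blackboard, node: str, metric: str, reference, spacing) -> float:
    el = bb.elements[node]
    if el.status != RECOGNIZED or el.selected is None:
        return 0.0
    if metric == "point-mse":
        sel = el.selected
        pred_idx = sel.point
        if pred_idx is None:
            pred_idx = ndimage.center_of_mass(sel.mask)
        pred_mm = [i * s for i, s in zip(pred_idx, spacing)]
        ref_mm = [i * s for i, s in zip(reference, spacing)]
        return point_fitness(pred_mm, ref_mm)
    if el.selected.mask is None:
        return 0.0
    return _METRICS[metric](el.selected.mask, reference)


def evaluate_fitness(chrom: Chromosome | str | None, net: SemanticNetwork,
                     cases: list[TuningCase], spec: FitnessSpec,
                     plugins: dict | None = None) -> float:
    """Weighted node metrics averaged over the tuning cases, in [0, 1].

    A node that is not recognized scores 0 on its metric; a think run that
    fails outright scores 0 for the whole case (degenerate parameter sets
    must not abort the optimization).
    """
    per_case = []
    for i, case in enumerate(cases):
        for node in spec.metrics:
            if node not in case.references:
                raise ValueError(f"case {i} has no reference for node {node!r}")
        image, spacing = case.load()
        try:
            bb = run_think(net, image, spacing, chromosome=chrom,
                           plugins=case.plugins or plugins)
        except Exception:
            per_case.append(0.0)
            continue
        total = 0.0
        for node, metric in spec.metrics.items():
            score = _node_score(bb, node, metric, case.references[node], spacing)
            total += spec.weights[node] * score
        per_case.append(total)
    return float(np.mean(per_case))


# ---------------------------------------------------------------------------
# distributor

def _sequential_backend(jobs):
    return {key: fn() for key, fn in jobs}


_BACKENDS = {"sequential": _sequential_backend}


def distribute(jobs, backend="sequential"):
    """Run ``(key, thunk)`` jobs through a backend; aggregation is a dict
    keyed by job and therefore independent of completion order.  A failing
    job is retried once, then recorded as fitness 0.
    """
    runner = _BACKENDS[backend] if isinstance(backend, str) else backend

    def guarded(fn):
        def run():
            for attempt in (1, 2):
                try:
                    return fn()
                except Exception:
                    if attempt == 2:
                        return 0.0
        return run

    return runner([(key, guarded(fn)) for key, fn in jobs])


# ---------------------------------------------------------------------------
# the genetic algorithm

def ga_optimize(net: SemanticNetwork, cases: list[TuningCase],
                spec: FitnessSpec, cfg: GAConfig | None = None,
                distributor="sequential", plugins: dict | None = None,
                initial_population: list[str] | None = None):
    """Seeded GA over the network's chromosome space.

    Returns ``(best Chromosome, specified network, trajectory DataFrame)``.
    Elites persist unchanged each generation, so best-so-far fitness is
    non-decreasing.  Identical seeds reproduce identical trajectories.
    """
    from .genome import apply_chromosome

    cfg = cfg or GAConfig()
    tunables = list_tunable_parameters(net)
    if not tunables:
        raise ValueError("nothing to optimize: the network has no tunable parameters")
    length = chromosome_span(net)
    p_mut = (cfg.mutation_prob_per_bit if cfg.mutation_prob_per_bit is not None
             else 1.0 / length)
    rng = np.random.default_rng(cfg.seed)

    if initial_population is not None:
        population = [Chromosome(b).bits for b in initial_population]
    else:
        population = [random_chromosome(length, rng).bits
                      for _ in range(cfg.population_size)]
    cache: dict[str, float] = {}

    def evaluate_all(bits_list):
        jobs = [(bits, (lambda b=bits: evaluate_fitness(b, net, cases, spec,
                                                        plugins=plugins)))
                for bits in dict.fromkeys(bits_list) if bits not in cache]
        cache.update(distribute(jobs, distributor))
        return [cache[b] for b in bits_list]

    best_bits, best_fit = None, -1.0
    rows = []
    for gen in range(cfg.generations):
        fits = evaluate_all(population)
        order = sorted(range(len(population)), key=lambda i: -fits[i])
        if fits[order[0]] > best_fit:
            best_fit, best_bits = fits[order[0]], population[order[0]]
        rows.append({"generation": gen,
                     "min_fitness": float(np.min(fits)),
                     "median_fitness": float(np.median(fits)),
                     "max_fitness": float(np.max(fits)),
                     "best_so_far": best_fit,
                     "best_bits": best_bits})
        if gen == cfg.generations - 1:
            break

        def tournament():
            picks = rng.integers(0, len(population), size=cfg.tournament_size)
            winner = max(picks, key=lambda i: fits[i])
            return population[winner]

        nxt = [population[i] for i in order[: cfg.elitism_count]]
        while len(nxt) < cfg.population_size:
            a, b = tournament(), tournament()
            if rng.random() < cfg.crossover_prob and length > 1:
                cut = int(rng.integers(1, length))
                a = a[:cut] + b[cut:]
            child = "".join(
                bit if rng.random() >= p_mut else ("1" if bit == "0" else "0")
                for bit in a)
            nxt.append(child)
        population = nxt

    best = Chromosome(best_bits)
    _, specified = apply_chromosome(net, best)
    trajectory = pd.DataFrame(rows)
    return best, specified, trajectory


def status_summary(trajectory: pd.DataFrame, path: str | Path | None = None,
                   baseline: float | None = None) -> tuple[pd.DataFrame, str]:
    """Per-generation fitness table (CSV-ready) plus a text report."""
    if trajectory.empty:
        raise ValueError("trajectory must contain at least one generation")
    table = trajectory.copy()
    lines = [f"generations: {len(table)}",
             f"final best fitness: {table['best_so_far'].iloc[-1]:.4f}",
             f"best chromosome: {table['best_bits'].iloc[-1]}"]
    if baseline is not None:
        above = table.index[table["best_so_far"] > baseline]
        if len(above):
            gen = int(table.loc[above[0], "generation"])
            lines.append(f"baseline {baseline} first exceeded at generation {gen}")
        else:
            lines.append(f"baseline {baseline} not exceeded")
    if path is not None:
        table.to_csv(path, index=False)
    return table, "\n".join(lines) + "\n"
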