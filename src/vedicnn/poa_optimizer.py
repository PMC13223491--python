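"""Pelican Optimization Algorithm (POA) for hyperparameter tuning.

Population metaheuristic modeled on pelican hunting: an exploration phase
("moving towards prey") pulls each candidate towards — or away from — a
randomly placed prey depending on the prey's fitness, and an exploitation
phase ("winging on the water surface") performs a local sweep whose radius
shrinks linearly to zero over the iterations.  Both phases accept a move
only if it improves fitness (greedy), so the best-so-far trace is monotone.

The module is generic over the fitness callable (lower is better) and ships
the standard sphere/Rastrigin benchmarks plus a DnCNN segmentation fitness
``1 − (w·DSC + (1−w)·IoU)`` evaluated by a short seeded training run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import dncnn_model as dm
from .metrics import confusion, scores

__all__ = [
    "Bounds", "Candidate", "POAConfig", "initialize", "exploration_step",
    "exploitation_step", "optimize", "sphere", "rastrigin",
    "HYPERPARAM_BOUNDS", "decode_candidate", "mask_fitness", "dncnn_fitness",
]


@dataclass(frozen=True)
class Bounds:
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("bounds must be 1-D vectors of equal length")
        if not np.all(lo < hi):
            raise ValueError("every lower bound must be below its upper bound")

    @property
    def m(self) -> int:
        return self.lower.size

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass
class Candidate:
    position: np.ndarray
    fitness: float


@dataclass(frozen=True)
class POAConfig:
    pop_size: int = 20
    iterations: int = 100
    seed: int = 0
    R: float = 0.2          # exploitation neighborhood constant

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("population size must be at least 2")
        if self.iterations < 1:
            raise ValueError("need at least one iteration")


def sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


def rastrigin(x: np.ndarray) -> float:
    return float(10 * x.size + np.sum(x * x - 10 * np.cos(2 * np.pi * x)))


def initialize(bounds: Bounds, cfg: POAConfig,
               rng: np.random.Generator | None = None) -> list[Candidate]:
    """Uniform seeded initialization: x_ij = l_j + rand_ij (u_j − l_j)."""
    rng = rng or np.random.default_rng(cfg.seed)
    pos = bounds.lower + rng.random((cfg.pop_size, bounds.m)) \
        * (bounds.upper - bounds.lower)
    return [Candidate(p, math.inf) for p in pos]


def _evaluate(c: Candidate, fitness) -> None:
    v = fitness(c.position)
    c.fitness = math.inf if (v is None or math.isnan(v)) else float(v)


def exploration_step(population: list[Candidate], prey: Candidate,
                     fitness, bounds: Bounds,
                     rng: np.random.Generator) -> None:
    """Moving towards prey: approach a better prey, retreat from a worse one;
    greedy acceptance keeps only improving moves, clamped to bounds."""
    m = bounds.m
    for c in population:
        r = rng.random(m)
        if prey.fitness < c.fitness:
            i_factor = rng.integers(1, 3)    # I in {1, 2}
            new = c.position + r * (prey.position - i_factor * c.position)
        else:
            new = c.position + r * (c.position - prey.position)
        new = bounds.clamp(new)
        v = fitness(new)
        if v is not None and not math.isnan(v) and v < c.fitness:
            c.position, c.fitness = new, float(v)


def exploitation_step(population: list[Candidate], t: int, T: int,
                      fitness, bounds: Bounds, rng: np.random.Generator,
                      R: float = 0.2) -> None:
    """Winging on the water surface: local sweep with radius R·(1 − t/T)
    around each candidate, shrinking to zero at the final iteration."""
    radius = R * (1.0 - t / T)
    m = bounds.m
    for c in population:
        new = bounds.clamp(c.position + radius * (2 * rng.random(m) - 1)
                           * c.position)
        v = fitness(new)
        if v is not None and not math.isnan(v) and v < c.fitness:
            c.position, c.fitness = new, float(v)


def optimize(fitness, bounds: Bounds, cfg: POAConfig,
             warm_starts: list[np.ndarray] | None = None
             ) -> tuple[Candidate, list[float]]:
    """Run POA; returns (best candidate, best-so-far fitness trace).

    ``warm_starts`` positions replace the first members of the random
    initial population — used to seed the search with a known default
    configuration so tuning can only match or improve on it.
    """
    rng = np.random.default_rng(cfg.seed)
    population = initialize(bounds, cfg, rng)
    if warm_starts:
        for i, w in enumerate(warm_starts[:len(population)]):
            population[i] = Candidate(bounds.clamp(np.asarray(w, float)),
                                      math.inf)
    for c in population:
        _evaluate(c, fitness)
    best = min(population, key=lambda c: c.fitness)
    best = Candidate(best.position.copy(), best.fitness)
    trace: list[float] = []
    for t in range(1, cfg.iterations + 1):
        # prey: a randomly selected population position for this iteration
        j = int(rng.integers(len(population)))
        prey = Candidate(population[j].position.copy(), population[j].fitness)
        exploration_step(population, prey, fitness, bounds, rng)
        exploitation_step(population, t, cfg.iterations, fitness, bounds,
                          rng, cfg.R)
        cur = min(population, key=lambda c: c.fitness)
        if cur.fitness < best.fitness:
            best = Candidate(cur.position.copy(), cur.fitness)
        trace.append(best.fitness)
    return best, trace


# ---------------------------------------------------------------------------
# DnCNN hyperparameter fitness
# ---------------------------------------------------------------------------

# search space: log10(learning rate), depth, width, mask threshold,
# post-processing disk radius
HYPERPARAM_BOUNDS = Bounds(
    lower=np.array([-4.0, 3.0, 8.0, 0.2, 0.0]),
    upper=np.array([-1.0, 9.0, 32.0, 0.8, 3.0]),
)

DEFAULT_HYPERPARAMS = np.array([math.log10(2e-3), 5.0, 16.0, 0.5, 1.0])


def decode_candidate(position: np.ndarray) -> dict:
    """Map a position vector to concrete hyperparameters (integers rounded
    to the nearest valid value)."""
    lr = 10.0 ** float(position[0])
    depth = int(np.clip(round(position[1]), 3, 9))
    width = int(np.clip(round(position[2]), 8, 32))
    threshold = float(np.clip(position[3], 0.2, 0.8))
    radius = int(np.clip(round(position[4]), 0, 3))
    return {"learning_rate": lr, "depth": depth, "width": width,
            "mask_threshold": threshold, "radius": radius}


def mask_fitness(pred_masks, true_masks, dsc_weight: float = 0.5) -> float:
    """Segmentation fitness 1 − (w·DSC + (1−w)·IoU) averaged over pairs.

    0 for a perfect segmenter; 1 when prediction and truth never overlap
    (undefined scores on empty-vs-empty pairs count as 0 overlap).
    """
    dscs, ious = [], []
    for pred, true in zip(pred_masks, true_masks):
        sc = scores(confusion(pred, true))
        dscs.append(0.0 if math.isnan(sc["dsc"]) else sc["dsc"])
        ious.append(0.0 if math.isnan(sc["iou"]) else sc["iou"])
    return 1.0 - (dsc_weight * float(np.mean(dscs))
                  + (1 - dsc_weight) * float(np.mean(ious)))


def dncnn_fitness(position: np.ndarray, phantom_train, phantom_val,
                  epochs: int = 8, seed: int = 0,
                  dsc_weight: float = 0.5) -> float:
    """Fitness 1 − (w·DSC + (1−w)·IoU) of a short seeded training run.

    Trains a segment-head DnCNN with the decoded hyperparameters on the
    training phantoms and scores the post-processed masks on the validation
    phantoms.  Lower is better; 0 is a perfect segmenter.
    """
    hp = decode_candidate(position)
    spec = dm.NetworkSpec(depth=hp["depth"], width=hp["width"],
                          head="segment")
    net = dm.build(spec, seed=seed)
    cfg = dm.TrainConfig(learning_rate=hp["learning_rate"], epochs=epochs,
                         batch_size=4, seed=seed,
                         mask_threshold=hp["mask_threshold"])
    try:
        dm.train(net, [(p.image, p.mask) for p in phantom_train], cfg)
    except RuntimeError:
        return float("nan")     # diverged: rejected by the optimizer
    preds = [dm.postprocess(
        dm.segment(net, p.image, hp["mask_threshold"]), hp["radius"])
        for p in phantom_val]
    return mask_fitness(preds, [p.mask for p in phantom_val], dsc_weight)
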