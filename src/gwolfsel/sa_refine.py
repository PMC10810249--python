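"""Simulated-annealing refinement of the alpha wolf.

At the end of each grey-wolf iteration the current alpha mask seeds a short
annealing pass.  Neighborhoods are produced by one of five order-permuting
binary operators chosen by roulette wheel — Swap, Insertion, Inversion,
R2L and R2R (rotate left/right by one).  All five conserve the number of
selected features, so the annealer explores *arrangements* of a fixed-size
selection; an optional bit-flip operator (off by default) lifts that
restriction.  Worse moves are accepted with the Boltzmann probability
exp(-delta_f / T) under a geometric cooling schedule, and the best mask seen
is returned (never worse than the input).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from gwolfsel.objective import FitnessValue

OPERATORS = ("swap", "insertion", "inversion", "r2l", "r2r")


@dataclass
class SAConfig:
    t0: float = 0.1
    cooling: float = 0.9
    t_final: float = 1e-3
    moves_per_temperature: int = 5
    operator_weights: dict[str, float] | None = None
    include_bitflip: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.t_final < self.t0:
            raise ValueError("require 0 < t_final < t0")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must lie in (0,1)")
        if self.moves_per_temperature < 1:
            raise ValueError("moves_per_temperature must be >= 1")
        ops = list(OPERATORS) + (["bitflip"] if self.include_bitflip else [])
        if self.operator_weights is None:
            self.operator_weights = {op: 1.0 for op in ops}
        unknown = set(self.operator_weights) - set(ops)
        if unknown:
            raise ValueError(f"unknown operators {sorted(unknown)}")
        w = np.array([self.operator_weights.get(op, 0.0) for op in ops])
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("operator weights must be non-negative, not all zero")
        self.operators = tuple(ops)

    def temperatures(self) -> list[float]:
        """Geometric ladder t0, t0*c, ... down to (and excluding below) t_final."""
        temps = []
        t = self.t0
        while t >= self.t_final:
            temps.append(t)
            t *= self.cooling
        return temps


def apply_operator(
    mask: np.ndarray, op: str, rng: np.random.Generator
) -> np.ndarray:
    """Apply one neighborhood operator; output has the same popcount
    (except ``bitflip``)."""
    mask = np.asarray(mask, dtype=np.int8)
    n = mask.shape[0]
    if n < 2:
        raise ValueError("mask must have length >= 2")
    out = mask.copy()
    if op == "swap":
        i, j = rng.choice(n, size=2, replace=False)
        out[i], out[j] = out[j], out[i]
    elif op == "insertion":
        i, j = rng.choice(n, size=2, replace=False)
        bit = out[i]
        out = np.delete(out, i)
        out = np.insert(out, j, bit)
    elif op == "inversion":
        i, j = np.sort(rng.choice(n, size=2, replace=False))
        out[i : j + 1] = out[i : j + 1][::-1]
    elif op == "r2l":
        out = np.roll(out, -1)
    elif op == "r2r":
        out = np.roll(out, 1)
    elif op == "bitflip":
        i = rng.integers(n)
        out[i] = 1 - out[i]
    else:
        raise ValueError(f"unknown operator {op!r}")
    return out


def roulette_select(
    weights: np.ndarray, rng: np.random.Generator, labels: tuple[str, ...] | None = None
) -> int | str:
    """Pick index (or label) i with probability w_i / sum(w)."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative roulette weight")
    total = w.sum()
    if total <= 0:
        raise ValueError("all roulette weights are zero")
    idx = int(np.searchsorted(np.cumsum(w) / total, rng.random(), side="right"))
    idx = min(idx, len(w) - 1)
    return labels[idx] if labels is not None else idx


def boltzmann_accept(
    delta_f: float, T: float, rng: np.random.Generator
) -> bool:
    """Accept better-or-equal moves outright, worse ones with exp(-df/T)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if delta_f <= 0:
        return True
    return rng.random() < np.exp(-delta_f / T)


def sa_refine(
    start: np.ndarray,
    fitness_fn: Callable[[np.ndarray], FitnessValue],
    cfg: SAConfig,
    rng: np.random.Generator,
    start_fitness: FitnessValue | None = None,
) -> tuple[np.ndarray, FitnessValue]:
    """Anneal from ``start`` and return the best (mask, fitness) seen.

    The incumbent-best is tracked separately from the annealing walk, so the
    returned mask is never worse than the input.
    """
    start = np.asarray(start, dtype=np.int8)
    weights = np.array(
        [cfg.operator_weights.get(op, 0.0) for op in cfg.operators], dtype=float
    )
    current = start.copy()
    current_fit = start_fitness if start_fitness is not None else fitness_fn(current)
    best, best_fit = current.copy(), current_fit
    for T in cfg.temperatures():
        for _ in range(cfg.moves_per_temperature):
            op = roulette_select(weights, rng, labels=cfg.operators)
            neighbor = apply_operator(current, op, rng)
            fv = fitness_fn(neighbor)
            delta = fv.fit - current_fit.fit
            if boltzmann_accept(delta, T, rng):
                current, current_fit = neighbor, fv
                if (fv.fit, fv.nf) < (best_fit.fit, best_fit.nf):
                    best, best_fit = neighbor.copy(), fv
    return best, best_fit
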