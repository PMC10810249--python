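"""Binary grey-wolf optimization over feature masks.

Wolves are binary vectors; the three best solutions (alpha, beta, delta)
guide every update.  Per dimension d and leader L:

    A = 2*a*r1 - a,  C = 2*r2,  D_L = |C * X_L - X_i|
    s_L = 1 / (1 + exp(-10 * (A * D_L - 0.5)))          (sigmoid transfer)
    bstep_L = [s_L >= r3]                               (binary step)
    X_L' = [X_L + bstep_L >= 1]                         (leader-anchored bit)

and the new bit is chosen uniformly among the three leader-anchored bits by
a stochastic crossover draw r4 (< 1/3 -> alpha's, < 2/3 -> beta's, else
delta's).  The distance-control scalar a decays linearly from 2 to 0 over
the run, trading exploration for exploitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from gwolfsel.objective import FitnessValue


@dataclass
class GWOConfig:
    n_wolves: int = 10
    t_max: int = 100
    init_density: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wolves < 3:
            raise ValueError("need at least 3 wolves (three leaders)")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if not 0 < self.init_density < 1:
            raise ValueError("init_density must lie in (0,1)")


def a_schedule(t: int, t_max: int) -> float:
    """Linear decay a = 2 - t * 2/t_max, from 2 at t=0 to 0 at t=t_max."""
    if not 0 <= t <= t_max:
        raise ValueError(f"iteration {t} outside [0, {t_max}]")
    return 2.0 - t * (2.0 / t_max)


@dataclass
class WolfUpdateDraws:
    """All random draws consumed by one position update, in draw order."""

    a: float
    r1: np.ndarray        # 3 x dim, one row per leader (alpha, beta, delta)
    r2: np.ndarray        # 3 x dim
    r3: np.ndarray        # dim, shared across the three binary steps
    r4: np.ndarray        # dim, crossover

    @classmethod
    def sample(
        cls, rng: np.random.Generator, dim: int, a: float
    ) -> "WolfUpdateDraws":
        r1 = np.empty((3, dim))
        r2 = np.empty((3, dim))
        for j in range(3):  # per-leader fresh draws, alpha first
            r1[j] = rng.random(dim)
            r2[j] = rng.random(dim)
        return cls(a=a, r1=r1, r2=r2, r3=rng.random(dim), r4=rng.random(dim))

    @property
    def A(self) -> np.ndarray:
        return 2.0 * self.a * self.r1 - self.a

    @property
    def C(self) -> np.ndarray:
        return 2.0 * self.r2


def update_wolf_position(
    wolf: np.ndarray,
    leaders: Sequence[np.ndarray],
    a: float,
    rng: np.random.Generator | None = None,
    draws: WolfUpdateDraws | None = None,
) -> np.ndarray:
    """One leader-guided binary position update (vectorized over dimensions).

    Either an ``rng`` (draws sampled internally) or a prepared ``draws``
    bundle must be supplied; the latter makes the update a deterministic
    function for verification against a step-by-step transcription.
    """
    wolf = np.asarray(wolf, dtype=np.int8)
    if len(leaders) != 3:
        raise ValueError("exactly three leaders required")
    L = np.vstack([np.asarray(ld, dtype=np.int8) for ld in leaders])
    if L.shape[1] != wolf.shape[0]:
        raise ValueError("mask length mismatch between wolf and leaders")
    if draws is None:
        if rng is None:
            raise ValueError("provide rng or draws")
        draws = WolfUpdateDraws.sample(rng, wolf.shape[0], a)
    A, C = draws.A, draws.C
    D = np.abs(C * L - wolf[None, :])
    s = 1.0 / (1.0 + np.exp(-10.0 * (A * D - 0.5)))
    bstep = (s >= draws.r3[None, :]).astype(np.int8)
    X = ((L + bstep) >= 1).astype(np.int8)  # leader-anchored candidate bits
    out = np.where(draws.r4 < 1.0 / 3.0, X[0], np.where(draws.r4 < 2.0 / 3.0, X[1], X[2]))
    return out.astype(np.int8)


@dataclass
class SelectionRun:
    """Result of one metaheuristic selection run."""

    algorithm: str
    best_mask: np.ndarray
    best_fitness: FitnessValue
    best_trace: list[float]
    seed: int
    config: dict = field(default_factory=dict)
    evaluation: object = None

    @property
    def nf(self) -> int:
        return int(self.best_mask.sum())


def _rank_key(fv: FitnessValue, index: int) -> tuple:
    # minimization; ties by fewer features, then wolf index
    return (fv.fit, fv.nf, index)


def bgwo_run(
    fitness_fn: Callable[[np.ndarray], FitnessValue],
    n_features: int,
    cfg: GWOConfig,
    leader_hook: Callable[[np.ndarray, FitnessValue], tuple[np.ndarray, FitnessValue]]
    | None = None,
    trace_log: list | None = None,
) -> SelectionRun:
    """Run the optimizer and return the best mask with its elitist trace.

    ``leader_hook`` (if given) may refine the alpha wolf at the end of each
    iteration; the refined mask replaces alpha only if not worse, so the
    recorded best-so-far trace stays non-increasing.
    """
    rng = np.random.default_rng(cfg.seed)
    positions = (rng.random((cfg.n_wolves, n_features)) < cfg.init_density).astype(
        np.int8
    )
    fitnesses = [fitness_fn(p) for p in positions]

    def ranked_indices() -> list[int]:
        return sorted(range(cfg.n_wolves), key=lambda i: _rank_key(fitnesses[i], i))

    order = ranked_indices()
    best_mask = positions[order[0]].copy()
    best_fit = fitnesses[order[0]]
    trace = [best_fit.fit]

    for t in range(1, cfg.t_max + 1):
        a = a_schedule(t, cfg.t_max)
        leaders = [positions[i].copy() for i in order[:3]]
        for i in range(cfg.n_wolves):
            positions[i] = update_wolf_position(positions[i], leaders, a, rng=rng)
            fitnesses[i] = fitness_fn(positions[i])
        order = ranked_indices()
        if leader_hook is not None:
            alpha_i = order[0]
            new_mask, new_fit = leader_hook(positions[alpha_i].copy(), fitnesses[alpha_i])
            if _rank_key(new_fit, alpha_i) <= _rank_key(fitnesses[alpha_i], alpha_i):
                positions[alpha_i] = np.asarray(new_mask, dtype=np.int8)
                fitnesses[alpha_i] = new_fit
                order = ranked_indices()
        cand = fitnesses[order[0]]
        if _rank_key(cand, 0) < _rank_key(best_fit, 0):
            best_mask = positions[order[0]].copy()
            best_fit = cand
        trace.append(min(trace[-1], best_fit.fit))
        if trace_log is not None:
            trace_log.append(
                {
                    "iteration": t,
                    "a": a,
                    "best_fit": best_fit.fit,
                    "best_nf": best_fit.nf,
                }
            )

    return SelectionRun(
        algorithm="bgwo",
        best_mask=best_mask,
        best_fitness=best_fit,
        best_trace=trace,
        seed=cfg.seed,
        config={
            "n_wolves": cfg.n_wolves,
            "t_max": cfg.t_max,
            "init_density": cfg.init_density,
        },
    )
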