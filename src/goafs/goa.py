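"""Binary grasshopper-style evolutionary search over feature masks.

The continuous grasshopper swarm model drives individuals by a social
force s(r) = f·exp(−r/l) − exp(−r) (repulsive at short range,
attractive at long range, zero at the "comfort distance"), a gravity
term and a wind term, with exploration shrinking over iterations via
the linear schedules a(t) and a2(t) and the stochastic coefficients
A, C and l.

For subset selection the swarm lives on bit vectors, where the force
model has no direct geometry.  The driver used here is best-guided
mutation: each individual is crossed toward a guide — the best-so-far
mask when the drawn |A| < 1 (exploitation), a random population member
when |A| ≥ 1 (exploration) — with disagreeing bits resampled
Bernoulli(0.5), then passes through the random-subset mutation
operator whose intensity is the intersection probability scaled by a
linearly interpolated per-iteration weight.  Elitism keeps the
best-so-far mask in the population, so the best-fitness history is
non-increasing.  All schedule and coefficient quantities are computed
exactly as in the continuous model and logged per iteration, so the
mapping between the two layers is auditable.

Fitness is minimized (the "least amount of error" contract).  Ties are
broken toward fewer selected features, then lexicographic bit order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .mask import FeatureMask

__all__ = [
    "GoaError",
    "SocialForceParams",
    "GrasshopperForces",
    "CoefficientDraw",
    "GoaParams",
    "GoaState",
    "social_force",
    "comfort_distance",
    "schedule_a",
    "schedule_a2",
    "draw_coefficients",
    "mutate",
    "initialize_population",
    "run",
]


class GoaError(RuntimeError):
    pass


@dataclass(frozen=True)
class SocialForceParams:
    """Attraction intensity f and length scale l of the social force.

    l > 1 guarantees a finite positive comfort distance
    r* = −l·ln(f)/(l − 1) for 0 < f < 1.  The defaults f = 0.5,
    l = 1.5 are the values customary for this swarm model.
    """

    f: float = 0.5
    l: float = 1.5

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("f must be positive")
        if self.l <= 1:
            raise ValueError("l must exceed 1")


@dataclass(frozen=True)
class GrasshopperForces:
    """Force decomposition of one individual: social + gravity + wind.

    Gravity and wind default to zero vectors; the swarm model gives
    them no operative formula here and they are retained for
    completeness of the decomposition.
    """

    social: tuple[float, ...]
    gravity: tuple[float, ...] = ()
    wind: tuple[float, ...] = ()

    def total(self) -> np.ndarray:
        s = np.asarray(self.social, dtype=float)
        g = np.asarray(self.gravity, dtype=float) if self.gravity else np.zeros_like(s)
        w = np.asarray(self.wind, dtype=float) if self.wind else np.zeros_like(s)
        return s + g + w


def social_force(r: float | np.ndarray, params: SocialForceParams = SocialForceParams()) -> float | np.ndarray:
    """s(r) = f·exp(−r/l) − exp(−r); repulsive (negative) at r = 0."""
    arr = np.asarray(r, dtype=float)
    if (arr < 0).any():
        raise ValueError("distance r must be non-negative")
    out = params.f * np.exp(-arr / params.l) - np.exp(-arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def comfort_distance(params: SocialForceParams = SocialForceParams()) -> float:
    """Positive root of s(r): the distance of zero net social force."""
    if not 0 < params.f < 1:
        raise ValueError("a positive root requires 0 < f < 1")
    return -params.l * math.log(params.f) / (params.l - 1)


def schedule_a(t: int, max_iter: int) -> float:
    """Linear exploration parameter: 2 at t = 0 down to 0 at t = max_iter."""
    if not 0 <= t <= max_iter:
        raise ValueError(f"iteration {t} outside 0..{max_iter}")
    return 2.0 - t * (2.0 / max_iter)


def schedule_a2(t: int, max_iter: int) -> float:
    """Linear shrink parameter: −1 at t = 0 down to −2 at t = max_iter."""
    if not 0 <= t <= max_iter:
        raise ValueError(f"iteration {t} outside 0..{max_iter}")
    return -1.0 + t * (-1.0 / max_iter)


@dataclass(frozen=True)
class CoefficientDraw:
    """One draw of the stochastic coefficients at iteration t.

    A = 2·a·r1 − a ∈ [−a, a]; C = 2·r2 ∈ [0, 2];
    l_coef = (a2 − 1)·u + 1 ∈ [a2, 1] (a2 ≤ 0 here, so the interval is
    ordered [a2, 1] with u ~ U[0, 1] mapping 1 → a2).
    """

    a: float
    a2: float
    A: float
    C: float
    l_coef: float
    r1: float
    r2: float


def draw_coefficients(a: float, a2: float, rng: np.random.Generator) -> CoefficientDraw:
    r1 = float(rng.random())
    r2 = float(rng.random())
    u = float(rng.random())
    return CoefficientDraw(
        a=a, a2=a2,
        A=2.0 * a * r1 - a,
        C=2.0 * r2,
        l_coef=(a2 - 1.0) * u + 1.0,
        r1=r1, r2=r2,
    )


def _repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not bits.any():
        bits = bits.copy()
        bits[rng.integers(bits.size)] = True
    return bits


def mutate(mask: FeatureMask, p_select: float, rng: np.random.Generator) -> FeatureMask:
    """Random-subset mutation: each position chosen independently with
    probability ``p_select`` is redrawn Bernoulli(0.5); the rest are
    copied.  An all-zero outcome is repaired by setting one uniformly
    chosen bit."""
    if not 0.0 <= p_select <= 1.0:
        raise ValueError("p_select must lie in [0, 1]")
    bits = mask.asarray().copy()
    if p_select > 0.0:
        chosen = rng.random(bits.size) < p_select
        k = int(chosen.sum())
        if k:
            bits[chosen] = rng.random(k) < 0.5
    return FeatureMask.from_array(_repair(bits, rng))


def _crossover(bits: np.ndarray, guide: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Pull toward the guide: agreeing bits kept, disagreeing bits
    resampled Bernoulli(0.5)."""
    out = bits.copy()
    disagree = bits != guide
    k = int(disagree.sum())
    if k:
        out[disagree] = rng.random(k) < 0.5
    return out


def initialize_population(pop_size: int, d: int, rng: np.random.Generator) -> list[FeatureMask]:
    """i.i.d. Bernoulli(0.5) bit vectors, each repaired to non-empty."""
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    if d < 1:
        raise ValueError("d must be >= 1")
    pop = []
    for _ in range(pop_size):
        bits = rng.random(d) < 0.5
        pop.append(FeatureMask.from_array(_repair(bits, rng)))
    return pop


@dataclass(frozen=True)
class GoaParams:
    """Search hyperparameters.

    ``intersection_prob`` is the base rate of the random-subset
    mutation; ``w_init``/``w_final`` linearly interpolate a
    per-iteration weight that scales it, so mutation intensity ramps
    from intersection_prob·w_init to intersection_prob·w_final across
    the run.
    """

    pop_size: int = 50
    max_iter: int = 100
    intersection_prob: float = 0.5
    w_init: float = 0.35
    w_final: float = 0.95
    force: SocialForceParams = field(default_factory=SocialForceParams)
    seed: int = 0
    d: int = 13

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 <= self.intersection_prob <= 1.0:
            raise ValueError("intersection_prob must lie in [0, 1]")
        if self.w_init > self.w_final:
            raise ValueError("w_init must not exceed w_final")


@dataclass
class GoaState:
    """Final search state: population, best-so-far and the fitness history."""

    population: list[FeatureMask]
    fitness: list[float]
    best_mask: FeatureMask
    best_fitness: float
    t: int
    history: list[float]
    trace: pd.DataFrame | None = None

    def write_trace(self, path: str | Path) -> None:
        if self.trace is None:
            raise ValueError("run() was called without trace collection")
        self.trace.to_csv(path, index=False)


def _key(fitness: float, mask: FeatureMask) -> tuple:
    # minimization; ties -> fewer features, then lexicographic bits
    return (fitness, mask.size, mask.bits)


def run(
    params: GoaParams,
    fitness_fn: Callable[[FeatureMask], float],
    collect_trace: bool = True,
) -> GoaState:
    """Run the binary search loop; ``fitness_fn`` is minimized.

    Deterministic given ``params.seed``; every evaluated mask is
    non-empty; the returned history (best fitness per iteration,
    including iteration 0) is non-increasing by elitism.
    """
    rng = np.random.default_rng(params.seed)
    d = params.d

    def evaluate(mask: FeatureMask, t: int) -> float:
        try:
            return float(fitness_fn(mask))
        except Exception as exc:  # pragma: no cover - defensive context
            raise GoaError(
                f"fitness evaluation failed at iteration {t} for mask "
                f"{mask.bitstring}: {exc}"
            ) from exc

    population = initialize_population(params.pop_size, d, rng)
    fitness = [evaluate(m, 0) for m in population]
    best_i = min(range(len(population)), key=lambda i: _key(fitness[i], population[i]))
    best_mask, best_fit = population[best_i], fitness[best_i]
    history = [best_fit]
    rows = []

    for t in range(1, params.max_iter + 1):
        a = schedule_a(t, params.max_iter)
        a2 = schedule_a2(t, params.max_iter)
        w_t = params.w_init + (params.w_final - params.w_init) * t / params.max_iter
        p_t = params.intersection_prob * w_t

        draws: list[CoefficientDraw] = []
        new_pop: list[FeatureMask] = []
        for i, mask in enumerate(population):
            cd = draw_coefficients(a, a2, rng)
            draws.append(cd)
            if abs(cd.A) < 1.0:
                guide = best_mask
            else:
                guide = population[int(rng.integers(params.pop_size))]
            base = _crossover(mask.asarray(), guide.asarray(), rng)
            cand = mutate(FeatureMask.from_array(_repair(base, rng)), p_t, rng)
            new_pop.append(cand)

        new_fit = [evaluate(m, t) for m in new_pop]
        # elitism: the incumbent best always survives
        worst_i = max(range(len(new_pop)), key=lambda i: _key(new_fit[i], new_pop[i]))
        if _key(best_fit, best_mask) < min(
            _key(new_fit[i], new_pop[i]) for i in range(len(new_pop))
        ):
            new_pop[worst_i], new_fit[worst_i] = best_mask, best_fit
        population, fitness = new_pop, new_fit
        cand_i = min(range(len(population)), key=lambda i: _key(fitness[i], population[i]))
        if _key(fitness[cand_i], population[cand_i]) < _key(best_fit, best_mask):
            best_mask, best_fit = population[cand_i], fitness[cand_i]
        history.append(best_fit)

        if collect_trace:
            A_vals = np.array([c.A for c in draws])
            rows.append({
                "t": t,
                "a": a,
                "a2": a2,
                "w": w_t,
                "p_select": p_t,
                "mean_abs_A": float(np.abs(A_vals).mean()),
                "mean_C": float(np.mean([c.C for c in draws])),
                "mean_l_coef": float(np.mean([c.l_coef for c in draws])),
                "best_fitness": best_fit,
                "best_mask": best_mask.bitstring,
            })

    trace = pd.DataFrame.from_records(rows) if collect_trace else None
    return GoaState(
        population=population,
        fitness=fitness,
        best_mask=best_mask,
        best_fitness=best_fit,
        t=params.max_iter,
        history=history,
        trace=trace,
    )
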