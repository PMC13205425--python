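"""Differential Evolution (DE/best/1/bin) over Gabor-bank decision vectors.

A candidate descriptor is a flat real vector of length 6*Nf holding, per
filter, the block (m, sigma, theta, lam, gamma, psi).  DE runs entirely in
continuous space; the integer window size m is produced only at decode time by
half-away-from-zero rounding.  The scheme is:

  mutation   V = best + F * (a - b)                 (donor from current best)
  crossover  binomial with rate CR and a forced coordinate j_rand
  repair     out-of-bound coordinates reflected back via the modulus of the
             coordinate's range (truncated-remainder convention)
  selection  greedy: the trial replaces its target iff strictly better

One generator drives a whole run and its draw order is fixed (per target, in
index order: the a/b pair, then j_rand, then the CR uniforms), so a run is
replayed exactly from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .gabor import PARAM_DOMAINS, PARAM_ORDER, GaborBank, GaborParams

__all__ = [
    "Bounds",
    "DEConfig",
    "Candidate",
    "OptimizationResult",
    "default_bounds",
    "init_population",
    "mutate_best1",
    "crossover_bin",
    "repair_bounds",
    "select_greedy",
    "decode",
    "encode",
    "run_optimization",
]


@dataclass(frozen=True)
class Bounds:
    """Per-coordinate lower/upper limits of the decision vector."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if not np.all(lower < upper):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dim(self) -> int:
        return self.lower.size


def default_bounds(n_filters: int = 4) -> Bounds:
    """Repeat the six per-parameter domains for each filter in the bank."""
    if n_filters < 1:
        raise ValueError("need at least one filter")
    lower = np.tile([PARAM_DOMAINS[k][0] for k in PARAM_ORDER], n_filters)
    upper = np.tile([PARAM_DOMAINS[k][1] for k in PARAM_ORDER], n_filters)
    return Bounds(lower, upper)


@dataclass(frozen=True)
class DEConfig:
    population_size: int = 30
    scale_factor: float = 0.8
    crossover_rate: float = 0.9
    max_iterations: int = 30
    error_threshold: float = 1e-6
    n_filters: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError(
                "DE/best/1 needs a population of at least 4 "
                "(best plus two distinct others plus the target)"
            )
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class Candidate:
    vector: np.ndarray
    fitness: float | None = None


@dataclass
class OptimizationResult:
    best_vector: np.ndarray
    best_fitness: float
    best_bank: GaborBank
    history: list[dict]          # per generation: generation, best, mean, std
    seed: int
    termination_reason: str      # "threshold" | "max_iterations"
    n_evaluations: int

    def to_dict(self) -> dict:
        return {
            "best_vector": self.best_vector.tolist(),
            "best_fitness": self.best_fitness,
            "best_bank": [p.to_dict() for p in self.best_bank],
            "history": self.history,
            "seed": self.seed,
            "termination_reason": self.termination_reason,
            "n_evaluations": self.n_evaluations,
        }


def init_population(cfg: DEConfig, bounds: Bounds, rng: np.random.Generator) -> np.ndarray:
    """N vectors drawn coordinate-wise uniformly from [lower, upper]."""
    return rng.uniform(
        bounds.lower, bounds.upper, size=(cfg.population_size, bounds.dim)
    )


def mutate_best1(best: np.ndarray, a: np.ndarray, b: np.ndarray, scale_factor: float) -> np.ndarray:
    return best + scale_factor * (a - b)


def crossover_bin(target: np.ndarray, donor: np.ndarray, crossover_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Binomial crossover; the forced coordinate j_rand guarantees at least one
    donor coordinate in every trial."""
    if target.shape != donor.shape:
        raise ValueError("target and donor must have equal length")
    j_rand = int(rng.integers(target.size))
    take_donor = rng.random(target.size) <= crossover_rate
    take_donor[j_rand] = True
    return np.where(take_donor, donor, target)


def repair_bounds(v: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Reflect out-of-bound coordinates back inside via the range modulus.

    Below the lower bound: U - |v mod (U-L)|; above the upper bound:
    L + |v mod (U-L)|, with the truncated (C-style) remainder, so e.g.
    -0.5 on [0, pi] folds to pi - 0.5.  In-range values pass through, and the
    repaired vector is always in range, making the operation idempotent.
    """
    v = np.asarray(v, dtype=float)
    span = bounds.upper - bounds.lower
    folded = np.abs(np.fmod(v, span))
    out = np.where(v < bounds.lower, bounds.upper - folded, v)
    out = np.where(v > bounds.upper, bounds.lower + folded, out)
    return out


def select_greedy(target: Candidate, trial: Candidate) -> Candidate:
    """Keep the trial iff strictly better; ties retain the target."""
    if target.fitness is None or trial.fitness is None:
        raise ValueError("both candidates must have evaluated fitness")
    return trial if trial.fitness < target.fitness else target


def decode(v: Sequence[float]) -> GaborBank:
    """Decision vector -> bank: blocks of six in the order (m, sigma, theta,
    lam, gamma, psi); m rounded half-away-from-zero and clamped to [1, 20]."""
    v = np.asarray(v, dtype=float)
    if v.size % 6 != 0 or v.size == 0:
        raise ValueError(f"decision vector length {v.size} is not a multiple of 6")
    filters = []
    for block in v.reshape(-1, 6):
        m_raw, sigma, theta, lam, gamma, psi = block
        m = int(math.floor(abs(m_raw) + 0.5)) * (1 if m_raw >= 0 else -1)
        m = min(max(m, 1), 20)
        filters.append(GaborParams(m=m, sigma=sigma, theta=theta, lam=lam,
                                   gamma=gamma, psi=psi))
    return GaborBank(tuple(filters))


def encode(bank: GaborBank) -> np.ndarray:
    """Bank -> flat decision vector; inverse of :func:`decode` on integer-m
    vectors."""
    return np.array(
        [getattr(p, name) for p in bank for name in PARAM_ORDER], dtype=float
    )


def run_optimization(cfg: DEConfig, fitness_fn: Callable[[np.ndarray], float],
                     bounds: Bounds | None = None) -> OptimizationResult:
    """Full DE/best/1/bin run; stops at the error threshold or iteration cap."""
    if bounds is None:
        bounds = default_bounds(cfg.n_filters)
    rng = np.random.default_rng(cfg.seed)
    pop = init_population(cfg, bounds, rng)
    n = cfg.population_size

    def _eval(vec: np.ndarray, generation: int, index: int) -> float:
        try:
            return float(fitness_fn(vec))
        except Exception as exc:
            raise RuntimeError(
                f"fitness evaluation failed at generation {generation}, "
                f"candidate {index}"
            ) from exc

    fits = np.array([_eval(pop[i], 0, i) for i in range(n)])
    n_evals = n
    history = [_generation_stats(0, fits)]

    reason = "max_iterations"
    if fits.min() <= cfg.error_threshold:
        reason = "threshold"
    else:
        for gen in range(1, cfg.max_iterations + 1):
            best_idx = int(np.argmin(fits))
            for i in range(n):
                pool = np.array([j for j in range(n) if j != i and j != best_idx])
                a, b = rng.choice(pool, size=2, replace=False)
                donor = mutate_best1(pop[best_idx], pop[a], pop[b], cfg.scale_factor)
                trial = repair_bounds(crossover_bin(pop[i], donor, cfg.crossover_rate, rng), bounds)
                trial_fit = _eval(trial, gen, i)
                n_evals += 1
                if trial_fit < fits[i]:
                    pop[i] = trial
                    fits[i] = trial_fit
            history.append(_generation_stats(gen, fits))
            if fits.min() <= cfg.error_threshold:
                reason = "threshold"
                break

    best_idx = int(np.argmin(fits))
    best_vec = pop[best_idx].copy()
    return OptimizationResult(
        best_vector=best_vec,
        best_fitness=float(fits[best_idx]),
        best_bank=decode(best_vec),
        history=history,
        seed=cfg.seed,
        termination_reason=reason,
        n_evaluations=n_evals,
    )


def _generation_stats(generation: int, fits: np.ndarray) -> dict:
    return {
        "generation": generation,
        "best": float(fits.min()),
        "mean": float(fits.mean()),
        "std": float(fits.std(ddof=0)),
    }
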