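"""Population-level experiments: coding range, robustness, and asymptotics.

The coding range of an M-module grid code is ``L_max = (c_A/delta)^{M-1}``,
exponential in the number of modules.  This module asks how the base of that
exponential behaves when the grid scales are not tuned: random geometric
progressions, perturbed progressions, and fully random scale sets drawn from
a bounded interval.  It also contains a Monte-Carlo check of the asymptotic
statement that for i.i.d. random scales the code stays unambiguous up to
``(zeta/delta)^{M-1}`` with failure probability of order ``(2 zeta)^M``, and
the closed-form information-rate comparisons between equal-size and
geometrically shrinking module populations.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import NoiseModel, ScaleSystem, circ_norm, first_ambiguous_integer
from .diophantine import CHatEstimate, c_hat_window, records_until

__all__ = [
    "ScaleSampler",
    "RobustnessResult",
    "MonteCarloAsymptotic",
    "sample_scale_systems",
    "coding_range",
    "robustness_experiment",
    "montecarlo_unambiguity",
    "information_rate",
]


@dataclass(frozen=True)
class ScaleSampler:
    """Random generator of scale systems.

    Modes: ``geometric`` draws a single ratio alpha from ``alpha_range`` and
    returns ``{alpha^i}``; ``perturbed_geometric`` multiplies each term by
    ``1 + eps_i`` with eps_i uniform on ``[-perturbation, perturbation]``;
    ``iid_uniform`` draws all M-1 upper scales independently from
    ``alpha_range`` (sorted, with alpha_0 = 1 prepended).
    """

    mode: str = "geometric"
    alpha_range: tuple = (1.0, 2.0)
    M: int = 10
    perturbation: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("geometric", "perturbed_geometric", "iid_uniform"):
            raise ValueError(f"unknown sampler mode {self.mode!r}")
        lo, hi = self.alpha_range
        if not 1.0 <= lo < hi:
            raise ValueError("alpha_range must be a nondegenerate interval in (1, inf)")
        if self.perturbation < 0:
            raise ValueError("perturbation must be nonnegative")
        if self.M < 2:
            raise ValueError("M must be at least 2")


@dataclass(frozen=True)
class RobustnessResult:
    """Per-system capacity estimates under a sampler, with summary moments."""

    c_values: tuple
    mean: float
    cv: float
    sampler: ScaleSampler
    delta_window: tuple
    failures: int = 0

    @property
    def median(self) -> float:
        return float(np.median(self.c_values))

    def to_json(self) -> str:
        return json.dumps({
            "mean": self.mean, "cv": self.cv, "median": self.median,
            "count": len(self.c_values), "failures": self.failures,
            "delta_window": list(self.delta_window),
            "sampler": {"mode": self.sampler.mode, "M": self.sampler.M,
                        "alpha_range": list(self.sampler.alpha_range),
                        "perturbation": self.sampler.perturbation,
                        "seed": self.sampler.seed},
            "c_values": list(self.c_values),
        })


@dataclass(frozen=True)
class MonteCarloAsymptotic:
    """Configuration of the random-scale unambiguity experiment."""

    M: int
    delta: float
    zeta: float
    alpha_max: float = 2.0
    trials: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.delta < 0.5:
            raise ValueError("delta must lie in (0, 0.5)")
        if not self.delta < self.zeta < 0.5:
            raise ValueError("need delta < zeta < 0.5")
        if self.alpha_max <= (1 + self.delta) / (1 - self.delta):
            raise ValueError("alpha_max must exceed (1+delta)/(1-delta)")
        if self.trials < 1:
            raise ValueError("trials must be positive")

    @property
    def x_max(self) -> float:
        return (self.zeta / self.delta) ** (self.M - 1)


def sample_scale_systems(sampler: ScaleSampler, count: int) -> list[ScaleSystem]:
    """Seeded, reproducible draws of ``count`` scale systems."""
    lo, hi = sampler.alpha_range
    out = []
    for index in range(count):
        # one child generator per system: modes that consume different
        # amounts of randomness still agree draw-by-draw (and
        # perturbation=0 reduces exactly to the geometric mode)
        rng = np.random.default_rng([sampler.seed, index])
        if sampler.mode == "geometric":
            a = rng.uniform(lo, hi)
            scales = a ** np.arange(sampler.M)
        elif sampler.mode == "perturbed_geometric":
            a = rng.uniform(lo, hi)
            eps = rng.uniform(-sampler.perturbation, sampler.perturbation, sampler.M)
            scales = (1.0 + eps) * a ** np.arange(sampler.M)
            scales = np.sort(scales / scales[0])
            scales[0] = 1.0
        else:  # iid_uniform
            upper = np.sort(rng.uniform(lo, hi, sampler.M - 1))
            scales = np.concatenate([[1.0], upper])
        out.append(ScaleSystem(tuple(float(s) for s in scales)))
    return out


def coding_range(system: ScaleSystem, noise: NoiseModel,
                 backend: str = "scan", l_cap: int = 10**6) -> int:
    """Largest integer distance below the first ambiguity, ``L_max``.

    ``scan`` walks integers directly (first ambiguous integer minus one);
    ``lattice`` reads the first record with gap below delta off the record
    sweep.  The two agree wherever both are computable.
    """
    if backend == "scan":
        first = first_ambiguous_integer(system, noise, l_cap=l_cap)
        if first is None:
            raise RuntimeError(f"no ambiguity up to the scan cap {l_cap}; L_max >= {l_cap}")
        return first - 1
    if backend == "lattice":
        records = records_until(system, noise.delta, backend="lattice")
        first = next(r.l for r in records if r.gap < noise.delta)
        return first - 1
    raise ValueError(f"unknown backend {backend!r}")


def robustness_experiment(sampler: ScaleSampler, count: int,
                          delta_window: tuple = (0.05, 0.2),
                          backend: str = "auto") -> RobustnessResult:
    """Distribution of the window capacity estimate over random scale systems.

    Per-system failures (estimator caps) are recorded, not fatal.  The
    headline observables are the mean and the coefficient of variation: with
    more modules the mean rises toward the ceiling 0.5 while the CV falls,
    the signature of robustness to the choice of scales.
    """
    if count < 10:
        raise ValueError("count must be at least 10 for meaningful moments")
    systems = sample_scale_systems(sampler, count)
    values, failures = [], 0
    for system in systems:
        try:
            est = c_hat_window(system, delta_window[0], delta_window[1], backend=backend)
            values.append(est.value)
        except RuntimeError:
            failures += 1
    arr = np.asarray(values)
    mean = float(arr.mean())
    cv = float(arr.std(ddof=1) / mean) if mean > 0 else math.inf
    return RobustnessResult(c_values=tuple(values), mean=mean, cv=cv,
                            sampler=sampler, delta_window=tuple(delta_window),
                            failures=failures)


def montecarlo_unambiguity(cfg: MonteCarloAsymptotic) -> dict:
    """Fraction of random-scale systems unambiguous up to ``(zeta/delta)^{M-1}``.

    Each trial draws M scales i.i.d. uniform on ``[1, alpha_max]`` and tests
    every integer distance ``l <= X_max`` for simultaneous interference
    (``||l/alpha_i|| < delta`` for all modules).  Returns the empirical
    probability with its binomial standard error; the theory puts the failure
    probability at order ``(2 zeta)^M``.
    """
    rng = np.random.default_rng(cfg.seed)
    x_max = int(cfg.x_max)
    if x_max < 1:
        return {"p_unambiguous": 1.0, "se": 0.0, "x_max": x_max,
                "trials": cfg.trials, "failure_order": (2 * cfg.zeta) ** cfg.M}
    ls = np.arange(1, x_max + 1, dtype=float)
    failures = 0
    for _ in range(cfg.trials):
        alphas = rng.uniform(1.0, cfg.alpha_max, cfg.M)
        interfere = np.ones(x_max, dtype=bool)
        for a in alphas:
            interfere &= circ_norm(ls / a) < cfg.delta
            if not interfere.any():
                break
        failures += bool(interfere.any())
    p = 1.0 - failures / cfg.trials
    se = math.sqrt(max(p * (1 - p), 1e-12) / cfg.trials)
    return {"p_unambiguous": p, "se": se, "x_max": x_max,
            "trials": cfg.trials, "failure_order": (2 * cfg.zeta) ** cfg.M}


def information_rate(N: float, r_bar: float, c: float, delta: float,
                     M: int, mode: str = "equal", alpha: float | None = None,
                     n0: float | None = None) -> float:
    """Information rate (bits conveyed per spike, up to one fixed constant).

    ``equal`` mode: all modules hold N neurons, rate ∝ log(c/delta)/(r_bar N)
    — independent of M.  ``geometric`` mode: module populations shrink as
    ``n0/alpha^{2i}`` so the total stays ``n0 alpha^2/(alpha^2-1)`` and the
    rate ∝ M (alpha^2-1)/(n0 alpha^2 r_bar) * log(c/delta).  Normalised so
    the equal-mode rate equals 1 at c/delta = e and r_bar*N = 1.  Raises if
    c <= delta, where the modulo-arithmetic code stops being favoured.
    """
    if min(N, r_bar, c, delta) <= 0:
        raise ValueError("all parameters must be positive")
    if c <= delta:
        raise ValueError("c <= delta: coding range below one period, MA code not favoured")
    log_term = math.log(c / delta)
    if mode == "equal":
        return log_term / (r_bar * N)
    if mode == "geometric":
        if alpha is None or n0 is None:
            raise ValueError("geometric mode needs alpha and n0")
        if alpha <= 1:
            raise ValueError("alpha must exceed 1")
        return M * (alpha**2 - 1) / (n0 * alpha**2 * r_bar) * log_term
    raise ValueError(f"unknown mode {mode!r}")


def geometric_population(n0: float, alpha: float, M: int) -> float:
    """Total neuron count of a geometric code, ``sum n0/alpha^{2i} -> n0 a^2/(a^2-1)``."""
    return float(sum(n0 / alpha ** (2 * i) for i in range(M + 1)))


def write_experiment_csv(result: RobustnessResult, path) -> None:
    """One row per sampled system."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "c_hat"])
        for i, v in enumerate(result.c_values):
            w.writerow([i, repr(v)])
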