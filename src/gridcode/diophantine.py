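"""Brute-force Diophantine interference statistics and capacity-constant estimators.

Interference of an M-module grid code at integer distance ``l`` is measured by
the smallest achievable maximum pairwise gap

    g(l) = min_{K, k_0 = l} max_{i<j} |k_i a_i - k_j a_j| / (a_i + a_j),

whose running minima ("record lows") determine how far the code remains
unambiguous at a given noise level.  The scaled statistic
``eps_hat(l) = g(l) * l^{1/(M-1)}`` removes the universal decay rate so that
its liminf is the capacity constant ``c_A``: the coding range is
``L_max = (c_A / delta)^{M-1}``.  Two practical estimators of ``c_A`` are
provided — the record-window estimator and the scan of ``delta * L_max``
over a noise grid — together with record scans and small number-theoretic
diagnostics (Hurwitz-bound counts).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import sympy as sp

from .core import NoiseModel, ScaleSystem, circ_norm, min_max_gap, pairwise_gap, parse_scale

__all__ = [
    "InterferenceRecord",
    "CHatEstimate",
    "eps_two",
    "record_lows_two",
    "eps_hat",
    "record_lows_M",
    "records_until",
    "c_hat_window",
    "c_hat_from_lmax_scan",
    "geometric_delta_grid",
    "hurwitz_deficit",
    "write_records_csv",
]

#: brute-force scans beyond this distance should use the lattice backend
BRUTE_FORCE_CAP = 10**7

#: minimum relative improvement for a new record low; improvements below this
#: are numerically indistinguishable ties and, per the first-l tie-break,
#: not records (keeps the brute-force and lattice record sequences identical)
RECORD_RTOL = 1e-9


@dataclass(frozen=True)
class InterferenceRecord:
    """A record-low interference event at integer distance ``l``.

    ``gap`` is the minimal max pairwise normalised gap at ``l`` (witnessed by
    the integer multiples ``K``, with ``k_0 = l``) and ``scaled`` is
    ``gap * l^{1/(M-1)}``, the statistic whose records estimate ``c_A``.
    """

    l: int
    K: tuple
    gap: float
    scaled: float

    def __post_init__(self):
        if self.l < 1 or self.gap < 0 or self.scaled < 0:
            raise ValueError("invalid interference record")


@dataclass(frozen=True)
class CHatEstimate:
    """An estimate of the capacity constant with its estimation windows."""

    value: float
    delta_window: tuple
    l_window: tuple
    method: str
    alpha_spec: ScaleSystem

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("c-hat must be nonnegative")
        if not self.delta_window[0] < self.delta_window[1]:
            raise ValueError("delta window must be increasing")
        if self.l_window[0] > self.l_window[1]:
            raise ValueError("l window must be ordered")

    @property
    def rounded(self) -> float:
        """The estimate at two decimals, the precision used for figure prints."""
        return round(self.value, 2)

    def to_json(self) -> str:
        return json.dumps({
            "value": self.value,
            "rounded": self.rounded,
            "delta_window": list(self.delta_window),
            "l_window": [int(v) for v in self.l_window],
            "method": self.method,
            "scales": list(self.alpha_spec.scales),
            "precision": self.alpha_spec.precision,
        })


def _alpha_value(alpha) -> float:
    if isinstance(alpha, (int, float)):
        return float(alpha)
    return float(sp.N(parse_scale(alpha), 20))


def eps_two(l, alpha):
    """Two-module approximation error ``||l/alpha||`` (= phase of module 1 at ``l``).

    Accepts a scalar or array of integer distances; ``alpha`` may be numeric
    or symbolic (evaluated to double precision).
    """
    a = _alpha_value(alpha)
    if a <= 1:
        raise ValueError("alpha must exceed 1")
    ls = np.asarray(l, dtype=float)
    if np.any(ls < 1):
        raise ValueError("l must be positive")
    out = circ_norm(ls / a)
    return float(out) if np.isscalar(l) else out


def record_lows_two(alpha, l_max: int) -> list[tuple[int, float]]:
    """Running minima of ``eps_two`` over ``l = 1..l_max``.

    Returns ``(l, eps)`` pairs with strictly increasing ``l`` and strictly
    decreasing ``eps``; ties at equal eps are not records (first l wins).
    For the golden ratio the record distances are the Fibonacci numbers.
    """
    if l_max < 1:
        raise ValueError("l_max must be positive")
    a = _alpha_value(alpha)
    records = []
    best = math.inf
    chunk = 1 << 17
    for start in range(1, l_max + 1, chunk):
        ls = np.arange(start, min(start + chunk, l_max + 1), dtype=float)
        eps = circ_norm(ls / a)
        thr = best * (1 - RECORD_RTOL) if math.isfinite(best) else best
        for idx in np.nonzero(eps < thr)[0]:
            if eps[idx] < best * (1 - RECORD_RTOL):
                best = float(eps[idx])
                records.append((int(ls[idx]), best))
    return records


def eps_hat(l: int, system: ScaleSystem) -> float:
    """Scaled interference statistic ``g(l) * l^{1/(M-1)}``.

    For M = 2 this reduces algebraically to
    ``||l/alpha|| * alpha/(1+alpha) * l``.
    """
    gap, _ = min_max_gap(l, system)
    return gap * float(l) ** (1.0 / (system.M - 1))


def _lower_bound_chunk(ls: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Cheap per-module lower bound on g(l): pairs with module 0 only."""
    lb = np.zeros(len(ls))
    for a in alphas[1:]:
        np.maximum(lb, circ_norm(ls / a) * a / (1.0 + a), out=lb)
    return lb


def _refine_records_mp(records: list[InterferenceRecord],
                       system: ScaleSystem) -> list[InterferenceRecord]:
    """Recompute record gaps at the system precision and drop spurious ones."""
    exponent = 1.0 / (system.M - 1)
    out: list[InterferenceRecord] = []
    best = math.inf
    for r in records:
        gap = float(pairwise_gap(r.K, system, dps=system.precision))
        if gap < best * (1 - RECORD_RTOL) or not out:
            best = gap
            out.append(InterferenceRecord(r.l, r.K, gap, gap * r.l**exponent))
    return out


def record_lows_M(system: ScaleSystem, l_max: int,
                  stop_gap: float | None = None) -> list[InterferenceRecord]:
    """Running minima of the unscaled gap ``g(l)`` for ``l = 1..l_max``.

    Vectorised brute force: the per-module lower bound eliminates almost all
    distances and the exact branch-and-bound minimisation runs only where the
    bound undercuts the current record.  ``stop_gap`` ends the scan early
    once a record falls below it (the window estimators only need records
    down to their finer noise threshold).  Distances beyond
    ``BRUTE_FORCE_CAP`` require the lattice backend (`lattice.sweep_records`).
    """
    if l_max < 1:
        raise ValueError("l_max must be positive")
    if l_max > BRUTE_FORCE_CAP:
        raise ValueError(
            f"brute force is capped at l_max={BRUTE_FORCE_CAP:.0e}; "
            "use gridcode.lattice.sweep_records for larger distances")
    alphas = system.alphas
    exponent = 1.0 / (system.M - 1)
    records: list[InterferenceRecord] = []
    best = math.inf
    chunk = 1 << 17
    for start in range(1, l_max + 1, chunk):
        ls = np.arange(start, min(start + chunk, l_max + 1), dtype=float)
        lb = _lower_bound_chunk(ls, alphas)
        thr = best * (1 - RECORD_RTOL) if math.isfinite(best) else best
        for idx in np.nonzero(lb < thr)[0]:
            thr = best * (1 - RECORD_RTOL) if math.isfinite(best) else best
            if lb[idx] >= thr:
                continue
            l = int(ls[idx])
            gap, K = min_max_gap(l, system)
            if gap < thr or not records:
                best = gap
                records.append(InterferenceRecord(l, K, gap, gap * l**exponent))
        if stop_gap is not None and best < stop_gap:
            break
    if system.symbolic is not None and l_max > 10**6:
        records = _refine_records_mp(records, system)
    return records


def records_until(system: ScaleSystem, stop_gap: float,
                  l_cap: int | None = None, backend: str = "auto") -> list[InterferenceRecord]:
    """Record lows of ``g(l)`` down to ``gap < stop_gap``.

    Chooses between the brute-force scan and the lattice epsilon-sweep based
    on a rough forecast of the distance at which the gap reaches ``stop_gap``
    (``l ~ (0.4/stop_gap)^{M-1}``); raises if the cap is hit first.
    """
    forecast = (0.4 / stop_gap) ** (system.M - 1)
    if backend == "auto":
        backend = "lattice" if forecast > 2e5 else "brute"
    if backend == "brute":
        cap = l_cap or min(BRUTE_FORCE_CAP, max(10**4, int(forecast * 50)))
        records = record_lows_M(system, cap, stop_gap=stop_gap)
    elif backend == "lattice":
        from . import lattice
        records = lattice.sweep_records(system, 1, l_cap or 10**18, stop_gap=stop_gap)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    if not records or records[-1].gap >= stop_gap:
        raise RuntimeError(
            f"no record below gap {stop_gap} found within the scan cap; "
            "raise l_cap or use the lattice backend")
    return records


def c_hat_window(system: ScaleSystem, delta1: float, delta2: float,
                 backend: str = "auto", l_cap: int | None = None) -> CHatEstimate:
    """Record-window estimator of the capacity constant.

    ``l_2`` is the first record distance beyond which the running-minimum gap
    stays below ``delta2`` and ``l_1`` the first at which it falls below
    ``delta1``; the estimate is the minimum of the scaled records inside
    ``[l_2, l_1]`` — the distance range actually probed by noise levels
    between ``delta1`` and ``delta2``.
    """
    if not 0 < delta1 < delta2 < 0.5:
        raise ValueError("need 0 < delta1 < delta2 < 0.5")
    records = records_until(system, delta1, l_cap=l_cap, backend=backend)
    l2 = next(r.l for r in records if r.gap < delta2)
    l1 = next(r.l for r in records if r.gap < delta1)
    window = [r for r in records if l2 <= r.l <= l1]
    if not window:
        raise RuntimeError(
            f"empty record window: l2={l2}, l1={l1} for deltas ({delta1}, {delta2})")
    value = min(r.scaled for r in window)
    return CHatEstimate(value=value, delta_window=(delta1, delta2),
                        l_window=(l2, l1), method="window", alpha_spec=system)


def geometric_delta_grid(delta_min: float, delta_max: float,
                         points_per_decade: int = 60) -> np.ndarray:
    """Geometric noise grid with at least ``points_per_decade`` points/decade."""
    decades = math.log10(delta_max / delta_min)
    n = max(2, int(math.ceil(decades * points_per_decade)) + 1)
    return np.geomspace(delta_min, delta_max, n)


def c_hat_from_lmax_scan(system: ScaleSystem, delta_grid: Sequence[float],
                         backend: str = "auto", l_cap: int | None = None) -> CHatEstimate:
    """Capacity estimate from the coding-range scan ``inf_delta delta * L_max(delta)^{1/(M-1)}``.

    For each noise level the first ambiguous integer is read off the record
    sequence (the first record with gap below ``delta``); the infimum over the
    grid of ``delta * L_max^{1/(M-1)}`` estimates ``c_A`` (exponent 1 when
    M = 2).
    """
    grid = np.asarray(sorted(delta_grid), dtype=float)
    if np.any(grid <= 0) or np.any(grid >= 0.5):
        raise ValueError("all deltas must lie in (0, 0.5)")
    records = records_until(system, float(grid[0]), l_cap=l_cap, backend=backend)
    rec_l = np.array([r.l for r in records])
    rec_gap = np.array([r.gap for r in records])
    exponent = 1.0 / (system.M - 1)
    values, lmaxes = [], []
    for d in grid:
        below = np.nonzero(rec_gap < d)[0]
        if len(below) == 0:
            raise RuntimeError(f"no ambiguity found below the cap for delta={d}")
        L = int(rec_l[below[0]])
        lmaxes.append(L)
        values.append(d * L**exponent)
    best = int(np.argmin(values))
    return CHatEstimate(value=float(values[best]),
                        delta_window=(float(grid[0]), float(grid[-1])),
                        l_window=(min(lmaxes), max(lmaxes)),
                        method="lmax_scan", alpha_spec=system)


def hurwitz_deficit(alpha, l_max: int) -> int:
    """Count of distances ``l <= l_max`` with ``eps(l) < 1/(sqrt(5) l)``.

    By Hurwitz's theorem every irrational admits infinitely many such
    approximations, and for the golden ratio the bound is sharp: the
    qualifying ``l * eps(l)`` approach ``1/sqrt(5)`` from below.
    """
    if l_max < 10:
        raise ValueError("l_max must be at least 10")
    a = _alpha_value(alpha)
    count = 0
    chunk = 1 << 17
    for start in range(1, l_max + 1, chunk):
        ls = np.arange(start, min(start + chunk, l_max + 1), dtype=float)
        eps = circ_norm(ls / a)
        count += int(np.sum(eps * ls * math.sqrt(5) < 1.0))
    return count


def write_records_csv(records: Sequence[InterferenceRecord], path) -> None:
    """Record series as CSV with header ``l,gap,scaled,k_0..k_{M-1}``."""
    if not records:
        Path(path).write_text("l,gap,scaled\n")
        return
    M = len(records[0].K)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["l", "gap", "scaled"] + [f"k_{i}" for i in range(M)])
        for r in records:
            writer.writerow([r.l, repr(r.gap), repr(r.scaled)] + list(r.K))
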