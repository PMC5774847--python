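"""Phases, circular distances and interference predicates for modular grid codes.

A grid-cell system is modelled as a set of M modules with spatial periods
(scales) ``alpha_0 = 1 < alpha_1 < ... < alpha_{M-1}``, distances being
expressed in units of the smallest period.  A position ``x`` is summarised by
the phase vector ``psi_i(x) = (x mod alpha_i)/alpha_i``.  Two positions are
confusable when every module assigns them nearly identical phases, which at
integer distances reduces to a simultaneous Diophantine approximation
condition on the scale vector.  This module provides the exact (brute-force)
side of that machinery: phase arithmetic, the pairwise interference
predicate, and direct coding-range scans.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import mpmath
import numpy as np
import sympy as sp

__all__ = [
    "ScaleSystem",
    "write_ambiguity_csv",
    "NoiseModel",
    "PhaseVector",
    "parse_scale",
    "phase",
    "circ_norm",
    "pairwise_gap",
    "min_max_gap",
    "ambiguous_at_integer",
    "ambiguous_at_x_bruteforce",
    "first_ambiguous_integer",
    "golden_identity",
]

#: golden ratio, the optimal two-module scale ratio
GOLDEN = (1 + sp.sqrt(5)) / 2


def parse_scale(token) -> sp.Expr:
    """Parse a scale specification into an exact sympy expression.

    Accepted forms: a number or numeric string (``"1.5"``, ``"3/2"``),
    ``"phi"``/``"sigma"`` (golden ratio), ``"e"``, ``"sqrtN"``/``"sqrt(N)"``,
    power expressions such as ``"2^(1/3)"`` or ``"phi^2"``, and
    ``"root:<integer polynomial in x>"`` which selects the largest real root
    (e.g. ``"root:x^10-x^7-1"``).  Decimal truncation of an algebraic scale
    changes its number-theoretic class, so symbolic forms should be preferred
    for the paper-level examples.
    """
    if isinstance(token, sp.Expr):
        return token
    if isinstance(token, (int, float)):
        return sp.nsimplify(token, rational=True) if float(token).is_integer() else sp.Float(token)
    text = str(token).strip()
    if text.startswith("root:"):
        poly = sp.Poly(sp.sympify(text[5:].replace("^", "**")), sp.Symbol("x"))
        roots = sp.real_roots(poly)
        if not roots:
            raise ValueError(f"polynomial {text[5:]!r} has no real root")
        return roots[-1]
    local = {"phi": GOLDEN, "sigma": GOLDEN, "e": sp.E, "pi": sp.pi}
    if text.startswith("sqrt") and not text.startswith("sqrt("):
        text = f"sqrt({text[4:]})"
    expr = sp.sympify(text.replace("^", "**"), locals=local)
    if not expr.is_number:
        raise ValueError(f"scale token {token!r} does not describe a number")
    return expr


def _evalf(expr: sp.Expr, dps: int) -> mpmath.mpf:
    with mpmath.workdps(dps):
        return mpmath.mpf(sp.N(expr, dps + 5).evalf(dps + 5))


@dataclass(frozen=True)
class ScaleSystem:
    """Ordered module scales with ``alpha_0 == 1``.

    Parameters
    ----------
    scales:
        Strictly increasing positive floats, first entry exactly 1.
    precision:
        Significant digits used whenever arithmetic is carried out on the
        arbitrary-precision path (symbolic scales, very large distances).
    symbolic:
        Optional per-scale exact sympy expressions; when present, each must
        agree with the corresponding float to the configured precision.
    """

    scales: tuple
    precision: int = 30
    symbolic: tuple | None = None

    def __post_init__(self):
        scales = tuple(float(a) for a in self.scales)
        object.__setattr__(self, "scales", scales)
        if len(scales) < 2:
            raise ValueError("a scale system needs at least two modules")
        if scales[0] != 1.0:
            raise ValueError("the first scale must be exactly 1")
        if any(not math.isfinite(a) or a <= 0 for a in scales):
            raise ValueError("scales must be finite and positive")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError("scales must be strictly increasing")
        if self.precision < 15:
            raise ValueError("precision below double precision is not supported")
        if self.symbolic is not None:
            sym = tuple(None if s is None else parse_scale(s) for s in self.symbolic)
            object.__setattr__(self, "symbolic", sym)
            if len(sym) != len(scales):
                raise ValueError("symbolic spec length must match scales")
            for a, s in zip(scales, sym):
                if s is not None and abs(float(sp.N(s, 20)) - a) > 1e-12 * max(1.0, a):
                    raise ValueError(f"symbolic scale {s} disagrees with numeric value {a}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_symbolic(cls, tokens: Iterable, precision: int = 30) -> "ScaleSystem":
        """Build a system from symbolic tokens (see :func:`parse_scale`)."""
        exprs = [parse_scale(t) for t in tokens]
        values = [float(sp.N(e, 20)) for e in exprs]
        return cls(tuple(values), precision=precision, symbolic=tuple(exprs))

    @classmethod
    def geometric(cls, alpha, M: int, precision: int = 30) -> "ScaleSystem":
        """Geometric progression ``{1, alpha, ..., alpha^{M-1}}``."""
        if M < 2:
            raise ValueError("M must be at least 2")
        expr = parse_scale(alpha)
        return cls.from_symbolic([expr**i for i in range(M)], precision=precision)

    # -- accessors ---------------------------------------------------------

    @property
    def M(self) -> int:
        return len(self.scales)

    @property
    def alphas(self) -> np.ndarray:
        return np.asarray(self.scales, dtype=float)

    def mp_scales(self, dps: int | None = None) -> list:
        """Scales as mpmath numbers at the working precision."""
        dps = dps or self.precision
        if self.symbolic is not None:
            return [
                _evalf(s, dps) if s is not None else mpmath.mpf(a)
                for a, s in zip(self.scales, self.symbolic)
            ]
        return [mpmath.mpf(a) for a in self.scales]

    # -- (de)serialisation -------------------------------------------------

    def to_json(self) -> str:
        doc = {"scales": list(self.scales), "precision": self.precision}
        if self.symbolic is not None:
            doc["symbolic"] = [None if s is None else str(s) for s in self.symbolic]
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "ScaleSystem":
        doc = json.loads(text)
        sym = doc.get("symbolic")
        return cls(tuple(doc["scales"]), precision=doc.get("precision", 30),
                   symbolic=None if sym is None else tuple(sym))

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "ScaleSystem":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class NoiseModel:
    """Relative phase uncertainty ``delta``, identical across modules.

    Module ``i`` localises the animal to within ``delta * alpha_i`` of the
    true position, i.e. with the same phase error ``delta`` everywhere.
    """

    delta: float

    def __post_init__(self):
        if not 0 < self.delta < 0.5:
            raise ValueError("delta must lie strictly between 0 and 0.5")


@dataclass(frozen=True)
class PhaseVector:
    """The phase tuple ``psi_i(x)`` of one position across all modules."""

    psi: tuple
    x: float

    def __post_init__(self):
        if any(not 0 <= p < 1 for p in self.psi):
            raise ValueError("phases must lie in [0, 1)")

    @classmethod
    def at(cls, x: float, system: ScaleSystem) -> "PhaseVector":
        return cls(tuple(phase(x, a) for a in system.scales), float(x))


def phase(x, alpha, precision: int | None = None):
    """Module phase ``(x mod alpha)/alpha`` in ``[0, 1)``.

    With ``precision`` set, the computation runs in mpmath arithmetic so the
    absolute phase error stays below ``10**(-precision+guard)`` even for
    ``x ~ 1e9``; otherwise plain doubles are used (adequate for x < ~1e6).
    """
    if precision is not None or isinstance(x, mpmath.mpf) or isinstance(alpha, (mpmath.mpf, sp.Expr)):
        dps = precision or mpmath.mp.dps
        with mpmath.workdps(dps + 10):
            a = _evalf(alpha, dps + 10) if isinstance(alpha, sp.Expr) else mpmath.mpf(alpha)
            if a <= 0:
                raise ValueError("alpha must be positive")
            p = mpmath.fmod(mpmath.mpf(x), a) / a
            if p < 0:
                p += 1
            if p >= 1:
                p -= 1
        return p
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return (x % alpha) / alpha % 1.0


def circ_norm(psi):
    """Distance of ``psi`` from the nearest integer, in ``[0, 0.5]``.

    Accepts scalars, arrays or mpmath numbers; the input is reduced modulo 1
    first, so any real value is valid.
    """
    if isinstance(psi, mpmath.mpf):
        frac = mpmath.fmod(psi, 1)
        if frac < 0:
            frac += 1
        return min(frac, 1 - frac)
    frac = np.mod(psi, 1.0)
    return np.minimum(frac, 1.0 - frac) if isinstance(frac, np.ndarray) else float(min(frac, 1.0 - frac))


def pairwise_gap(K: Sequence[int], system: ScaleSystem, dps: int | None = None):
    """Maximum normalised pairwise gap ``max_{i<j} |k_i a_i - k_j a_j|/(a_i + a_j)``.

    ``K`` supplies one integer multiple per module (``k_0`` playing the role
    of the integer distance ``l``).  This is the quantity whose smallness, for
    all pairs simultaneously, defines interference at that distance.
    """
    if len(K) != system.M:
        raise ValueError(f"K has {len(K)} entries but the system has {system.M} modules")
    if dps is not None:
        alphas = system.mp_scales(dps)
        with mpmath.workdps(dps):
            prods = [k * a for k, a in zip(K, alphas)]
            return max(
                abs(prods[i] - prods[j]) / (alphas[i] + alphas[j])
                for i, j in itertools.combinations(range(system.M), 2)
            )
    a = system.alphas
    prods = np.asarray(K, dtype=float) * a
    gap = 0.0
    for i, j in itertools.combinations(range(system.M), 2):
        gap = max(gap, abs(prods[i] - prods[j]) / (a[i] + a[j]))
    return gap


def _candidates(l: int, alpha: float) -> list:
    """Integer multiples of ``alpha`` that can lie within one period of ``l``."""
    base = l / alpha
    lo = math.floor(base)
    return sorted({lo - 1, lo, lo + 1, lo + 2}, key=lambda k: abs(l - k * alpha))


def min_max_gap(l: int, system: ScaleSystem) -> tuple[float, tuple]:
    """Minimise :func:`pairwise_gap` over integer vectors ``K`` with ``k_0 = l``.

    The search runs over the candidate set ``k_i`` in {floor(l/a_i)-1, ...,
    ceil(l/a_i)+1} (any multiple within module reach of ``x ~ l`` must be one
    of the two nearest ones; the +-1 guard covers boundary rounding), with
    depth-first branch-and-bound pruning on the running maximum.  Returns the
    minimal max-gap and its witness ``K``.
    """
    if l < 1:
        raise ValueError("l must be a positive integer")
    a = system.alphas
    M = system.M
    cand = [_candidates(l, a[i]) for i in range(1, M)]
    # upper bound from per-module nearest rounding
    best_K = [l] + [c[0] for c in cand]
    best = pairwise_gap(best_K, system)
    if M == 2:
        return best, tuple(best_K)

    prods0 = [l * 1.0]

    def dfs(i: int, prods: list, cur: float, K: list):
        nonlocal best, best_K
        if cur >= best:
            return
        if i == M:
            best, best_K = cur, list(K)
            return
        for k in cand[i - 1]:
            p = k * a[i]
            new = cur
            ok = True
            for j in range(i):
                g = abs(prods[j] - p) / (a[j] + a[i])
                if g >= best:
                    ok = False
                    break
                if g > new:
                    new = g
            if ok:
                prods.append(p)
                K.append(k)
                dfs(i + 1, prods, new, K)
                prods.pop()
                K.pop()

    dfs(1, prods0, 0.0, [l])
    return best, tuple(best_K)


def ambiguous_at_integer(l: int, system: ScaleSystem, noise: NoiseModel):
    """Is the integer distance ``l`` confusable with the origin?

    True iff some integer vector ``K`` with ``k_0 = l`` satisfies the strict
    pairwise interference condition ``|k_i a_i - k_j a_j| < (a_i + a_j) delta``
    for every pair; the witness ``K`` is returned alongside.
    """
    if l < 1:
        raise ValueError("l must be a positive integer")
    gap, K = min_max_gap(l, system)
    return (True, K) if gap < noise.delta else (False, None)


def ambiguous_at_x_bruteforce(system: ScaleSystem, noise: NoiseModel,
                              x_max: float, step: float) -> np.ndarray:
    """All grid points ``x`` in ``(delta, x_max]`` confusable with the origin.

    A point is confusable when every module has an integer multiple within
    ``alpha_i * delta`` of it, i.e. ``||x/alpha_i|| < delta`` for all ``i``.
    Serves as the independent oracle for the integer-distance predicate; the
    step must not exceed ``delta/4`` or interference intervals could be
    skipped.
    """
    delta = noise.delta
    if step > delta / 4:
        raise ValueError("step must be at most delta/4 to resolve interference intervals")
    xs = np.arange(step, x_max + step / 2, step)
    xs = xs[xs > delta]
    mask = np.ones(len(xs), dtype=bool)
    for a in system.scales:
        mask &= circ_norm(xs / a) < delta
    return xs[mask]


def first_ambiguous_integer(system: ScaleSystem, noise: NoiseModel,
                            l_cap: int = 10**6) -> int | None:
    """Smallest integer distance in ``1..l_cap`` confusable with the origin.

    Scans in vectorised chunks: the cheap per-module lower bound
    ``max_i ||l/a_i|| a_i/(1+a_i)`` rules out almost every ``l``; the exact
    branch-and-bound check runs only on the survivors.  Returns ``None`` when
    the whole range is unambiguous.
    """
    if l_cap < 1:
        raise ValueError("l_cap must be at least 1")
    a = system.alphas
    delta = noise.delta
    chunk = 1 << 16
    for start in range(1, l_cap + 1, chunk):
        ls = np.arange(start, min(start + chunk, l_cap + 1), dtype=float)
        lb = np.zeros(len(ls))
        for ai in a[1:]:
            np.maximum(lb, circ_norm(ls / ai) * ai / (1.0 + ai), out=lb)
        for idx in np.nonzero(lb < delta)[0]:
            l = int(ls[idx])
            if min_max_gap(l, system)[0] < delta:
                return l
    return None


def golden_identity(x, precision: int = 30):
    """Residual of the golden-ratio phase identity for scales ``{1, s, s^2}``.

    Because the golden ratio ``s`` solves ``s^2 = s + 1``, the third module's
    phase is determined by the first two: ``psi_2(x) = (psi_0 - psi_1) mod 1``.
    Returns ``circ_norm(psi_2(x) - (psi_0(x) - psi_1(x)))``, which must vanish
    to the working precision for every ``x`` — the redundancy that makes
    geometric golden-ratio systems suboptimal beyond two modules.
    """
    with mpmath.workdps(precision + 10):
        s = (1 + mpmath.sqrt(5)) / 2
        p0 = phase(x, mpmath.mpf(1), precision=precision)
        p1 = phase(x, s, precision=precision)
        p2 = phase(x, s * s, precision=precision)
        return circ_norm(p2 - (p0 - p1))


def write_ambiguity_csv(path, system: ScaleSystem, noise: NoiseModel, l_max: int) -> None:
    """Per-integer ambiguity table: header ``l,ambiguous,k_0..k_{M-1},gap``."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["l", "ambiguous"] + [f"k_{i}" for i in range(system.M)] + ["gap"])
        for l in range(1, l_max + 1):
            gap, K = min_max_gap(l, system)
            w.writerow([l, int(gap < noise.delta)] + list(K) + [repr(gap)])
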