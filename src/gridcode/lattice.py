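"""Lattice formulation of simultaneous approximation with a common numerator.

Interference records at distances far beyond brute force are found through a
lattice whose vectors have one coordinate per module pair, equal to the
normalised gap ``(k_j a_j - k_i a_i)/(a_i + a_j)``, plus a penalty coordinate
``l * epsilon``.  The sup-norm-shortest nonzero vector of that lattice
minimises ``max(l*eps, max-pair-gap)``, so as the penalty weight ``epsilon``
decreases the optimum walks down the record sequence of the gap statistic.
The sweep exploits that structure exactly: the optimiser as a function of
``epsilon`` is a step function over the records, and the breakpoint between
adjacent records ``(l_a, g_a)`` and ``(l_b, g_b)`` sits at
``eps = g_a / l_b`` — probing exactly there either certifies adjacency or
exposes a strictly better intermediate record, so the full record sequence
is recovered with about two shortest-vector calls per record.

Shortest vectors are computed by LLL reduction (own implementation; the
lattices have rank <= M <= ~11) followed by a branch-and-bound enumeration
with Euclidean pruning bounds derived from the reduced Gram-Schmidt data,
checking the sup norm at the leaves.  When the scales are symbolic and the
implied distances are large, the reduction runs in mpmath arithmetic to
avoid false optima from catastrophic cancellation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import mpmath
import numpy as np
from numba import njit

from .core import ScaleSystem, min_max_gap, pairwise_gap
from .diophantine import RECORD_RTOL, InterferenceRecord

__all__ = [
    "LatticeBasis",
    "SupShortestResult",
    "build_basis",
    "lll_reduce",
    "svp_sup",
    "sweep_records",
]


@dataclass(frozen=True)
class LatticeBasis:
    """Rows generating the interference lattice of a scale system.

    One column per unordered module pair ``(i, j)`` (coordinate = normalised
    pair gap) plus one penalty column; one row per free integer coefficient
    ``k_1 .. k_{M-1}`` and a final row for the common numerator ``l``.  For
    M modules the matrix is ``M x (M(M-1)/2 + 1)``.
    """

    rows: tuple
    pairs: tuple
    epsilon: float
    system: ScaleSystem
    transform: tuple | None = None  # unimodular map from the original rows

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        M = self.system.M
        if len(self.rows) != M or len(self.rows[0]) != M * (M - 1) // 2 + 1:
            raise ValueError("basis shape must be M x (M(M-1)/2 + 1)")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[float(x) for x in row] for row in self.rows])

    def dump(self) -> str:
        """Plain-text matrix for debugging."""
        return "\n".join("  ".join(f"{float(x): .12e}" for x in row) for row in self.rows)


@dataclass(frozen=True)
class SupShortestResult:
    """Sup-norm-shortest lattice vector with its integer coefficients.

    ``coeffs`` are the coefficients with respect to the original basis rows
    ``(k_1, ..., k_{M-1}, l)``; ``l`` is the implied integer distance.
    ``optimal`` is False only when the enumeration hit its node budget.
    """

    coeffs: tuple
    vector: tuple
    sup_norm: float
    l: int
    optimal: bool = True


def build_basis(system: ScaleSystem, epsilon: float,
                dps: int | None = None) -> LatticeBasis:
    """Generating rows of the interference lattice with penalty weight ``epsilon``.

    Row ordering matches the printed layout: coefficient rows for
    ``k_1 .. k_{M-1}`` first, the numerator row (entries ``-1/(1+a_j)`` in the
    module-0 pair columns and ``epsilon`` in the penalty column) last.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    M = system.M
    pairs = tuple(itertools.combinations(range(M), 2))
    ctx = mpmath.workdps(dps) if dps is not None else None
    if ctx is not None:
        ctx.__enter__()
    try:
        if dps is not None:
            alphas = system.mp_scales(dps)
            zero, eps = mpmath.mpf(0), mpmath.mpf(epsilon)
        else:
            alphas = [float(a) for a in system.scales]
            zero, eps = 0.0, float(epsilon)
        ncol = len(pairs) + 1
        rows = []
        for m in range(1, M):
            row = [zero] * ncol
            for c, (i, j) in enumerate(pairs):
                if m == j:
                    row[c] = alphas[m] / (alphas[i] + alphas[j])
                elif m == i:
                    row[c] = -alphas[m] / (alphas[i] + alphas[j])
            rows.append(tuple(row))
        last = [zero] * ncol
        for c, (i, j) in enumerate(pairs):
            if i == 0:
                last[c] = -1 / (1 + alphas[j])
        last[-1] = eps
        rows.append(tuple(last))
    finally:
        if ctx is not None:
            ctx.__exit__(None, None, None)
    return LatticeBasis(rows=tuple(rows), pairs=pairs, epsilon=float(epsilon),
                        system=system)


# ---------------------------------------------------------------------------
# LLL reduction


def _gso(B: np.ndarray):
    n = B.shape[0]
    Bstar = np.zeros_like(B)
    mu = np.zeros((n, n))
    norm2 = np.zeros(n)
    for i in range(n):
        v = B[i].copy()
        for j in range(i):
            mu[i, j] = (B[i] @ Bstar[j]) / norm2[j]
            v -= mu[i, j] * Bstar[j]
        Bstar[i] = v
        norm2[i] = v @ v
    return Bstar, mu, norm2


def _lll_np(B: np.ndarray, delta: float):
    """Float LLL; returns reduced rows and the integer transform."""
    B = B.copy()
    n = B.shape[0]
    U = [[int(i == j) for j in range(n)] for i in range(n)]
    scale = max(float(np.max(np.abs(B))), 1e-300)
    _, _, norm2 = _gso(B)
    if np.min(norm2) < (1e-13 * scale) ** 2:
        raise ValueError("basis rows are linearly dependent")
    k = 1
    guard = 0
    while k < n:
        guard += 1
        if guard > 10000:  # float LLL can cycle on near-degenerate input
            break
        _, mu, norm2 = _gso(B)
        for j in range(k - 1, -1, -1):
            q = round(mu[k, j])
            if q:
                B[k] -= q * B[j]
                U[k] = [uk - q * uj for uk, uj in zip(U[k], U[j])]
                _, mu, norm2 = _gso(B)
        if norm2[k] >= (delta - mu[k, k - 1] ** 2) * norm2[k - 1]:
            k += 1
        else:
            B[[k - 1, k]] = B[[k, k - 1]]
            U[k - 1], U[k] = U[k], U[k - 1]
            k = max(k - 1, 1)
    return B, U


def _lll_mp(rows: list, delta, dps: int):
    """LLL in mpmath arithmetic for precision-critical (large-distance) bases."""
    with mpmath.workdps(dps):
        B = [list(r) for r in rows]
        n = len(B)
        U = [[int(i == j) for j in range(n)] for i in range(n)]

        def dot(x, y):
            return mpmath.fsum(a * b for a, b in zip(x, y))

        def gso():
            Bstar, mu, norm2 = [], [[mpmath.mpf(0)] * n for _ in range(n)], []
            for i in range(n):
                v = list(B[i])
                for j in range(i):
                    mu[i][j] = dot(B[i], Bstar[j]) / norm2[j]
                    v = [a - mu[i][j] * b for a, b in zip(v, Bstar[j])]
                Bstar.append(v)
                norm2.append(dot(v, v))
            return mu, norm2

        mu, norm2 = gso()
        if min(norm2) <= 0:
            raise ValueError("basis rows are linearly dependent")
        k, guard = 1, 0
        while k < n:
            guard += 1
            if guard > 20000:
                break
            mu, norm2 = gso()
            for j in range(k - 1, -1, -1):
                q = int(mpmath.nint(mu[k][j]))
                if q:
                    B[k] = [a - q * b for a, b in zip(B[k], B[j])]
                    U[k] = [uk - q * uj for uk, uj in zip(U[k], U[j])]
                    mu, norm2 = gso()
            if norm2[k] >= (delta - mu[k][k - 1] ** 2) * norm2[k - 1]:
                k += 1
            else:
                B[k - 1], B[k] = B[k], B[k - 1]
                U[k - 1], U[k] = U[k], U[k - 1]
                k = max(k - 1, 1)
        return B, U


def lll_reduce(basis: LatticeBasis, delta: float = 0.99,
               dps: int | None = None) -> LatticeBasis:
    """LLL-reduce the basis (strong reduction, default Lovasz delta 0.99).

    The returned basis generates the same lattice; the unimodular transform
    from the original rows is recorded on the result.  With ``dps`` the
    reduction runs in mpmath arithmetic and the reduced rows are returned as
    floats (safe: reduced entries are small even when coefficients are huge).
    """
    if dps is not None:
        rows, U = _lll_mp([list(r) for r in basis.rows], mpmath.mpf(delta), dps)
        rows = [tuple(float(x) for x in r) for r in rows]
    else:
        B, U = _lll_np(basis.matrix, delta)
        rows = [tuple(float(x) for x in r) for r in B]
    prev = basis.transform
    if prev is not None:  # compose with an earlier transform
        U = [[sum(U[i][k] * prev[k][j] for k in range(len(prev)))
              for j in range(len(prev[0]))] for i in range(len(U))]
    return LatticeBasis(rows=tuple(rows), pairs=basis.pairs, epsilon=basis.epsilon,
                        system=basis.system, transform=tuple(tuple(r) for r in U))


# ---------------------------------------------------------------------------
# Exact sup-norm shortest vector


@njit(cache=True)
def _enumerate_sup(Bfull, mu, norm2, best_sup0, d_enum, node_cap):  # pragma: no cover
    """Iterative branch-and-bound over reduced-basis integer coefficients.

    Euclidean pruning in the d_enum-dimensional projection; the full sup
    norm is evaluated at the leaves and shrinks the radius on improvement.
    Returns (best_sup, best_x, nodes, capped); best_x all-zero means no
    vector below the initial bound was found.
    """
    n, ncol = Bfull.shape
    best_sup = best_sup0
    R2 = d_enum * best_sup * best_sup
    xs = np.zeros(n, dtype=np.int64)
    best_x = np.zeros(n, dtype=np.int64)
    cur = np.zeros(n, dtype=np.int64)
    hi = np.zeros(n, dtype=np.int64)
    center = np.zeros(n)
    partial = np.zeros(n + 1)
    nodes = 0
    capped = False

    i = n - 1
    center[i] = 0.0
    partial[i] = 0.0
    half = math.sqrt(max(R2 - partial[i], 0.0) / norm2[i])
    cur[i] = int(math.ceil(-center[i] - half - 1e-9)) - 1
    hi[i] = int(math.floor(-center[i] + half + 1e-9))
    while True:
        cur[i] += 1
        if cur[i] > hi[i]:
            i += 1
            if i >= n:
                break
            continue
        nodes += 1
        if nodes > node_cap:
            capped = True
            break
        contrib = (cur[i] + center[i]) ** 2 * norm2[i]
        if partial[i] + contrib > R2 * (1.0 + 1e-12):
            continue
        if i == 0:
            nonzero = False
            for k in range(n):
                if cur[k] != 0:
                    nonzero = True
                    break
            if not nonzero:
                continue
            sup = 0.0
            for j in range(ncol):
                w = 0.0
                for k in range(n):
                    w += cur[k] * Bfull[k, j]
                aw = abs(w)
                if aw > sup:
                    sup = aw
            if 0.0 < sup and sup * (1.0 + 1e-12) < best_sup:
                best_sup = sup
                for k in range(n):
                    best_x[k] = cur[k]
                R2 = d_enum * best_sup * best_sup
            continue
        partial[i - 1] = partial[i] + contrib
        i -= 1
        c = 0.0
        for j in range(i + 1, n):
            c += mu[j, i] * cur[j]
        center[i] = c
        half = math.sqrt(max(R2 - partial[i], 0.0) / norm2[i])
        cur[i] = int(math.ceil(-c - half - 1e-9)) - 1
        hi[i] = int(math.floor(-c + half + 1e-9))
    return best_sup, best_x, nodes, capped


def svp_sup(basis: LatticeBasis, upper_bound: float | None = None,
            node_cap: int = 100_000_000, dps: int | None = None) -> SupShortestResult:
    """Exact sup-norm-shortest nonzero vector of the lattice.

    LLL-reduces first (in mpmath when ``dps`` is given), then enumerates
    integer coefficient vectors branch-and-bound style with the Euclidean
    pruning radius ``sqrt(d) * U`` implied by the current best sup norm ``U``
    (initialised from the best reduced row, optionally tightened by a known
    achievable ``upper_bound``).  Only strict improvements replace the
    incumbent, so among numerically tied solutions the first one found is
    kept.  If the node budget is exhausted the best vector found so far is
    returned with ``optimal=False``.
    """
    M = basis.system.M
    ncol = len(basis.pairs) + 1
    # the module-0 pair columns plus the penalty column form a full-rank
    # square subsystem (det = prod a_i/(1+a_i) * eps != 0); every coordinate
    # of a sup-bounded vector is bounded there too, so enumeration can run in
    # this M-dimensional projection (Euclidean radius sqrt(M)*U instead of
    # sqrt(M(M-1)/2+1)*U) with the full sup norm checked only at the leaves
    enum_cols = list(range(M - 1)) + [ncol - 1]

    sub = [[row[c] for c in enum_cols] for row in basis.rows]
    if dps is not None:
        _, U = _lll_mp(sub, mpmath.mpf(0.99), dps)
        with mpmath.workdps(dps):
            rows_mp = [list(r) for r in basis.rows]
            red_full = [[mpmath.fsum(U[i][k] * rows_mp[k][j] for k in range(M))
                         for j in range(ncol)] for i in range(M)]
        B = np.array([[float(x) for x in r] for r in red_full])
    else:
        _, U = _lll_np(np.array(sub, dtype=float), 0.99)
        B = np.array(U, dtype=float) @ basis.matrix
    if basis.transform is not None:
        U = [[sum(U[i][k] * basis.transform[k][j] for k in range(M))
              for j in range(M)] for i in range(M)]
    n = B.shape[0]
    d = len(enum_cols)
    Benum = B[:, enum_cols]
    Bstar, mu, norm2 = _gso(Benum)
    if np.min(norm2) <= 0:
        raise ValueError("reduced basis is rank deficient")

    sups = np.max(np.abs(B), axis=1)
    best_sup = float(np.min(sups))
    best_x = [int(i == int(np.argmin(sups))) for i in range(n)]
    if upper_bound is not None:
        # known-achievable bound: the slack must exceed the float error
        # accumulated in the reduced rows (which grows with the implied
        # coefficient magnitude ~ upper_bound/epsilon), or the achieving
        # vector itself becomes invisible to the enumeration
        err = 0.0 if dps is not None else upper_bound / basis.epsilon * 5e-15
        bound = float(upper_bound) * (1 + 1e-6) + err
        if bound < best_sup:
            best_sup = bound
            best_x = None
    sup_found, x_found, _, was_capped = _enumerate_sup(
        np.ascontiguousarray(B), np.ascontiguousarray(mu),
        np.ascontiguousarray(norm2), best_sup, float(d), node_cap)
    if np.any(x_found):
        best_sup, best_x = float(sup_found), [int(v) for v in x_found]
    if best_x is None:
        raise RuntimeError("no lattice vector found below the supplied upper bound")
    if was_capped:
        warnings.warn("sup-norm enumeration hit its node budget; result may be suboptimal",
                      RuntimeWarning, stacklevel=2)
    # map reduced-basis coefficients to original-row coefficients
    orig = [sum(best_x[k] * U[k][j] for k in range(n)) for j in range(n)]
    if orig[-1] < 0:
        orig = [-v for v in orig]
    vec = np.array(orig, dtype=float) @ np.array(
        [[float(x) for x in row] for row in basis.rows])
    return SupShortestResult(coeffs=tuple(orig), vector=tuple(float(v) for v in vec),
                             sup_norm=float(best_sup), l=abs(int(orig[-1])),
                             optimal=not was_capped)


# ---------------------------------------------------------------------------
# Parametric epsilon-sweep


def _gap_of(system: ScaleSystem, K, l: int) -> float:
    dps = system.precision if (system.symbolic is not None and l > 10**6) else None
    return float(pairwise_gap(K, system, dps=dps))


def _needs_mp(epsilon: float, hint: float | None) -> bool:
    # float LLL size-reduction coefficients scale like objective/epsilon;
    # their rounding noise must stay well below the objective itself
    scale = hint if hint is not None else 1.0
    return epsilon < 1e-13 / max(scale, 1e-30) or epsilon < 1e-14


def _solve(system: ScaleSystem, epsilon: float, hint: float | None,
           node_cap: int) -> tuple[int, float, tuple] | None:
    """Best (l, gap, K) with l != 0 at penalty weight epsilon, or None."""
    dps = system.precision + 10 if _needs_mp(epsilon, hint) else None
    try:
        basis = build_basis(system, epsilon, dps=dps)
        res = svp_sup(basis, upper_bound=hint, node_cap=node_cap, dps=dps)
    except RuntimeError:
        if dps is not None:
            raise
        # float reduction lost the achieving vector to rounding: redo in mp
        dps = system.precision + 10
        basis = build_basis(system, epsilon, dps=dps)
        res = svp_sup(basis, upper_bound=hint, node_cap=node_cap, dps=dps)
    if not res.optimal:
        raise RuntimeError(
            f"sup-norm enumeration exhausted its node budget at eps={epsilon:g}; "
            "the record sweep cannot be certified")
    if res.l == 0:
        return None
    K = (res.l,) + tuple(res.coeffs[:-1])
    return res.l, _gap_of(system, K, res.l), K


def sweep_records(system: ScaleSystem, l_min: int = 1, l_max: int = 10**12,
                  stop_gap: float | None = None,
                  node_cap: int = 100_000_000) -> list[InterferenceRecord]:
    """Record lows of the gap statistic via the lattice parametric sweep.

    Walks the record sequence from ``l = 1`` outward, then certifies that no
    record was skipped by probing each adjacent pair's breakpoint penalty
    ``eps = g_a / l_b``.  Stops once a record exceeds ``l_max`` or falls
    below ``stop_gap``.  Returns the records with ``l_min <= l <= l_max``,
    gaps recomputed at the system precision where that matters; must agree
    exactly with the brute-force scan wherever both are computable.
    """
    if l_min < 1:
        raise ValueError("l_min must be at least 1")
    if l_min > l_max:
        return []
    M = system.M
    exponent = 1.0 / (M - 1)
    g1, K1 = min_max_gap(1, system)
    found: list[tuple[int, float, tuple]] = [(1, g1, K1)]

    # extend outward until the stopping condition is reachable
    for _ in range(500):
        l_z, g_z, _ = found[-1]
        if g_z <= 0 or l_z >= l_max or (stop_gap is not None and g_z < stop_gap):
            break
        if stop_gap is not None:
            # forecast of the distance at which the gap reaches stop_gap,
            # assuming the generic decay exponent; expanded below if short
            l_est = min(float(l_max), l_z * (g_z / stop_gap) ** (M - 1) + 1)
        else:
            l_est = float(l_max)
        step = None
        while True:
            eps = g_z / max(l_est, l_z + 1)
            step = _solve(system, eps, hint=g_z, node_cap=node_cap)
            if step is not None and step[0] > l_z:
                break
            if l_est >= l_max - 1e-9:
                step = None  # no further record up to l_max
                break
            l_est = min(float(l_max), l_est * 32)
        if step is None:
            break
        found.append(step)

    # certify adjacency / recover skipped records by breakpoint probing
    stack = [(found[i], found[i + 1]) for i in range(len(found) - 1)]
    records = {l: (g, K) for l, g, K in found}
    guard = 0
    while stack:
        guard += 1
        if guard > 10000:
            warnings.warn("record sweep certification budget exhausted",
                          RuntimeWarning, stacklevel=2)
            break
        (l_a, g_a, K_a), (l_b, g_b, K_b) = stack.pop()
        if l_b <= l_a + 1 or g_a <= 0:
            continue
        eps = g_a / l_b
        step = _solve(system, eps, hint=g_a, node_cap=node_cap)
        if step is None:
            continue
        l_c, g_c, K_c = step
        objective = max(l_c * eps, g_c)
        if l_c in records or not (l_a < l_c < l_b) or objective >= g_a * (1 - 1e-9):
            continue  # adjacent pair certified
        records[l_c] = (g_c, K_c)
        stack.append(((l_a, g_a, K_a), (l_c, g_c, K_c)))
        stack.append(((l_c, g_c, K_c), (l_b, g_b, K_b)))

    out = []
    best = math.inf
    for l in sorted(records):
        g, K = records[l]
        if g < best * (1 - RECORD_RTOL) or not math.isfinite(best):
            best = g
            if l_min <= l <= l_max:
                out.append(InterferenceRecord(l, K, g, g * l**exponent))
    return out
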