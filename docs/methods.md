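# Methods

## The model

A grid-cell system is a set of M modules with spatial periods (scales)
`alpha_0 = 1 < alpha_1 < ... < alpha_{M-1}`, distances measured in units of
the smallest period.  Module `i` represents position `x` through its phase
`psi_i(x) = (x mod alpha_i)/alpha_i`, and an ideal observer reads each phase
with the same relative error `delta` (so module `i` pins the position to
within `delta * alpha_i`).  Position coding is ambiguous at distance `x`
when every module is simultaneously near phase zero; because the firing
fields within a module are evenly spaced, it suffices to test integer
distances `l` (a confusable pair `x_1, x_2` implies `|x_1 - x_2|` is
confusable with the origin, and that requires it to be near a multiple of
`alpha_0 = 1`).

Interference at `l` is a simultaneous Diophantine approximation event: there
must be integers `K = (k_0 = l, k_1, ..., k_{M-1})` with

    |k_i alpha_i - k_j alpha_j| < (alpha_i + alpha_j) * delta   for all pairs i < j.

The package works throughout with the minimal max pairwise normalised gap

    g(l) = min_{K, k0=l} max_{i<j} |k_i a_i - k_j a_j| / (a_i + a_j),

whose running minima ("record lows") are the only distances that matter: the
code first becomes ambiguous at noise level `delta` at the first record with
`g < delta`.  The scaled statistic `eps_hat(l) = g(l) * l^(1/(M-1))` removes
the universal Dirichlet decay, and its record values estimate the capacity
constant `c_A`, the base of the exponential coding range
`L_max = (c_A/delta)^(M-1)` (theoretical ceiling `c_A = 0.5`).

## Estimators of the capacity constant

Two estimators are provided and cross-checked against each other:

- **Record-window estimator** (`diophantine.c_hat_window`): `l_2` is the
  first record with `g < delta_2`, `l_1` the first with `g < delta_1`
  (`delta_1 < delta_2`); the estimate is the minimum of the scaled records
  in `[l_2, l_1]`.  The noise window `[delta_1, delta_2]` delimits the
  distance range a system with that noise level actually probes, which is
  what makes the estimate well defined for non-algebraic scales whose
  asymptotic constant is 0.  The "finitely many small-`l` exceptions" of the
  algebraic lower bounds are excluded automatically because records before
  `l_2` fall outside the window — no exception list exists anywhere.
- **Coding-range scan** (`diophantine.c_hat_from_lmax_scan`): the infimum
  over a geometric noise grid (>= 50 points per decade) of
  `delta * L_max(delta)^(1/(M-1))`, with `L_max(delta)` the first ambiguous
  integer.  `L_max` is defined as the *first ambiguous* distance (not the
  last unambiguous one); with that convention the two estimators agree to
  well under 5% on badly-approximable systems, and the golden-ratio system
  yields 0.2755 -> printed 0.28, matching the closed form
  `sigma/(sqrt(5)(1+sigma)) = 0.27639...`.

Records are tie-broken by keeping the first `l` attaining a new minimum; a
new record must additionally undercut the running minimum by a relative
margin of 1e-9, below which two gaps are numerically indistinguishable ties.
This single convention keeps the brute-force and lattice record sequences
identical.

## Brute force and its reach

The direct scan (`diophantine.record_lows_M`) vectorises a per-module lower
bound `max_i ||l/alpha_i|| * alpha_i/(1+alpha_i) <= g(l)` over chunks of
distances and runs the exact branch-and-bound minimisation over the
candidate multiples `k_i in {floor(l/a_i)-1, ..., ceil(l/a_i)+1}` only where
the bound undercuts the current record.  Any multiple within module reach of
`x ~ l` must be one of the two nearest ones; the extra +-1 guards against
boundary rounding.  The scan is capped at `l = 1e7` (double precision keeps
the absolute gap error near `l * 1e-16`, comfortably below the gaps of
interest there); beyond the cap the lattice backend takes over.

## The lattice backend

Vectors of the interference lattice have one coordinate per module pair,
equal to the normalised pair gap, plus a penalty coordinate `l * eps`
(`lattice.build_basis`; for M modules the matrix is M rows by
`M(M-1)/2 + 1` columns, the numerator row carrying `-1/(1+alpha_j)` in the
module-0 pair columns and `eps` in the penalty column).  The sup-norm
shortest nonzero vector therefore minimises `max(l*eps, g(l))`, and sweeping
the penalty weight walks the optimum down the record sequence.

Rather than a fixed penalty schedule, the sweep performs an exact
parametric search.  As a function of `eps`, the optimiser is a step function
over the records: a record `(l, g)` beats its successor `(l', g')` exactly
on `eps > g/l'` and its predecessors on `eps <= g_prev/l`, so each record
wins on a nonempty interval and non-records never win.  The breakpoint
between adjacent records `(l_a, g_a)` and `(l_b, g_b)` sits at
`eps* = g_a/l_b`, where both achieve objective `g_a`; any record strictly
between them achieves strictly less there.  Probing exactly at `eps*`
therefore either certifies that the pair is adjacent or exposes a skipped
record, and the complete sequence is recovered with about two
shortest-vector calls per record.  (A fixed geometric schedule with factor
1/2 can provably skip records whose win interval has width ratio `l'/l < 2`
— the golden ratio's Fibonacci records, ratio 1.618, are the canonical
counterexample — which is why the parametric search is used instead.)

Each shortest-vector call LLL-reduces the basis (own implementation, Lovász
parameter 0.99 — the lattices have rank <= ~11, so the strong reduction is
essentially free) and then enumerates integer coefficient vectors
branch-and-bound style with Euclidean pruning radii from the reduced
Gram–Schmidt data, warm-started from a known achievable bound (the
neighbouring record's objective).  Two structural facts keep the
enumeration small: the module-0 pair columns plus the penalty column form a
full-rank square subsystem, so pruning can run in that M-dimensional
projection (radius `sqrt(M) * U` instead of `sqrt(M(M-1)/2+1) * U`) with
the full sup norm checked only at leaves; and every improvement shrinks the
radius.  The inner loop is numba-compiled.  Reported gaps are always
recomputed from the witness `K` directly (at mpmath precision for symbolic
scales beyond `l = 1e6`), never read off floating-point lattice
coordinates.

Precision: float64 reduction is reliable while the LLL size-reduction
coefficients (~ objective/eps) stay small enough that their rounding noise
is far below the objective; the implementation switches to mpmath
arithmetic when `eps < 1e-13 / objective-scale`, and falls back to mpmath
whenever the float path cannot reproduce a known-achievable bound.  With
the enumeration slack tied to the estimated float error, records computed
this way match the brute-force scan exactly on every system where both are
computable (a standing test).

## Spiking calibration of the module noise

`delta` is not free: it is what an ideal observer achieves.  The simulation
follows the standard calibration: a 1-D Brownian walk (`dt = 1 ms`,
`D = 0.005 m^2/s`, giving 5 cm RMS displacement in 0.5 s), N grid cells
with tuning `r_k(x) = r_max sin^n(pi x/lambda - phi_k) + r_0`
(`r_max = 15 Hz`, `r_0 = 0.1 Hz`, `lambda = 0.25 m`, `n = 22`; the even
exponent keeps rates nonnegative and its value sets the spatial mean rate
to `15 * C(22,11)/2^22 + 0.1 = 2.62 Hz`, near the experimentally observed
2.5 Hz), preferred phases deterministically equally spaced on `[0, 2 pi)`,
and Poisson spike counts per 1 ms bin.  The recursive Bayes filter keeps a
B = 256-bin posterior over the phase circle `[0, lambda)`: per step, exact
wrapped-Gaussian diffusion applied in the Fourier domain (multiplying mode
`m` by `exp(-(sigma_rad m)^2/2)` — no truncated kernel, so even diffusion
much narrower than a bin accumulates correctly), pointwise multiplication
by the Poisson likelihood, renormalisation (with a log-domain fallback so
the posterior can never underflow to zero).  Each step the posterior is
summarised by its circular resultant; the von Mises concentration comes
from exact table inversion of `R = I1(kappa)/I0(kappa)`.

The relative width is `delta_t = 1/(2 pi sqrt(kappa_t))` — the von Mises
standard deviation in radians over the full cycle.  (The printed form of
this relation in the source literature carries a spurious `lambda` and is
dimensionally inconsistent for a relative width; the form used here
reproduces both calibration anchors.)  The module's `delta` is the 99th
percentile (linear-interpolation quantile) of the post-burn-in `delta_t`
series; runs are 100 s (1e5 steps) with 1 s burn-in, which stabilises the
percentile to a few percent across seeds.  The small module
(`lambda = 0.25 m`, N = 10) gives `delta ~= 0.12`; the large module
(`lambda = 2.5 m`, N = 300) is simulated on the same 0.25 m geometry with
the walk slowed tenfold (`D = 0.00005 m^2/s`) — the relative width is
dimensionless, so this is exactly the 2.5 m module — and gives
`delta ~= 0.01`.

What the generator does *not* emulate: 2-D trajectories and triangular
grids (the axis-aligned planar problem reduces to this 1-D one),
non-Poisson spiking, heterogeneous or learned tuning curves, and phase
drift between modules.  Passing tests therefore validate the ideal-observer
calibration pipeline, not biological variability beyond Poisson noise.

## Robustness and asymptotic experiments

Random scale systems come from three samplers (geometric ratio uniform on
an interval; the same with i.i.d. +-1% multiplicative jitter per scale;
fully i.i.d. scales), each system drawn from its own child generator of the
experiment seed so the modes agree draw-by-draw and zero jitter reduces
exactly to the geometric mode.  The robustness experiment estimates
`c_hat` per system with the window estimator over `0.05 < delta < 0.2`
(the realistic noise band from the spiking calibration) and reports the
mean and coefficient of variation; with M = 10 the estimates use the
lattice backend, since the window reaches distances near
`(c/0.05)^9 ~ 1e7..1e9`.

The Monte-Carlo check of the asymptotic statement draws M scales i.i.d.
uniform on `[1, alpha_max]` and tests all integers up to
`X_max = (zeta/delta)^(M-1)` for simultaneous interference
(`||l/alpha_i|| < delta` for every module) — integers only, consistent with
the integer-distance reduction; the epsilon-dense grid of the proof is an
analysis device.  The empirical failure fraction is reported with its
binomial standard error and compared in order of magnitude with
`(2 zeta)^M`.

The information-rate comparisons are closed forms, normalised so the
equal-population rate is 1 at `c/delta = e` and `r_bar N = 1`: equal-size
modules give a rate independent of M; geometrically shrinking populations
(`n_i = n_0/alpha^{2i}`, total `n_0 alpha^2/(alpha^2-1)`) make it linear in
M.  A configuration with `c <= delta` is rejected: the modulo-arithmetic
code is only favoured when the coding range exceeds one period.

## Problem sizes used in the test suite

Chosen so that the full suite and the acceptance script each run in
minutes on one CPU, while every claim is still exercised in the regime
where it is nontrivial: record scans to `l = 1e4` for the
lattice-vs-brute-force equivalence (20 random systems, M in {2, 3});
`l = 1e5` for the order-10 algebraic slope (-1/9); powers of
`sigma - 1/2` at M = 5 with the lattice sweep to `l = 1e9` for the
crossover to the second-order `1/l` regime (the crossover distance grows
with M, so M = 5 shows at accessible distances the same phenomenon that
M = 10 shows near `l = 1e6..1e8`); 50 random M = 10 systems for the
robustness band; 3 seeds of 1e5 filter steps per spiking anchor; 200
random instances for the integer-distance/position-scan equivalence.

## Known limitations

- `c_hat` for non-algebraic scales depends on the noise window by
  construction (the true asymptotic constant is 0); always report the
  window alongside the value.
- Hairline record ties (relative gap difference below 1e-9) are resolved by
  the first-`l` convention; which side of the tie is reported can differ
  from an infinite-precision scan, with effect below 1e-9 on any estimate.
- The sup-norm enumeration certifies optimality only within its node budget
  (default 1e8); exhaustion raises rather than silently degrading.
- The Bayes filter assumes the generative parameters (D, tuning curves) are
  known to the observer; it calibrates an ideal-observer bound, not a
  biologically attainable decoder.
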