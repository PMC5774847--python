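# gridcode

Capacity and robustness of modular grid-cell phase codes, measured through
simultaneous Diophantine approximation.

Grid cells in the rodent entorhinal cortex are organised into modules, each
firing periodically in space with its own period (scale) α.  The joint phase
vector `ψ_i(x) = (x mod α_i)/α_i` of M modules can represent position far
beyond the largest period — a modulo-arithmetic code — until two distant
locations acquire indistinguishable phase vectors.  With per-module phase
noise δ, ambiguity at integer distance ℓ is a number-theoretic event: some
integer vector K with k₀ = ℓ satisfies `|k_i α_i − k_j α_j| < (α_i + α_j) δ`
for every module pair.  The package computes the minimal max pairwise gap

    g(ℓ) = min_{K, k₀=ℓ} max_{i<j} |k_i α_i − k_j α_j| / (α_i + α_j),

its record lows, and the capacity constant ĉ estimated from the scaled
statistic `ε̂(ℓ) = g(ℓ)·ℓ^{1/(M−1)}`.  The constant is the base of the
exponential coding range `L_max = (ĉ/δ)^{M−1}` (ceiling 0.5).  It answers:
how far does the code reach, how much does that depend on choosing the
scales well, and what δ does a spiking module actually achieve?

For whom: computational neuroscientists studying population codes for
space, and anyone interested in the numerics of simultaneous Diophantine
approximation with a common numerator (record lows, badly approximable
vectors, sup-norm shortest lattice vectors).

## What is inside

- `gridcode.core` — scale systems (numeric or exact symbolic: `phi`,
  `2^(1/3)`, `root:x^10-x^7-1`), phases, the interference predicate, and
  direct coding-range scans.
- `gridcode.diophantine` — record-low scans, the record-window and
  coding-range-scan estimators of ĉ, Hurwitz-bound diagnostics.
- `gridcode.lattice` — the large-distance backend: interference lattice
  with a penalty column, LLL reduction, exact sup-norm shortest-vector
  search, and an exact parametric penalty sweep that recovers the record
  sequence out to ℓ ~ 10⁹.
- `gridcode.neural` — spiking calibration of δ: Brownian walk, Poisson
  grid-cell rasters, a circular recursive Bayes filter, von Mises widths
  (this module doubles as the package's synthetic-data generator).
- `gridcode.capacity` — robustness over random scale choices, Monte-Carlo
  check of the random-scale asymptotics, information-rate comparisons.
- `gridcode.cli` — a thin `gridcode` command (`chat`, `records`,
  `neural-delta`, `robustness`, `montecarlo`, `coding-range`).
- `examples/` — short narrative scripts, one per capability.

## Worked example

```python
from gridcode import NoiseModel, ScaleSystem, coding_range
from gridcode.diophantine import c_hat_window

for label, tokens in [("golden ratio", ["1", "phi"]),
                      ("rational 3/2", ["1", "3/2"]),
                      ("e", ["1", "e"])]:
    est = c_hat_window(ScaleSystem.from_symbolic(tokens), 0.001, 0.05)
    print(f"{label:13s}  c_hat = {est.value:.4f} (prints as {est.rounded})")

system = ScaleSystem.from_symbolic(["1", "phi"])
for delta in (0.05, 0.01, 0.001):
    print(f"delta = {delta:5.3f}  ->  L_max = {coding_range(system, NoiseModel(delta))}")
```

prints

```
golden ratio   c_hat = 0.2755 (prints as 0.28)
rational 3/2   c_hat = 0.0000 (prints as 0.0)
e              c_hat = 0.1033 (prints as 0.1)
delta = 0.050  ->  L_max = 7
delta = 0.010  ->  L_max = 33
delta = 0.001  ->  L_max = 376
```

The golden ratio attains the two-module optimum `σ/(√5(1+σ)) ≈ 0.276` —
the printed 0.28 — so with 0.1% phase noise two modules of unit and σ
period disambiguate ~376 periods.  A rational ratio collapses (exact
interference at ℓ = 3 no matter how small the noise), and a transcendental
ratio like e sits in between, its ĉ genuinely window-dependent.  With ten
modules the picture reverses: almost any random geometric progression on
(1, 2) lands in ĉ ∈ [0.2, 0.4] (see
`examples/random_scale_robustness.py`), so no tuning of the scales is
needed — the robustness the theory promises.

The same from the shell:

```
gridcode chat --scales 1,phi --delta 0.001:0.05
gridcode neural-delta --cells 10 --steps 100000
gridcode robustness --modules 10 --draws 50 --delta 0.05:0.2
```

## Documentation

`docs/methods.md` describes the model and its assumptions, both ĉ
estimators, the lattice sweep and its precision safeguards, the Bayes
filter, the defaults and the problem sizes, and known limitations.
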