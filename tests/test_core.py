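"""Phase arithmetic and the interference predicates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridcode import (
    NoiseModel,
    PhaseVector,
    ScaleSystem,
    ambiguous_at_integer,
    ambiguous_at_x_bruteforce,
    circ_norm,
    first_ambiguous_integer,
    golden_identity,
    min_max_gap,
    pairwise_gap,
    phase,
)
from gridcode.core import parse_scale

from .conftest import random_system

SIGMA = (1 + math.sqrt(5)) / 2


class TestPhase:
    @pytest.mark.parametrize("x,alpha,expected", [
        (2.3, 1.0, 0.3),      # both modules around phase 0.3 at distance 2.3
        (3.0, 1.5, 0.0),      # perfect interference: 3 = 2 * (3/2)
        (0.0, 2.71, 0.0),     # origin has zero phase in every module
    ])
    def test_examples(self, x, alpha, expected):
        assert phase(x, alpha) == pytest.approx(expected, abs=1e-12)

    def test_high_precision_path_at_large_x(self):
        # double precision would lose ~7 digits at x ~ 1e9; mpmath must not
        import mpmath
        with mpmath.workdps(40):
            p = phase(mpmath.mpf("1000000000.3"), 1, precision=30)
            assert abs(p - mpmath.mpf("0.3")) < 1e-25

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            phase(1.0, 0.0)
        with pytest.raises(ValueError):
            phase(1.0, -2.0, precision=30)

    @given(st.floats(0, 1e6), st.floats(0.1, 10))
    @settings(max_examples=100, derandomize=True)
    def test_output_range(self, x, alpha):
        assert 0 <= phase(x, alpha) < 1


class TestCircNorm:
    @pytest.mark.parametrize("psi,expected", [
        (0.944, 0.056), (0.3, 0.3), (1.0, 0.0), (-0.25, 0.25), (7.5, 0.5),
    ])
    def test_examples(self, psi, expected):
        assert circ_norm(psi) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-100, 100))
    @settings(max_examples=100, derandomize=True)
    def test_range_and_symmetry(self, psi):
        v = circ_norm(psi)
        assert 0 <= v <= 0.5
        assert circ_norm(-psi) == pytest.approx(v, abs=1e-9)


class TestPairwiseGap:
    def test_rational_perfect_interference(self, rational2):
        assert pairwise_gap((3, 2), rational2) == pytest.approx(0.0, abs=1e-15)

    def test_golden_example(self, sigma2):
        # |3*sigma - 5| / (1 + sigma), evaluated independently at high precision
        expected = abs(3 * SIGMA - 5) / (1 + SIGMA)
        got = pairwise_gap((5, 3), sigma2)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.055728090000841, rel=1e-9)

    def test_zero_vector(self):
        assert pairwise_gap((0, 0), ScaleSystem((1.0, 1.7))) == 0.0

    def test_length_mismatch(self, sigma3):
        with pytest.raises(ValueError):
            pairwise_gap((1, 1), sigma3)

    def test_mp_path_agrees_with_float(self, sigma3):
        K = (8, 5, 3)
        assert float(pairwise_gap(K, sigma3, dps=40)) == pytest.approx(
            pairwise_gap(K, sigma3), rel=1e-12)


class TestAmbiguity:
    def test_rational_ambiguous_at_three(self, rational2):
        flag, K = ambiguous_at_integer(3, rational2, NoiseModel(0.1))
        assert flag and K == (3, 2)

    def test_golden_not_ambiguous_at_five_low_noise(self, sigma2):
        # eps(5) = ||5/sigma|| ~ 0.090 exceeds (1+a)delta/a ~ 0.0162
        flag, K = ambiguous_at_integer(5, sigma2, NoiseModel(0.01))
        assert not flag and K is None

    def test_neighbouring_integers_interfere_at_high_noise(self):
        flag, _ = ambiguous_at_integer(1, ScaleSystem((1.0, 1.9)), NoiseModel(0.4))
        assert flag

    def test_x_scan_localises_rational_interference(self, rational2):
        noise = NoiseModel(0.1)
        xs = ambiguous_at_x_bruteforce(rational2, noise, 4.0, 0.02)
        assert len(xs) > 0
        assert np.all(np.abs(xs - 3.0) <= noise.delta * (1 + 1.5))

    def test_x_scan_empty_for_golden_triple(self, sigma3):
        xs = ambiguous_at_x_bruteforce(sigma3, NoiseModel(0.05), 7.0, 0.01)
        assert len(xs) == 0

    def test_x_scan_trivially_empty_below_one(self, sigma2):
        xs = ambiguous_at_x_bruteforce(sigma2, NoiseModel(0.2), 0.79, 0.05)
        assert len(xs) == 0

    def test_x_scan_step_contract(self, sigma2):
        with pytest.raises(ValueError):
            ambiguous_at_x_bruteforce(sigma2, NoiseModel(0.1), 5.0, 0.2)


class TestFirstAmbiguous:
    @pytest.mark.parametrize("scales,delta,expected", [
        (("1", "3/2"), 0.05, 3),
        (("1", "phi"), 0.2, 2),
    ])
    def test_examples(self, scales, delta, expected):
        system = ScaleSystem.from_symbolic(scales)
        assert first_ambiguous_integer(system, NoiseModel(delta)) == expected

    def test_none_below_cap(self, sigma2):
        # L_max ~ 0.276/0.001 ~ 276 exceeds the cap of 100
        assert first_ambiguous_integer(sigma2, NoiseModel(0.001), l_cap=100) is None

    def test_monotone_in_delta(self, sigma2):
        deltas = [0.01, 0.02, 0.05, 0.1, 0.2, 0.3]
        firsts = [first_ambiguous_integer(sigma2, NoiseModel(d), l_cap=10**4)
                  for d in deltas]
        assert all(f is not None for f in firsts)
        assert all(a >= b for a, b in zip(firsts, firsts[1:]))


class TestClaimEquivalence:
    """Integer-distance pairwise interference == existence of a confusable x."""

    def test_random_instances(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 200:
            M = int(rng.integers(2, 5))
            system = random_system(rng, M)
            delta = float(rng.uniform(0.05, 0.2))
            l = int(rng.integers(1, 40))
            gap, _ = min_max_gap(l, system)
            if abs(gap - delta) < 0.05 * delta:
                continue  # below grid resolution; regenerate
            flag, _ = ambiguous_at_integer(l, system, NoiseModel(delta))
            step = delta / 8
            xs = ambiguous_at_x_bruteforce(system, NoiseModel(delta), l + 0.6, step)
            near = xs[np.abs(xs - l) < 0.5] if len(xs) else xs
            assert flag == (len(near) > 0), (system.scales, delta, l)
            checked += 1

    def test_two_module_closed_form(self):
        # ambiguity at l <=> ||l/alpha|| < (1+alpha) delta / alpha
        rng = np.random.default_rng(7)
        for _ in range(100):
            alpha = float(rng.uniform(1.05, 2.5))
            delta = float(rng.uniform(0.01, 0.2))
            l = int(rng.integers(1, 10**4))
            system = ScaleSystem((1.0, alpha))
            flag, _ = ambiguous_at_integer(l, system, NoiseModel(delta))
            predicted = circ_norm(l / alpha) < (1 + alpha) * delta / alpha
            assert flag == predicted

    def test_confusable_pairs_map_to_ambiguous_integers(self, rational2):
        # if x1, x2 are mutually confusable then |x1-x2| sits near an
        # ambiguous integer (here: 3, the exact interference of {1, 3/2})
        delta = 0.08
        xs = np.arange(0.0, 4.5, delta / 8)
        amb = []
        for i, x1 in enumerate(xs):
            d = xs[i + 1:] - x1
            sep = d[(circ_norm(d / 1.0) < delta) & (circ_norm(d / 1.5) < delta) & (d > 0.5)]
            amb.extend(sep)
        assert amb and np.all(np.abs(np.asarray(amb) - 3.0) <= delta * (1 + 1.5))


class TestGoldenIdentity:
    def test_identity_at_eight(self):
        assert float(golden_identity(8)) < 1e-25
        # and the common phase at 8 is ~0.0557: the triple nearly coincides
        assert float(phase(8, SIGMA * SIGMA)) == pytest.approx(0.0557, abs=2e-3)

    def test_trivial_points(self):
        assert float(golden_identity(0)) < 1e-25
        assert float(golden_identity(SIGMA)) < 1e-15

    def test_random_positions(self):
        rng = np.random.default_rng(3)
        for x in rng.uniform(0, 10**6, 200):
            assert float(golden_identity(float(x), precision=30)) < 1e-12


class TestScaleSystem:
    def test_invariants(self):
        with pytest.raises(ValueError):
            ScaleSystem((1.0,))
        with pytest.raises(ValueError):
            ScaleSystem((1.5, 2.0))
        with pytest.raises(ValueError):
            ScaleSystem((1.0, 0.5))
        with pytest.raises(ValueError):
            ScaleSystem((1.0, 1.3, 1.3))
        with pytest.raises(ValueError):
            ScaleSystem((1.0, 1.5), symbolic=("1", "phi"))

    def test_json_roundtrip(self, tmp_path, sigma3):
        path = tmp_path / "system.json"
        sigma3.save(path)
        back = ScaleSystem.load(path)
        assert back.scales == sigma3.scales
        assert back.precision == sigma3.precision
        assert [str(s) for s in back.symbolic] == [str(s) for s in sigma3.symbolic]

    def test_symbolic_tokens(self):
        assert float(parse_scale("phi").evalf()) == pytest.approx(SIGMA)
        assert float(parse_scale("sqrt2").evalf()) == pytest.approx(math.sqrt(2))
        assert float(parse_scale("root:x^10-x^7-1").evalf()) == pytest.approx(1.127247, abs=1e-5)
        assert float(parse_scale("2^(1/3)").evalf()) == pytest.approx(2 ** (1 / 3))

    def test_phase_vector(self, sigma2):
        pv = PhaseVector.at(2.3, sigma2)
        assert pv.psi[0] == pytest.approx(0.3)
        assert all(0 <= p < 1 for p in pv.psi)
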