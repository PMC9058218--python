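"""Eyring rates and Eckart (ZCT-0) tunneling transmission coefficients."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radscav.constants import GAS_CONSTANT, WAVENUMBER_TO_J_MOL, eyring_prefactor
from radscav.core import Mechanism, Pathway, RateMethod
from radscav.synthetic import BENZENE, WATER
from radscav.tst import (
    EckartBarrier,
    eckart_kappa,
    eckart_transmission,
    eyring_rate,
    rate_for_pathway,
    temperature_profile,
)


class TestEyring:
    def test_zero_barrier_gives_prefactor(self):
        assert eyring_rate(0.0) == pytest.approx(6.2124e12, rel=5e-5)

    def test_34_kj_barrier(self):
        # frozen from direct evaluation of (k_B T / h) exp(-dG/RT)
        assert eyring_rate(34.0) == pytest.approx(6.866253e6, rel=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        dg=st.floats(min_value=0.0, max_value=200.0),
        sigma=st.integers(min_value=1, max_value=6),
        T=st.floats(min_value=200.0, max_value=400.0),
    )
    def test_matches_direct_product_evaluation(self, dg, sigma, T):
        """Log-space assembly agrees with the naive product to 12 digits."""
        direct = sigma * eyring_prefactor(T) * math.exp(-dg * 1000.0 / (GAS_CONSTANT * T))
        assert eyring_rate(dg, T, degeneracy=sigma) == pytest.approx(direct, rel=1e-12)

    def test_degeneracy_is_linear(self):
        assert eyring_rate(34.0, degeneracy=2) == pytest.approx(2 * eyring_rate(34.0))

    def test_negative_barrier_warns_but_computes(self):
        with pytest.warns(UserWarning, match="negative activation"):
            k = eyring_rate(-5.0)
        assert k > eyring_prefactor(298.15)


def oracle_kappa(barrier: EckartBarrier, T: float, n: int = 200_000) -> float:
    """Independent fine-grid trapezoid of the Boltzmann-averaged transmission.

    Uses the plain cosh form of the asymmetric Eckart probability (safe for
    the moderate parameters exercised here), not the package's log-space path.
    """
    RT = GAS_CONSTANT * T
    vf = barrier.forward_barrier * 1000.0
    vr = barrier.reverse_barrier * 1000.0
    hnu = barrier.imag_freq * WAVENUMBER_TO_J_MOL
    a1, a2 = 2 * math.pi * vf / hnu, 2 * math.pi * vr / hnu

    def prob(E):
        if E <= max(0.0, vf - vr):
            return 0.0
        den = 1 / math.sqrt(a1) + 1 / math.sqrt(a2)
        a = 2 * math.sqrt(a1 * E / vf) / den
        b = 2 * math.sqrt(a1 * E / vf - a1 + a2) / den
        disc = a1 * a2 - math.pi**2 / 4
        ch_d = math.cosh(2 * math.sqrt(disc)) if disc >= 0 else math.cos(2 * math.sqrt(-disc))
        return 1 - (math.cosh(a - b) + ch_d) / (math.cosh(a + b) + ch_d)

    grid = np.linspace(max(0.0, vf - vr), vf + 25 * RT, n)
    vals = np.array([prob(e) * math.exp((vf - e) / RT) for e in grid]) / RT
    return float(np.trapezoid(vals, grid))


class TestEckart:
    def test_classical_limit_small_frequency(self):
        """A vanishing imaginary frequency removes tunneling: kappa -> 1."""
        kappa = eckart_kappa(EckartBarrier(30.0, 30.0, 1.0))
        assert kappa == pytest.approx(1.0, abs=1e-3)

    def test_high_temperature_limit(self):
        kappa = eckart_kappa(EckartBarrier(30.0, 30.0, 1000.0), T=3000.0)
        assert kappa == pytest.approx(1.0, rel=0.05)

    def test_symmetric_barrier_matches_trapezoid_oracle(self):
        barrier = EckartBarrier(30.0, 30.0, 1500.0)
        kappa = eckart_kappa(barrier)
        assert kappa == pytest.approx(oracle_kappa(barrier, 298.15), rel=1e-4)

    @pytest.mark.parametrize(
        "vf,vr,nu",
        [(20.0, 40.0, 800.0), (45.0, 15.0, 1200.0), (60.0, 60.0, 2000.0)],
    )
    def test_asymmetric_barriers_match_oracle(self, vf, vr, nu):
        barrier = EckartBarrier(vf, vr, nu)
        assert eckart_kappa(barrier) == pytest.approx(oracle_kappa(barrier, 298.15), rel=1e-4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        vf=st.floats(min_value=10.0, max_value=80.0),
        vr=st.floats(min_value=10.0, max_value=80.0),
        nu=st.floats(min_value=100.0, max_value=2500.0),
    )
    def test_kappa_at_least_one(self, vf, vr, nu):
        assert eckart_kappa(EckartBarrier(vf, vr, nu)) >= 1.0 - 1e-9

    def test_kappa_decreases_with_temperature(self):
        barrier = EckartBarrier(30.0, 30.0, 1500.0)
        assert eckart_kappa(barrier, 280.0) > eckart_kappa(barrier, 320.0)

    def test_kappa_increases_with_frequency(self):
        assert eckart_kappa(EckartBarrier(30.0, 30.0, 1800.0)) > eckart_kappa(
            EckartBarrier(30.0, 30.0, 900.0)
        )

    def test_transmission_zero_below_product_asymptote(self):
        barrier = EckartBarrier(50.0, 20.0, 1000.0)
        assert eckart_transmission(barrier, 10.0) == 0.0  # below vf - vr = 30

    def test_stiff_barrier_does_not_overflow(self):
        # huge alpha: cosh arguments far beyond float range without log-space
        kappa = eckart_kappa(EckartBarrier(150.0, 150.0, 50.0))
        assert math.isfinite(kappa) and kappa >= 1.0


class TestDispatch:
    def test_barrierless_water_pathway_gets_diffusion_rate(self):
        p = Pathway(Mechanism.RAF, "3-C,5-C", "X", -33.8, barrierless=True, degeneracy=2)
        row = rate_for_pathway(p, WATER)
        assert row.method is RateMethod.DIFFUSION
        assert row.k == pytest.approx(1.91e9)

    def test_activated_hat_without_frequency_is_plain_tst(self):
        p = Pathway(Mechanism.HAT, "1-OH", "X", -118.7, delta_G_act=34.0)
        row = rate_for_pathway(p, BENZENE)
        assert row.method is RateMethod.TST_PLAIN
        assert row.kappa == 1.0
        assert row.k == pytest.approx(6.866253e6, rel=1e-6)

    def test_hat_with_frequency_gets_eckart_boost(self):
        p = Pathway(
            Mechanism.HAT, "1-OH", "X", -118.7, delta_G_act=34.0,
            imag_freq=1500.0, reverse_barrier=150.0,
        )
        row = rate_for_pathway(p, BENZENE)
        assert row.method is RateMethod.TST_ECKART
        assert row.kappa > 1.0
        assert row.k == pytest.approx(row.kappa * 6.866253e6, rel=1e-6)

    def test_electron_transfer_goes_through_marcus(self):
        p = Pathway(Mechanism.ET, "ring", "X", -30.0, vertical_energy=40.0)
        row = rate_for_pathway(p, WATER)
        assert row.method is RateMethod.MARCUS
        assert row.delta_G_act_marcus is not None and row.k_activation is not None
        assert row.k <= 1.91e9 * (1 + 1e-12)

    def test_activated_pathway_missing_barrier_raises(self):
        p = Pathway(Mechanism.RAF, "2-C", "X", -30.0)
        with pytest.raises(ValueError, match="missing delta_G_act"):
            rate_for_pathway(p, BENZENE)

    def test_rate_rows_are_per_site(self):
        """Degeneracy multiplies in aggregation, not in the rate row."""
        p1 = Pathway(Mechanism.HAT, "a", "X", -100.0, delta_G_act=34.0, degeneracy=1)
        p3 = Pathway(Mechanism.HAT, "b", "X", -100.0, delta_G_act=34.0, degeneracy=3)
        assert rate_for_pathway(p1, BENZENE).k == rate_for_pathway(p3, BENZENE).k


class TestTemperatureProfile:
    def test_monotone_increasing_without_tunneling(self):
        p = Pathway(Mechanism.HAT, "1-OH", "X", -100.0, delta_G_act=34.0)
        pts = temperature_profile(p, [280.0, 298.15, 320.0])
        ks = [k for _, k in pts]
        assert ks == sorted(ks) and ks[0] < ks[-1]

    def test_single_point_reproduces_eyring(self):
        p = Pathway(Mechanism.HAT, "1-OH", "X", -100.0, delta_G_act=34.0)
        [(_, k)] = temperature_profile(p, [298.15])
        assert k == pytest.approx(eyring_rate(34.0))

    def test_tunneling_correction_larger_when_cold(self):
        p = Pathway(
            Mechanism.HAT, "1-OH", "X", -100.0, delta_G_act=34.0,
            imag_freq=1500.0, reverse_barrier=120.0,
        )
        barrier = EckartBarrier(34.0, 120.0, 1500.0)
        assert eckart_kappa(barrier, 280.0) > eckart_kappa(barrier, 320.0)
        pts = dict(temperature_profile(p, [280.0, 320.0]))
        assert pts[320.0] > pts[280.0]  # Arrhenius still wins overall

    def test_empty_grid_is_an_error(self):
        p = Pathway(Mechanism.HAT, "1-OH", "X", -100.0, delta_G_act=34.0)
        with pytest.raises(ValueError, match="empty"):
            temperature_profile(p, [])
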