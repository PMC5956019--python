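"""Equilibrium math: binary depletion isotherm, exact ternary competition,
IC50 <-> K_i conversion, Mueller's binding-site equation.

The ternary solver is checked against an independent bisection oracle that
works on a different variable (free tracer rather than free sites).
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mstkit as mk
from mstkit.equilibria import bound_tracer
from mstkit.errors import DegenerateSystemError, DomainError, SolverError


def ternary_oracle(i0, t0, l0, kd, ki, iters=300):
    """Bisection on the bound-tracer concentration: independent of the
    solver's free-site root variable.

    Given bound tracer bt, mass action fixes the free sites
    r = kd*bt/(t0-bt), the bound competitor follows, and the site-balance
    residual r + bt + bl - i0 is strictly increasing in bt.
    """
    def site_residual(bt):
        ft = t0 - bt
        if ft <= 0:
            return float("inf")
        r = kd * bt / ft
        bound_l = l0 * r / (r + ki)
        return r + bt + bound_l - i0

    lo, hi = 0.0, min(t0, i0)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if site_residual(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)  # bound tracer


class TestBinaryBoundFraction:
    def test_no_antibody_means_nothing_bound(self):
        assert mk.binary_bound_fraction(0.0, 1.0, 5.0) == 0.0

    def test_hyperbolic_limit_half_saturation_at_kd(self):
        # vanishing tracer: f -> A/(A+Kd) = 1/2 at A = Kd
        f = mk.binary_bound_fraction(5.0, 5e-9, 5.0)
        assert f == pytest.approx(0.5, abs=1e-6)

    def test_stoichiometric_limit(self):
        f = mk.binary_bound_fraction(10.0, 10.0, 1e-12)
        assert f == pytest.approx(1.0, abs=1e-6)

    def test_zero_tracer_rejected(self):
        with pytest.raises(DegenerateSystemError):
            mk.binary_bound_fraction(1.0, 0.0, 5.0)

    @given(
        a=st.floats(1e-3, 1e6),
        t=st.floats(1e-3, 1e4),
        kd=st.floats(1e-2, 1e6),
    )
    def test_fraction_in_unit_interval_and_monotone_in_sites(self, a, t, kd):
        f = mk.binary_bound_fraction(a, t, kd)
        assert 0.0 <= f <= 1.0
        assert mk.binary_bound_fraction(2 * a, t, kd) >= f


class TestTernaryEquilibrium:
    def test_reduces_to_binary_without_competitor(self):
        st_ = mk.ternary_equilibrium(mk.TernarySystem(10.0, 0.25, 0.0, 5.0, 1.0))
        f = mk.binary_bound_fraction(10.0, 0.25, 5.0)
        assert st_.bound_tracer == pytest.approx(f * 0.25, rel=1e-10)

    def test_infinitely_weak_competitor_is_no_competitor(self):
        with_l = mk.ternary_equilibrium(mk.TernarySystem(10.0, 0.25, 100.0, 5.0, 1e12))
        without = mk.ternary_equilibrium(mk.TernarySystem(10.0, 0.25, 0.0, 5.0, 1e12))
        assert with_l.bound_tracer == pytest.approx(without.bound_tracer, rel=1e-6)

    def test_symmetry_between_equal_ligands(self):
        st_ = mk.ternary_equilibrium(mk.TernarySystem(7.0, 3.0, 3.0, 2.0, 2.0))
        assert st_.bound_tracer == pytest.approx(st_.bound_competitor, rel=1e-12)

    def test_against_bisection_oracle_reference_system(self):
        st_ = mk.ternary_equilibrium(mk.TernarySystem(10.0, 0.25, 100.0, 5.0, 1.0))
        expected = ternary_oracle(10.0, 0.25, 100.0, 5.0, 1.0)
        assert st_.bound_tracer == pytest.approx(expected, rel=1e-8)

    @given(
        i0=st.floats(1e-2, 1e3),
        t0=st.floats(1e-3, 1e2),
        l0=st.floats(0.0, 1e5),
        kd=st.floats(1e-2, 1e6),
        ki=st.floats(1e-2, 1e6),
    )
    def test_mass_conservation(self, i0, t0, l0, kd, ki):
        s = mk.ternary_equilibrium(mk.TernarySystem(i0, t0, l0, kd, ki))
        assert s.bound_tracer + s.free_tracer == pytest.approx(t0, rel=1e-9)
        assert s.bound_competitor + s.free_competitor == pytest.approx(l0, rel=1e-9, abs=1e-12)
        assert s.free_sites + s.bound_tracer + s.bound_competitor == pytest.approx(i0, rel=1e-9)
        for v in (s.free_sites, s.bound_tracer, s.bound_competitor, s.free_tracer, s.free_competitor):
            assert v >= 0

    def test_bound_tracer_monotonicity(self):
        base = bound_tracer(10.0, 0.25, 50.0, 5.0, 2.0)
        assert bound_tracer(10.0, 0.25, 100.0, 5.0, 2.0) < base  # more competitor
        assert bound_tracer(10.0, 0.25, 50.0, 5.0, 1.0) < base  # tighter competitor
        assert bound_tracer(20.0, 0.25, 50.0, 5.0, 2.0) > base  # more sites


class TestIc50Ki:
    def test_weak_competitor_ic50_diverges(self):
        ic50 = mk.ic50_from_ki(mk.TernarySystem(10.0, 0.25, 1.0, 5.0, 1e9))
        assert ic50 > 1e8

    def test_cheng_prusoff_limit(self):
        # negligible antibody: IC50 -> Ki * (1 + T0/Kd)
        ic50 = mk.ic50_from_ki(mk.TernarySystem(1e-6, 0.25, 1.0, 5.0, 2.0))
        assert ic50 == pytest.approx(2.0 * (1 + 0.25 / 5.0), rel=5e-3)

    def test_linearity_in_cheng_prusoff_regime(self):
        a = mk.ic50_from_ki(mk.TernarySystem(1e-6, 0.25, 1.0, 5.0, 2.0))
        b = mk.ic50_from_ki(mk.TernarySystem(1e-6, 0.25, 1.0, 5.0, 4.0))
        assert b / a == pytest.approx(2.0, rel=1e-3)

    def test_round_trip_identity(self):
        ic50 = mk.ic50_from_ki(mk.TernarySystem(10.0, 0.25, 8000.0, 4.58, 7.3))
        ki = mk.ki_from_ic50(4.58, 10.0, 0.25, 8000.0, ic50)
        assert ki == pytest.approx(7.3, rel=1e-6)

    @pytest.mark.parametrize("ki_true", np.geomspace(0.1, 1e4, 9).tolist())
    def test_round_trip_identity_across_affinity_decades(self, ki_true):
        # the standard competition design: 10 nM sites, 0.25 nM tracer
        ic50 = mk.ic50_from_ki(mk.TernarySystem(10.0, 0.25, 1e9, 7.65, ki_true))
        ki = mk.ki_from_ic50(7.65, 10.0, 0.25, 1e9, ic50)
        assert ki == pytest.approx(ki_true, rel=1e-6)

    def test_cheng_prusoff_inversion(self):
        ki = mk.ki_from_ic50(5.0, 1e-6, 0.25, 100.0, 2.1)
        assert ki == pytest.approx(2.0, rel=5e-3)

    def test_ki_monotone_in_ic50(self):
        kis = [
            mk.ki_from_ic50(4.58, 10.0, 0.25, 8000.0, ic50)
            for ic50 in np.geomspace(8.0, 5000.0, 12)
        ]
        assert np.all(np.diff(kis) > 0)

    def test_ic50_beyond_titration_range_rejected(self):
        with pytest.raises(DomainError, match="unidentifiable"):
            mk.ki_from_ic50(4.58, 10.0, 0.25, 100.0, 200.0)

    def test_ic50_below_zero_affinity_floor_rejected(self):
        # with 10 nM sites the competitor is consumed by binding, so even an
        # infinitely tight binder has a finite IC50; below it no Ki exists
        with pytest.raises(SolverError):
            mk.ki_from_ic50(7.65, 10.0, 0.25, 8000.0, 1.0)


class TestMuellerEquation:
    def test_zero_bound_means_zero_sites(self):
        assert mk.mueller_binding_sites(0.0, 5.0, 5.0) == 0.0

    def test_hand_computed_value(self):
        # b=0.5, Tt=5, Kd=5: 2.5 + 5*0.5/0.5 = 7.5 nM
        assert mk.mueller_binding_sites(0.5, 5.0, 5.0) == pytest.approx(7.5)

    def test_saturated_fraction_rejected(self):
        with pytest.raises(DomainError):
            mk.mueller_binding_sites(1.0, 5.0, 5.0)

    def test_exactly_inverts_binary_equilibrium(self):
        ab, t, kd = 12.0, 5.0, 3.0
        b = mk.binary_bound_fraction(ab, t, kd)
        assert mk.mueller_binding_sites(b, t, kd) == pytest.approx(ab, abs=1e-9)

    @given(ab=st.floats(0.1, 1e3), t=st.floats(1e-2, 1e2), kd=st.floats(1e-2, 1e3))
    def test_inversion_property(self, ab, t, kd):
        b = mk.binary_bound_fraction(ab, t, kd)
        assert mk.mueller_binding_sites(b, t, kd) == pytest.approx(ab, rel=1e-7)


class TestAverageBindingSites:
    def test_single_and_pair(self):
        assert mk.average_binding_sites([10.0]) == 10.0
        assert mk.average_binding_sites([8.0, 12.0]) == 10.0

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            mk.average_binding_sites([])

    def test_composition_with_mueller_round_trip(self):
        ests = [
            mk.mueller_binding_sites(mk.binary_bound_fraction(12.0, t, kd), t, kd)
            for t, kd in [(5.0, 3.0), (2.0, 0.5)]
        ]
        assert mk.average_binding_sites(ests) == pytest.approx(12.0, abs=1e-9)
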