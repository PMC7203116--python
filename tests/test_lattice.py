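"""Lattice arithmetic: pitch/rise/twist conversions, repeats, selection rule."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

import pilax as px
from pilax.lattice import rounded


class TestSymmetryFromLattice:
    @pytest.mark.parametrize(
        "pitch,upt,rise,twist",
        [
            (36.3, 3.89, 9.33, 92.5),  # wide filament, printed precision
            (48.1, 4.27, 11.26, 84.3),  # narrow filament
            (10.0, 4.0, 2.5, 90.0),  # integer helix
        ],
    )
    def test_printed_values(self, pitch, upt, rise, twist):
        sym = px.symmetry_from_lattice(px.LatticeEstimate(pitch, upt))
        r = rounded(sym)
        assert r.rise == pytest.approx(rise, abs=1e-9)
        assert r.twist == pytest.approx(twist, abs=1e-9)

    def test_full_precision_retained(self):
        sym = px.symmetry_from_lattice(px.LatticeEstimate(36.3, 3.89))
        assert sym.rise == pytest.approx(36.3 / 3.89, rel=1e-15)
        assert sym.twist == pytest.approx(360.0 / 3.89, rel=1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            px.LatticeEstimate(-1.0, 4.0)
        with pytest.raises(ValueError):
            px.LatticeEstimate(36.3, 0.5)


class TestRoundTrip:
    def test_simple(self):
        lat = px.lattice_from_symmetry(px.HelicalSymmetry(2.5, 90.0))
        assert lat.pitch == pytest.approx(10.0)
        assert lat.units_per_turn == pytest.approx(4.0)

    def test_wide(self):
        lat = px.lattice_from_symmetry(px.HelicalSymmetry(9.33, 92.5))
        assert lat.pitch == pytest.approx(36.31, abs=0.005)
        assert lat.units_per_turn == pytest.approx(3.892, abs=0.0005)

    @settings(derandomize=True, max_examples=100)
    @given(
        rise=st.floats(0.1, 100.0, allow_nan=False),
        # in-scope filaments have more than one subunit per turn (twist < 360)
        twist=st.floats(1.0, 359.0, allow_nan=False),
    )
    def test_inverse_property(self, rise, twist):
        sym = px.HelicalSymmetry(rise, twist)
        back = px.symmetry_from_lattice(px.lattice_from_symmetry(sym))
        assert back.rise == pytest.approx(sym.rise, rel=1e-9)
        assert back.twist == pytest.approx(sym.twist, rel=1e-9)


class TestUnitsPerTurnFromSpacings:
    def test_wide_estimate(self):
        assert px.units_per_turn_from_spacings(9.0, 36.0) == pytest.approx(4.0)

    def test_narrow_estimate(self):
        upt = px.units_per_turn_from_spacings(11.3, 48.1)
        assert round(upt, 2) == 4.26
        assert round(360.0 / upt, 1) == 84.6

    def test_identity(self):
        assert px.units_per_turn_from_spacings(7.7, 7.7) == pytest.approx(1.0)

    def test_inverted_order_warns(self):
        with pytest.warns(UserWarning):
            px.units_per_turn_from_spacings(36.0, 9.0)


def brute_force_repeat(upt, max_turns):
    """Independent oracle: exhaustive scan of all reduced fractions."""
    best = None
    for t in range(1, max_turns + 1):
        for u in range(1, int(upt * max_turns) + 2):
            f = Fraction(u, t)
            err = abs(float(f) - upt)
            key = (err, f.denominator, f.numerator)
            if best is None or key < best:
                best = key
    return best[2], best[1]


class TestBestRationalRepeat:
    def test_wide_repeats_after_nine_turns(self):
        rep = px.best_rational_repeat(3.89, 20)
        assert (rep.subunits, rep.turns) == (35, 9)
        assert brute_force_repeat(3.89, 20) == (35, 9)

    def test_integer_case(self):
        rep = px.best_rational_repeat(4.0, 20)
        assert (rep.subunits, rep.turns) == (4, 1)

    def test_narrow(self):
        rep = px.best_rational_repeat(4.27, 20)
        assert (rep.subunits, rep.turns) == brute_force_repeat(4.27, 20) == (47, 11)

    @settings(derandomize=True, max_examples=50)
    @given(u=st.integers(3, 200), t=st.integers(1, 18))
    def test_exact_fraction_recovered(self, u, t):
        if math.gcd(u, t) != 1 or u <= t:
            return
        rep = px.best_rational_repeat(u / t, max_turns=20)
        assert (rep.subunits, rep.turns) == (u, t)

    def test_invalid(self):
        with pytest.raises(ValueError):
            px.best_rational_repeat(3.89, 0)


class TestSelectionRule:
    def test_ninth_layer_is_order_one(self):
        rep = px.RepeatSolution(35, 9)
        assert px.allowed_bessel_orders(9, rep, max_abs_m=1) == [1]

    def test_equator(self):
        assert px.allowed_bessel_orders(0, px.RepeatSolution(35, 9), 0) == [0]

    def test_meridional_layer(self):
        orders = px.allowed_bessel_orders(35, px.RepeatSolution(35, 9), 1)
        assert 0 in orders

    @pytest.mark.parametrize("u,t", [(35, 9), (47, 11), (4, 1), (22, 7)])
    def test_identities(self, u, t):
        rep = px.RepeatSolution(u, t)
        assert px.allowed_bessel_orders(0, rep, 0) == [0]
        assert px.allowed_bessel_orders(t, rep, 0) == [1]

    def test_all_returned_orders_satisfy_rule(self):
        rep = px.RepeatSolution(35, 9)
        for n in px.allowed_bessel_orders(17, rep, max_abs_m=3):
            assert any(
                17 == rep.turns * n + rep.subunits * m for m in range(-3, 4)
            )


class TestLayerLineSpacing:
    def test_meridional_equals_rise(self):
        rep = px.RepeatSolution(35, 9)
        assert px.layer_line_spacing(35, rep, 9.33) == pytest.approx(9.33)

    def test_order_one_equals_pitch(self):
        rep = px.RepeatSolution(35, 9)
        spacing = px.layer_line_spacing(9, rep, 9.33)
        assert spacing == pytest.approx(35 * 9.33 / 9)
        # consistency with pitch = rise * u / t
        assert spacing == pytest.approx(px.HelicalSymmetry(9.33, 360 * 9 / 35).pitch)

    def test_integer_helix_pitch(self):
        assert px.layer_line_spacing(1, px.RepeatSolution(4, 1), 2.5) == pytest.approx(10.0)

    def test_equator_rejected(self):
        with pytest.raises(ValueError):
            px.layer_line_spacing(0, px.RepeatSolution(35, 9), 9.33)


class TestEnumerateCandidates:
    def test_wide_grid(self):
        grid = px.enumerate_symmetry_candidates(36.3, (3.5, 4.5), 0.01)
        upts = [round(c.units_per_turn, 2) for c in grid]
        assert len(grid) == 101
        assert 3.89 in upts and 4.10 in upts

    def test_narrow_grid_contains_candidate_set(self):
        grid = px.enumerate_symmetry_candidates(48.1, (4.0, 4.5), 0.01)
        upts = {round(c.units_per_turn, 2) for c in grid}
        assert {4.11, 4.14, 4.27, 4.30} <= upts

    def test_degenerate_range(self):
        grid = px.enumerate_symmetry_candidates(36.3, (4.0, 4.0), 0.01)
        assert len(grid) == 1

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            px.enumerate_symmetry_candidates(36.3, (4.5, 3.5), 0.01)


class TestAsymmetricUnits:
    @pytest.mark.parametrize(
        "segments,step,rise,expected",
        [
            (65656, 27.99, 9.33, 196968),  # wide filament bookkeeping
            (51301, 33.78, 11.26, 153903),  # narrow filament bookkeeping
            (1, 7.7, 7.7, 1),
        ],
    )
    def test_printed_counts(self, segments, step, rise, expected):
        assert px.asymmetric_units(segments, step, rise) == expected

    def test_linear_in_segments(self):
        one = px.asymmetric_units(1, 27.99, 9.33)
        for n in (2, 10, 65656):
            assert px.asymmetric_units(n, 27.99, 9.33) == n * one

    def test_non_integral_ratio_rejected(self):
        with pytest.raises(ValueError):
            px.asymmetric_units(100, 25.0, 9.33)
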