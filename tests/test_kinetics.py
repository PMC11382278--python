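"""Kinetics layer: pKa corrections, Eyring conversions, pH-rate model.

The regression values here are the familiar experimental-arithmetic numbers
for dopaquinone cyclization at 37 degC and pH 7.4, reproduced with the
conventional rounded thermal energy kT = 0.617 kcal/mol.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from evbkit.constants import KT_37C, eyring_prefactor
from evbkit.kinetics import (
    KineticContext,
    PHRateModel,
    amine_correction,
    barrier_from_rate,
    composite_barrier,
    format_half_life,
    half_life,
    hydroxide_correction,
    intrinsic_barrier,
    ph_barrier,
    ph_rate,
    ph_scan,
    rate_from_barrier,
)

CTX = KineticContext(temperature=310.15, kT=KT_37C, pH=7.4)
K_EXP = 2.56e-7  # experimental rate constant, s^-1


class TestPkaCorrections:
    def test_hydroxide_correction_at_ph_7_4(self):
        assert round(hydroxide_correction(CTX), 2) == 11.79

    def test_amine_correction_at_ph_7_4(self):
        assert round(amine_correction(CTX), 2) == 1.01

    def test_amine_correction_vanishes_at_its_pka(self):
        # (the water pKa, 15.7, lies outside the modelled pH domain)
        assert amine_correction(CTX.at_ph(8.11)) == pytest.approx(0.0, abs=1e-12)

    def test_vesicle_ph(self):
        """Acidic vesicle interior (pH 5.9) raises the hydroxide cost."""
        assert hydroxide_correction(CTX.at_ph(5.9)) == pytest.approx(
            0.617 * math.log(10) * 9.8, abs=1e-9
        )

    def test_amine_correction_at_acidic_ph(self):
        assert amine_correction(CTX.at_ph(2.0)) == pytest.approx(
            0.617 * math.log(10) * 6.11, abs=1e-9
        )


class TestBarrierArithmetic:
    def test_composite_evb_barrier(self):
        corr = [hydroxide_correction(CTX), amine_correction(CTX)]
        assert round(composite_barrier(18.13, corr), 2) == 30.93

    @pytest.mark.parametrize("chem, expected", [(8.54, 21.34), (10.80, 23.60)])
    def test_composite_continuum_barriers(self, chem, expected):
        corr = [hydroxide_correction(CTX), amine_correction(CTX)]
        assert round(composite_barrier(chem, corr), 2) == expected

    def test_intrinsic_barrier_decomposition(self):
        assert intrinsic_barrier(27.55, [11.79, 1.01]) == pytest.approx(14.75)

    @given(st.floats(-50, 50), st.lists(st.floats(-20, 20), max_size=4))
    def test_composite_and_intrinsic_are_inverses(self, x, corr):
        assert intrinsic_barrier(composite_barrier(x, corr), corr) == pytest.approx(
            x, abs=1e-9
        )

    def test_empty_corrections_identity(self):
        assert composite_barrier(3.5, []) == 3.5
        assert intrinsic_barrier(3.5, []) == 3.5


class TestEyring:
    def test_experimental_barrier_from_rate(self):
        """k = 2.56e-7 s^-1 at 37 degC corresponds to ~27.55 kcal/mol.

        The 0.03 tolerance is the propagated precision of the rounded
        kT = 0.617 (three decimals) entering the conversion.
        """
        assert barrier_from_rate(K_EXP, CTX) == pytest.approx(27.55, abs=0.03)

    def test_round_trip_is_exact(self):
        for k in (K_EXP, 0.147, 1.0):
            assert rate_from_barrier(barrier_from_rate(k, CTX), CTX) == pytest.approx(
                k, rel=1e-12
            )

    def test_zero_barrier_gives_attempt_frequency(self):
        ctx = KineticContext(temperature=310.0, kT=KT_37C)
        assert rate_from_barrier(0.0, ctx) == pytest.approx(6.46e12, rel=1e-2)
        assert rate_from_barrier(0.0, ctx) == pytest.approx(eyring_prefactor(310.0))

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            barrier_from_rate(0.0, CTX)


class TestHalfLife:
    def test_experimental_half_life_in_hours(self):
        assert round(half_life(K_EXP) / 3600.0) == 752
        assert format_half_life(half_life(K_EXP)) == "752 h"

    def test_fast_quinone_half_life_in_seconds(self):
        assert format_half_life(half_life(0.147)) == "4.7 s"

    def test_ln2_rate_gives_one_second(self):
        assert half_life(math.log(2.0)) == pytest.approx(1.0)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            half_life(-1.0)


class TestPhModel:
    model = PHRateModel.anchored(27.55, CTX)

    def test_anchoring_round_trip(self):
        assert ph_barrier(self.model, 7.4) == pytest.approx(27.55, abs=1e-12)
        assert ph_rate(self.model, 7.4) == pytest.approx(
            rate_from_barrier(27.55, CTX), rel=1e-12
        )

    def test_log_rate_slope_is_exactly_two(self):
        """log10 k is affine in pH with slope 2, to machine precision."""
        phs = [4.0, 5.5, 7.0]
        logs = [math.log10(ph_rate(self.model, p)) for p in phs]
        s1 = (logs[1] - logs[0]) / (phs[1] - phs[0])
        s2 = (logs[2] - logs[1]) / (phs[2] - phs[1])
        assert s1 == pytest.approx(2.0, abs=1e-10)
        assert s2 == pytest.approx(2.0, abs=1e-10)
        assert logs[0] == pytest.approx(self.model.c + 2 * phs[0], abs=1e-9)

    def test_one_ph_unit_is_a_factor_hundred(self):
        assert ph_rate(self.model, 6.4) / ph_rate(self.model, 7.4) == pytest.approx(
            1e-2, rel=1e-10
        )

    def test_scan_is_strictly_increasing_in_ph(self):
        table = ph_scan(self.model, np.linspace(4.0, 8.0, 17))
        assert len(table) == 17
        assert np.all(np.diff(table["k_per_s"]) > 0)
        assert np.all(np.diff(table["dG_act_kcal_mol"]) < 0)

    def test_two_point_scan(self):
        table = ph_scan(self.model, [6.4, 7.4])
        assert len(table) == 2
        assert table["k_per_s"].iloc[0] / table["k_per_s"].iloc[1] == pytest.approx(
            1e-2, rel=1e-9
        )

    def test_ph_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            ph_barrier(self.model, -0.5)
        with pytest.raises(ValueError):
            ph_barrier(self.model, 14.5)

    def test_ph_above_amine_pka_flagged(self):
        with pytest.warns(UserWarning, match="amine"):
            ph_barrier(self.model, 9.0)


class TestKineticContext:
    def test_physical_kt_default(self):
        ctx = KineticContext(temperature=310.15)
        assert ctx.kT == pytest.approx(0.61633, abs=1e-4)

    def test_invalid_context_rejected(self):
        with pytest.raises(ValueError):
            KineticContext(temperature=-1.0)
        with pytest.raises(ValueError):
            KineticContext(pH=15.0)
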