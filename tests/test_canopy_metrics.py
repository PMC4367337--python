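"""Porosity, clumping index, Beer's-law LAI and its k-inversion."""

import math

import numpy as np
import pytest

from canopylai.canopy_metrics import (
    SaturationWarning,
    clumping_index,
    crown_porosity,
    destructive_lai,
    invert_k,
    lai_from_cover,
)


def _random_canopy_tuples(n, seed=7):
    """Consistent (f_f, f_c, phi, omega0) tuples over the valid domain."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        f_c = rng.uniform(0.3, 1.0)
        f_f = rng.uniform(0.05, 0.95) * f_c
        if f_f <= 0.0 or f_f >= 1.0:
            continue
        phi = crown_porosity(f_f, f_c)
        if not 0.0 < phi < 1.0:
            continue
        out.append((f_f, f_c, phi, clumping_index(f_f, phi)))
    return out


class TestCrownPorosity:
    def test_worked_example(self):
        assert crown_porosity(0.80, 0.92) == pytest.approx(0.130435, abs=1e-6)

    @pytest.mark.parametrize(
        "f_f, f_c, expected", [(0.5, 0.5, 0.0), (0.0, 0.7, 1.0)]
    )
    def test_extremes(self, f_f, f_c, expected):
        assert crown_porosity(f_f, f_c) == pytest.approx(expected)

    def test_error_contracts(self):
        with pytest.raises(ValueError, match="no crown cover"):
            crown_porosity(0.0, 0.0)
        with pytest.raises(ValueError, match="exceed"):
            crown_porosity(0.9, 0.8)
        with pytest.raises(ValueError, match="f_f"):
            crown_porosity(1.2, 1.0)


class TestClumpingIndex:
    def test_full_crown_cover_means_no_clumping(self):
        # with f_c = 1 the porosity is 1 - f_f and the expression collapses to 1
        for f_f in (0.1, 0.5, 0.66, 0.9):
            assert clumping_index(f_f, 1.0 - f_f) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize(
        "f_f, phi, expected",
        [
            # frozen from high-precision evaluation of the defining expression
            (0.80, 0.130435, 0.8588564),
            (0.66, 0.131579, 0.6998929),
        ],
    )
    def test_frozen_oracle_values(self, f_f, phi, expected):
        oracle = (1 - phi) * math.log(1 - f_f) / (math.log(phi) * f_f)
        assert oracle == pytest.approx(expected, abs=5e-7)
        assert clumping_index(f_f, phi) == pytest.approx(oracle, rel=1e-14)

    def test_bounded_on_valid_domain(self):
        for f_f, f_c, phi, omega0 in _random_canopy_tuples(200):
            assert 0.0 < omega0 <= 1.0 + 1e-12

    def test_limit_at_zero_porosity_flagged(self):
        with pytest.warns(SaturationWarning):
            assert clumping_index(0.5, 0.0) == 0.0

    def test_error_contracts(self):
        with pytest.raises(ValueError, match="saturated"):
            clumping_index(1.0, 0.1)
        with pytest.raises(ValueError):
            clumping_index(0.0, 0.5)


class TestLaiFromCover:
    def test_worked_example(self):
        est = lai_from_cover(0.92, 0.130435, 0.858857, 0.68)
        assert est.lai == pytest.approx(2.3670, abs=5e-4)
        assert est.k_used == 0.68

    def test_reduces_to_classic_beers_law_when_crown_fills_frame(self):
        for f_f in (0.2, 0.5, 0.8):
            est = lai_from_cover(1.0, 1.0 - f_f, 1.0, 0.68)
            assert est.lai == pytest.approx(-math.log(1 - f_f) / 0.68, rel=1e-12)

    def test_empty_canopy(self):
        assert lai_from_cover(0.0, 1.0, 1.0, 0.68).lai == 0.0

    def test_strictly_decreasing_and_inverse_in_k(self):
        f_f, f_c, phi, omega0 = _random_canopy_tuples(1)[0]
        base = lai_from_cover(f_c, phi, omega0, 0.5).lai
        for c in (0.5, 2.0, 3.7):
            assert lai_from_cover(f_c, phi, omega0, 0.5 * c).lai == pytest.approx(
                base / c, rel=1e-12
            )

    def test_phi_free_form_agrees_everywhere(self):
        # the direct product and the algebraic substitution of omega0 must
        # coincide wherever both are defined
        for f_f, f_c, phi, omega0 in _random_canopy_tuples(300):
            direct = -f_c * (math.log(phi) / 0.68) * omega0
            phi_free = -f_c * (1 - phi) * math.log(1 - f_f) / (0.68 * f_f)
            assert direct == pytest.approx(phi_free, rel=1e-12)
            assert lai_from_cover(f_c, phi, omega0, 0.68).lai == pytest.approx(
                direct, rel=1e-12
            )

    def test_saturated_porosity_uses_guarded_form(self):
        with pytest.warns(SaturationWarning):
            est = lai_from_cover(0.9, 1e-12, 0.0, 0.68)
        f_f = 0.9 * (1 - 1e-12)
        assert est.lai == pytest.approx(-math.log(1 - f_f) / 0.68, rel=1e-6)

    def test_error_contracts(self):
        with pytest.raises(ValueError):
            lai_from_cover(0.9, 0.1, 0.9, 0.0)
        # phi = 1 means the crown holds no foliage at all: f_f = 0, LAI = 0
        assert lai_from_cover(0.9, 1.0, 0.9, 0.68).lai == 0.0


class TestInvertK:
    def test_worked_example_roundtrip(self):
        k = invert_k(0.92, 0.130435, 0.858857, 2.3670).k_M
        assert k == pytest.approx(0.68, abs=5e-4)

    def test_inverse_proportional_to_lai(self):
        k1 = invert_k(0.92, 0.13, 0.86, 2.0).k_M
        k2 = invert_k(0.92, 0.13, 0.86, 4.0).k_M
        assert k1 == pytest.approx(2 * k2, rel=1e-14)

    def test_exact_inverse_of_lai_from_cover(self):
        rng = np.random.default_rng(11)
        for f_f, f_c, phi, omega0 in _random_canopy_tuples(1000):
            k = rng.uniform(0.2, 1.2)
            lai = lai_from_cover(f_c, phi, omega0, k).lai
            assert invert_k(f_c, phi, omega0, lai).k_M == pytest.approx(k, rel=1e-10)

    def test_error_contracts(self):
        with pytest.raises(ValueError):
            invert_k(0.9, 0.1, 0.9, 0.0)
        with pytest.raises(ValueError):
            invert_k(0.9, 0.0, 0.9, 2.0)


class TestDestructiveLai:
    def test_unit_arithmetic(self):
        # 2000 g x 30 cm2/g = 6 m2 of leaf over a 4.5 m2 ground allotment
        assert destructive_lai(2000, 30, 3.0, 1.5) == pytest.approx(4 / 3)

    def test_typical_sla_magnitude(self):
        # apple-orchard SLA sits near 30 cm2/g; LAI comes out O(1)
        lai = destructive_lai(3500, 29.9, 3.0, 1.5)
        assert 1.0 < lai < 4.0

    @pytest.mark.parametrize("bad", ["mass", "sla", "row", "plant"])
    def test_nonpositive_inputs_rejected(self, bad):
        args = {"mass": 2000.0, "sla": 30.0, "row": 3.0, "plant": 1.5}
        args[bad] = 0.0
        with pytest.raises(ValueError):
            destructive_lai(args["mass"], args["sla"], args["row"], args["plant"])
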