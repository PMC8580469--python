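"""The divergence measure: hand values, identities, covariance, FFT path."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from symscan.fields import IntensityField
from symscan.ti import (
    difference_map,
    ti_scan,
    transformation_information,
    translation_ti_periodic,
)
from symscan.transforms import EmptyOverlapError, TransformSpec, reflection_spec


def _shift_ti(curve, sx, sy):
    gx, gy = (list(map(int, np.asarray(g))) for g in curve.param_grid)
    return curve.ti_values[gx.index(sx), gy.index(sy)]


class TestPointEvaluations:
    def test_identity_is_zero(self, random_field):
        assert transformation_information(random_field, TransformSpec("identity")) == 0.0

    def test_constant_field_rotation_zero(self):
        field = IntensityField(np.full((9, 9), 4.0))
        ti = transformation_information(field, TransformSpec("rotation", angle=30.0))
        assert abs(ti) < 1e-12

    def test_hand_computed_periodic_shift(self):
        """[[2,1],[1,1]] shifted one pixel horizontally: TI = ln(2)/4."""
        field = IntensityField(np.array([[2.0, 1.0], [1.0, 1.0]]))
        spec = TransformSpec("translation", shift=(1.0, 0.0), boundary="periodic")
        ti = transformation_information(field, spec)
        # independent scalar evaluation of the discrete sum
        mu = field.values
        tmu = np.roll(mu, 1, axis=1)
        expected = np.mean(mu * np.log(mu / tmu))
        assert np.isclose(ti, np.log(2) / 4, atol=1e-14)
        assert np.isclose(ti, expected, atol=1e-14)

    def test_clamped_constant_field_zero_ti(self):
        from symscan.fields import ensure_positive

        field = ensure_positive(np.full((8, 8), -1.0), floor=1.0)
        ti = transformation_information(field, TransformSpec("rotation", angle=45.0))
        assert abs(ti) < 1e-12


class TestScaleCovariance:
    @pytest.mark.parametrize("c", [0.5, 2.0, 117.3])
    def test_ti_scales_linearly(self, smooth_field, c):
        spec = TransformSpec("rotation", angle=23.0)
        base = transformation_information(smooth_field, spec)
        scaled = transformation_information(smooth_field.with_values(c * smooth_field.values), spec)
        assert np.isclose(scaled, c * base, rtol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        vals=arrays(np.float64, (6, 6), elements=st.floats(1.0, 50.0)),
        c=st.floats(0.01, 100.0),
    )
    def test_covariance_property_periodic(self, vals, c):
        field = IntensityField(vals + 0.1)
        spec = TransformSpec("translation", shift=(2.0, 1.0), boundary="periodic")
        a = transformation_information(field, spec)
        b = transformation_information(field.with_values(c * field.values), spec)
        assert np.isclose(b, c * a, rtol=1e-11, atol=1e-13)


class TestTranslationMap:
    def test_zero_shift_exactly_zero(self, random_field):
        curve = translation_ti_periodic(random_field)
        assert _shift_ti(curve, 0, 0) == 0.0

    def test_fft_equals_direct(self, rng):
        field = IntensityField(rng.uniform(1.0, 8.0, (64, 64)))
        fft = translation_ti_periodic(field, method="fft")
        direct = translation_ti_periodic(field, method="direct")
        denom = np.abs(direct.ti_values).max()
        assert np.abs(fft.ti_values - direct.ti_values).max() / denom < 1e-9

    def test_role_swap_equals_negated_shift(self, random_field):
        """Exchanging μ and Tμ at shift s gives the TI at −s, exactly."""
        mu = random_field.values
        a = translation_ti_periodic(random_field, method="direct")
        for sx, sy in [(1, 0), (2, 2), (-3, 1)]:
            tmu = np.roll(mu, (-sy, sx), axis=(0, 1))  # Tμ for the shift (sx, sy)
            swapped = np.mean(tmu * np.log(tmu / mu))
            assert np.isclose(swapped, _shift_ti(a, -sx, -sy), atol=1e-12)

    def test_nonnegative_on_equal_mass_periodic(self, rng):
        # Gibbs' inequality applied per-mass: periodic shifts preserve mass
        field = IntensityField(rng.uniform(1.0, 8.0, (16, 16)))
        curve = translation_ti_periodic(field)
        assert curve.ti_values.min() > -1e-10


class TestScans:
    def test_rotation_scan_contains_identity_zero(self, smooth_field):
        curve = ti_scan(smooth_field, "rotation", np.arange(0.0, 360.0, 45.0))
        assert abs(curve.ti_values[0]) < 1e-12

    def test_empty_overlap_flagged_nan(self, random_field):
        # reflections about a far-away axis leave no overlap
        curve = ti_scan(
            random_field, "reflection", np.array([0.0]), axis_point=(0.0, -500.0)
        )
        assert np.isnan(curve.ti_values).all()

    def test_scan_csv_roundtrip(self, tmp_path, smooth_field):
        curve = ti_scan(smooth_field, "rotation", np.arange(0.0, 360.0, 90.0))
        p = tmp_path / "curve.csv"
        curve.to_csv(p)
        import pandas as pd

        df = pd.read_csv(p)
        assert list(df.columns) == ["angle_deg", "ti"]
        assert np.allclose(df["ti"], curve.ti_values)


class TestDifferenceMap:
    def test_identity_zero_map(self, random_field):
        dm = difference_map(random_field, TransformSpec("identity"))
        assert dm.max_abs() == 0.0

    def test_sign_convention(self):
        """Positive where the transformed image is higher."""
        field = IntensityField(np.array([[1.0, 5.0], [1.0, 1.0]]))
        spec = TransformSpec("translation", shift=(1.0, 0.0), boundary="periodic")
        dm = difference_map(field, spec)
        # after a +x shift the high pixel lands one column right
        assert dm.values[0, 0] > 0  # transformed higher (5 arrived from the left... wrapped)
        assert dm.values[0, 1] < 0  # original higher (5 left this pixel)
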