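"""Minima detection, ranking, and centre estimation."""

import numpy as np
import pytest

from symscan.fields import BinaryMask, IntensityField
from symscan.fixtures import FixtureSpec, make_fixture
from symscan.search import (
    bilateral_axis_search,
    estimate_center_area,
    estimate_center_reflection,
    estimate_center_rotational,
    find_symmetries,
)
from symscan.ti import TICurve, ti_scan, transformation_information
from symscan.transforms import TransformSpec


@pytest.fixture(scope="module")
def rosette():
    field, truth = make_fixture(FixtureSpec("rosette", n_fold=5, size=128))
    return field, truth


class TestFindSymmetries:
    def test_rosette_four_candidates(self, rosette):
        field, _ = rosette
        curve = ti_scan(field, "rotation", np.arange(0.0, 360.0, 1.0))
        cands = find_symmetries(curve)
        angles = sorted(c.spec.angle for c in cands)
        assert len(cands) == 4
        assert np.allclose(angles, [72.0, 144.0, 216.0, 288.0], atol=1.0)

    def test_identity_excluded(self, rosette):
        field, _ = rosette
        curve = ti_scan(field, "rotation", np.arange(0.0, 360.0, 1.0))
        assert all(c.spec.angle % 360.0 != 0.0 for c in find_symmetries(curve))

    def test_monotone_curve_empty(self):
        curve = TICurve("reflection", np.arange(10.0), np.linspace(0.0, 5.0, 10))
        assert find_symmetries(curve) == []

    def test_ranked_ascending_by_ti(self, rosette):
        field, _ = rosette
        curve = ti_scan(field, "rotation", np.arange(0.0, 360.0, 1.0))
        cands = find_symmetries(curve)
        tis = [c.ti_value for c in cands]
        assert tis == sorted(tis)
        assert [c.rank for c in cands] == list(range(1, len(cands) + 1))

    def test_all_nan_curve_raises(self):
        curve = TICurve("rotation", np.arange(5.0), np.full(5, np.nan))
        with pytest.raises(ValueError):
            find_symmetries(curve)

    def test_asymmetric_rosette_ranking_responds_to_morphology(self):
        """Petals with one-sided lobes keep rotation minima but kill reflections."""
        field, _ = make_fixture(FixtureSpec("rosette", n_fold=5, asymmetry=0.8, size=128))
        rot = find_symmetries(ti_scan(field, "rotation", np.arange(0.0, 360.0, 2.0)))
        refl_curve = ti_scan(field, "reflection", np.arange(0.0, 180.0, 2.0))
        assert len(rot) == 4
        best_rot = min(c.ti_value for c in rot)
        assert best_rot < np.nanmin(refl_curve.ti_values)


class TestRotationalCentre:
    def test_recovers_embedded_centre(self):
        field, _ = make_fixture(FixtureSpec("rosette", n_fold=5, size=128))
        canvas = np.full((192, 192), 10.0)
        canvas[20:148, 30:158] = field.values
        big = IntensityField(canvas, provenance="fixture")
        true_c = (30 + 63.5, (191 - (20 + 63.5)))
        est = estimate_center_rotational(
            big,
            ((true_c[0] - 20, true_c[0] + 20), (true_c[1] - 20, true_c[1] + 20)),
            n_angles=12,
            downsample_factor=4,
        )
        assert est.found
        assert abs(est.coordinates[0] - true_c[0]) <= 4.0  # one downsampled pixel
        assert abs(est.coordinates[1] - true_c[1]) <= 4.0

    def test_constant_field_no_centre(self):
        field = IntensityField(np.full((64, 64), 5.0))
        est = estimate_center_rotational(field, ((16, 48), (16, 48)), downsample_factor=4)
        assert not est.found

    def test_argmax_stable_under_intensity_rescaling(self):
        field, _ = make_fixture(FixtureSpec("rosette", n_fold=5, size=128))
        window = ((54, 74), (54, 74))
        a = estimate_center_rotational(field, window, downsample_factor=4)
        doubled = field.with_values(2.0 * field.values)
        b = estimate_center_rotational(doubled, window, downsample_factor=4)
        assert a.coordinates == b.coordinates

    def test_bad_window_raises(self, random_field):
        with pytest.raises(ValueError):
            estimate_center_rotational(random_field, ((0, 500), (0, 500)), downsample_factor=2)


class TestReflectionCentre:
    def test_vertical_axis_recovered(self):
        field, _ = make_fixture(FixtureSpec("bilateral_blob", axis_angle=90.0, size=128))
        est = estimate_center_reflection(field, ((44, 84), (44, 84)))
        assert est.found
        assert abs(est.coordinates[0] - 63.5) <= 1.0

    def test_axial_asymmetry_biases_along_axis_coordinate(self):
        """Two unequal lobes on the symmetry axis pull the along-axis
        estimate away from their geometric midpoint (the two-semicell
        effect); equal lobes centre exactly on it."""
        def two_blobs(top_amp):
            x = np.arange(128) - 63.5
            X, Y = x[None, :], x[::-1][:, None]  # y increases upward
            vals = (10.0
                    + 200.0 * np.exp(-((X**2 + (Y - 25.0) ** 2) / 12.0**2)) * top_amp
                    + 200.0 * np.exp(-((X**2 + (Y + 25.0) ** 2) / 12.0**2)))
            return IntensityField(vals)

        window = ((34, 94), (34, 94))
        equal = estimate_center_reflection(two_blobs(1.0), window)
        assert abs(equal.coordinates[1] - 63.5) <= 1.0
        uneven = estimate_center_reflection(two_blobs(0.4), window)
        assert abs(uneven.coordinates[1] - 63.5) > 2.0

    def test_constant_field_flat(self):
        field = IntensityField(np.full((64, 64), 3.0))
        est = estimate_center_reflection(field, ((16, 48), (16, 48)))
        assert not est.found


class TestAreaCentre:
    def test_centred_disc(self):
        X, Y = np.meshgrid(np.arange(65) - 32, np.arange(65) - 32)
        mask = BinaryMask((X**2 + Y**2 <= 20**2).astype(np.uint8))
        est = estimate_center_area(mask)
        assert est.coordinates == (32.0, 32.0)

    def test_single_pixel(self):
        m = np.zeros((9, 9), dtype=np.uint8)
        m[2, 6] = 1
        est = estimate_center_area(BinaryMask(m))
        assert est.coordinates == (6.0, 6.0)  # y up: row 2 -> y = 8 - 2

    def test_half_disc_matches_bruteforce(self):
        X, Y = np.meshgrid(np.arange(64) - 32, np.arange(64) - 32)
        mask = ((X**2 + Y**2 <= 25**2) & (Y >= 0)).astype(np.uint8)
        est = estimate_center_area(BinaryMask(mask))
        # independent brute force over all integer split lines
        def brute(sums):
            sums = sums.astype(int)
            best, arg = None, None
            for p in range(len(sums)):
                diff = abs(sums[:p].sum() - sums[p + 1:].sum())
                if best is None or diff < best:
                    best, arg = diff, p
            return arg

        bx = brute(mask.sum(axis=0))
        by_row = brute(mask.sum(axis=1))
        assert est.coordinates == (float(bx), float(63 - by_row))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            estimate_center_area(BinaryMask(np.zeros((8, 8), dtype=np.uint8)))


class TestBilateralAxisSearch:
    @pytest.mark.parametrize("angle", [0.0, 4.5])
    def test_recovers_construction_angle(self, angle):
        field, _ = make_fixture(FixtureSpec("bilateral_blob", axis_angle=angle, size=128))
        best, curve = bilateral_axis_search(field, step=0.5)
        assert abs(best - angle) <= 0.5
        assert curve.ti_values.size == len(np.arange(-30.0, 30.25, 0.5))

    def test_invalid_step(self, random_field):
        with pytest.raises(ValueError):
            bilateral_axis_search(random_field, step=0.0)
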