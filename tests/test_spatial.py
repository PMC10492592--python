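"""Spatial analysis: N maps, regions, radial/azimuthal profiles vs brute force."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polarpath.spatial import (
    ImageGeometry,
    RegionSpec,
    compare_rectangle_orientations,
    lobe_profile,
    radial_profile,
    region_mask,
    region_npp,
    scatter_count_map,
    sum_intensity,
)

GEOM5 = ImageGeometry(nx=5, ny=5, field_mm=5.0, pol_axis_deg=0.0)


class TestScatterCountMap:
    def test_hand_computed_quotient(self):
        totals = np.arange(25, dtype=float).reshape(5, 5)
        counts = np.full((5, 5), 2.0)
        counts[0, 0] = 0.0
        counts[1, 1] = 4.0
        nmap = scatter_count_map(totals, counts, min_photons=1)
        assert not nmap.mask[0, 0]
        assert nmap.values[1, 1] == pytest.approx(6.0 / 4.0)
        expect = totals[2:, :] / 2.0
        assert nmap.values[2:, :] == pytest.approx(expect)

    def test_zero_totals_and_masked_pixels(self):
        nmap = scatter_count_map(np.zeros((3, 3)), np.full((3, 3), 7.0), 5)
        assert np.all(nmap.values == 0.0)
        assert np.all(nmap.mask)
        nmap = scatter_count_map(np.ones((3, 3)), np.zeros((3, 3)), 0)
        assert not nmap.mask.any()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            scatter_count_map(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_scale_invariance_of_npp(self):
        """N is a ratio: scaling tallies and counts together changes nothing."""
        rng = np.random.default_rng(0)
        totals = rng.random((5, 5)) * 50
        counts = rng.integers(1, 20, (5, 5)).astype(float)
        a = scatter_count_map(totals, counts, 1)
        b = scatter_count_map(totals * 3.7, counts * 3.7, 1)
        region = RegionSpec("disc", diameter_mm=3.0)
        ma = region_npp(a, region, GEOM5)
        mb = region_npp(b, region, GEOM5)
        assert ma.npp == pytest.approx(mb.npp, rel=1e-12)


class TestRegions:
    def test_full_image_baseline_consistency(self):
        rng = np.random.default_rng(1)
        nmap = scatter_count_map(rng.random((5, 5)), np.ones((5, 5)), 1)
        metric = region_npp(nmap, RegionSpec("full_image"), GEOM5)
        assert metric.npp == pytest.approx(nmap.values.mean(), rel=1e-12)
        assert metric.reduction_vs_full == pytest.approx(0.0, abs=1e-12)
        assert metric.pixel_count == 25

    def test_hand_drawn_rectangle_enumeration(self):
        """Pixel-centre rule: a 3x1 mm rectangle on a 1 mm grid = 3 pixels."""
        values = np.arange(25, dtype=float).reshape(5, 5)
        nmap = scatter_count_map(values, np.ones((5, 5)), 1)
        rect = RegionSpec(
            "oriented_rectangle", length_mm=3.0, width_mm=1.0, angle_deg=0.0
        )
        mask = region_mask(rect, GEOM5)
        # centre row (y = 0), middle 3 columns
        assert mask.sum() == 3
        metric = region_npp(nmap, rect, GEOM5)
        hand = values[2, 1:4].mean()
        assert metric.npp == pytest.approx(hand, rel=1e-12)

    def test_uniform_map_all_regions_equal(self):
        nmap = scatter_count_map(np.full((5, 5), 6.0), np.ones((5, 5)), 1)
        for region in (
            RegionSpec("disc", diameter_mm=2.0),
            RegionSpec("oriented_rectangle", length_mm=4.0, width_mm=2.0, angle_deg=30.0),
        ):
            m = region_npp(nmap, region, GEOM5)
            assert m.npp == pytest.approx(6.0)
            assert m.reduction_vs_full == pytest.approx(0.0, abs=1e-12)

    def test_empty_region_raises(self):
        nmap = scatter_count_map(np.ones((5, 5)), np.zeros((5, 5)), 1)
        with pytest.raises(ValueError):
            region_npp(nmap, RegionSpec("full_image"), GEOM5)

    def test_disc_nesting_monotone_for_radially_increasing_map(self):
        geom = ImageGeometry(nx=41, ny=41, field_mm=20.0)
        X, Y = geom.pixel_centers_mm()
        nmap = scatter_count_map(np.hypot(X, Y), np.ones_like(X), 1)
        npps = [
            region_npp(nmap, RegionSpec("disc", diameter_mm=d), geom).npp
            for d in (2.0, 5.0, 10.0, 18.0)
        ]
        assert np.all(np.diff(npps) > 0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        angle=st.floats(0.0, 180.0),
        length=st.floats(1.0, 18.0),
        width=st.floats(0.5, 6.0),
        seed=st.integers(0, 100),
    )
    def test_region_mean_equals_enumeration_oracle(self, angle, length, width, seed):
        """Aggregates equal a per-pixel loop over the same inclusion rule."""
        geom = ImageGeometry(nx=17, ny=17, field_mm=17.0, pol_axis_deg=-45.0)
        rng = np.random.default_rng(seed)
        values = rng.random((17, 17)) * 10
        nmap = scatter_count_map(values, np.ones((17, 17)), 1)
        rect = RegionSpec(
            "oriented_rectangle", length_mm=length, width_mm=width, angle_deg=angle
        )
        X, Y = geom.pixel_centers_mm()
        alpha = np.radians(geom.pol_axis_deg + rect.angle_deg)
        vals = []
        for iy in range(17):
            for ix in range(17):
                dx, dy = X[iy, ix], Y[iy, ix]
                a = np.cos(alpha) * dx + np.sin(alpha) * dy
                b = -np.sin(alpha) * dx + np.cos(alpha) * dy
                if abs(a) <= length / 2 and abs(b) <= width / 2:
                    vals.append(values[iy, ix])
        if not vals:
            with pytest.raises(ValueError):
                region_npp(nmap, rect, geom)
        else:
            m = region_npp(nmap, rect, geom)
            assert m.npp == pytest.approx(np.mean(vals), rel=1e-12)
            assert m.pixel_count == len(vals)


class TestRadialProfile:
    def test_uniform_map_constant_profile(self):
        geom = ImageGeometry(nx=21, ny=21, field_mm=21.0)
        prof = radial_profile(np.full((21, 21), 3.3), geom, bin_width_mm=2.0)
        ok = prof.n_pixels > 0
        assert np.allclose(prof.mean[ok], 3.3)

    def test_single_center_pixel(self):
        geom = ImageGeometry(nx=21, ny=21, field_mm=21.0)
        img = np.zeros((21, 21))
        img[10, 10] = 5.0
        prof = radial_profile(img, geom, bin_width_mm=1.0)
        assert prof.mean[0] == pytest.approx(5.0)
        assert np.all(prof.mean[1:][prof.n_pixels[1:] > 0] == 0.0)

    def test_against_per_pixel_loop_oracle(self):
        geom = ImageGeometry(nx=64, ny=64, field_mm=16.0)
        rng = np.random.default_rng(7)
        img = rng.random((64, 64))
        dr = 0.8
        prof = radial_profile(img, geom, bin_width_mm=dr)
        X, Y = geom.pixel_centers_mm()
        r = np.hypot(X, Y)
        for b in range(prof.bin_centers_mm.size):
            sel = (r >= b * dr) & (r < (b + 1) * dr)
            if sel.any():
                assert prof.mean[b] == pytest.approx(img[sel].mean(), abs=1e-12)
            else:
                assert np.isnan(prof.mean[b])


class TestOrientationSweep:
    def test_rotationally_symmetric_map(self):
        geom = ImageGeometry(nx=41, ny=41, field_mm=20.0)
        X, Y = geom.pixel_centers_mm()
        nmap = scatter_count_map(np.hypot(X, Y) + 1.0, np.ones_like(X), 1)
        df = compare_rectangle_orientations(nmap, geom, 18.0, 3.0, [0, 45, 90, 135])
        assert df.npp.max() - df.npp.min() < 0.05 * df.npp.mean()

    def test_low_ridge_detected_at_its_orientation(self):
        """A low-N ridge along the 90 deg axis minimizes Npp at 90 deg."""
        geom = ImageGeometry(nx=41, ny=41, field_mm=20.0, pol_axis_deg=-45.0)
        X, Y = geom.pixel_centers_mm()
        alpha = np.radians(geom.pol_axis_deg + 90.0)
        across = -np.sin(alpha) * X + np.cos(alpha) * Y
        values = np.where(np.abs(across) < 1.0, 1.0, 10.0)
        nmap = scatter_count_map(values, np.ones_like(X), 1)
        df = compare_rectangle_orientations(nmap, geom, 18.0, 1.5, [0, 45, 90, 135])
        best = df.loc[df.npp.idxmin(), "angle_deg"]
        assert best == pytest.approx(90.0)


class TestLobeProfile:
    def test_constructed_four_lobe_harmonic(self):
        """I(phi) = 1 + cos(4 phi) peaks at 0/90/180/270 deg (rel. pol axis)."""
        geom = ImageGeometry(nx=101, ny=101, field_mm=20.0, pol_axis_deg=-45.0)
        X, Y = geom.pixel_centers_mm()
        phi = np.arctan2(Y, X) - np.radians(geom.pol_axis_deg)
        img = 1.0 + np.cos(4 * phi)
        prof = lobe_profile(img, geom, 2.0, 8.0, n_bins=72)
        assert prof.peaks_deg.size == 4
        for expected in (0.0, 90.0, 180.0, 270.0):
            dist = np.abs(((prof.peaks_deg - expected) + 180.0) % 360.0 - 180.0)
            assert dist.min() <= 5.1

    def test_empty_annulus_raises(self):
        geom = ImageGeometry(nx=11, ny=11, field_mm=10.0)
        with pytest.raises(ValueError):
            lobe_profile(np.ones((11, 11)), geom, 20.0, 30.0)


class TestSumIntensity:
    def test_trivial_and_oracle(self):
        geom = ImageGeometry(nx=9, ny=9, field_mm=9.0)
        assert sum_intensity(np.zeros((9, 9)), RegionSpec("full_image"), geom) == 0.0
        img = np.full((9, 9), 2.0)
        disc = RegionSpec("disc", diameter_mm=4.0)
        k = region_mask(disc, geom).sum()
        assert sum_intensity(img, disc, geom) == pytest.approx(2.0 * k)
        rng = np.random.default_rng(3)
        img = rng.random((9, 9))
        assert sum_intensity(img, disc, geom) == pytest.approx(
            img[region_mask(disc, geom)].sum(), rel=1e-12
        )
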