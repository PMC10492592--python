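"""Polarized Monte Carlo: launch, transport, scattering and detection physics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from polarpath.mie import POLYSTYRENE_PHANTOM, MieParameters, StokesVector, compute_mueller_table
from polarpath.montecarlo import (
    BeamSpec,
    DetectorConfig,
    DetectorGrid,
    MediumSpec,
    PhaseSamplingTable,
    detect_packet,
    launch_packet,
    propagate_step,
    rotate_stokes,
    run_simulation,
    sample_beam_positions,
    scatter_event,
)


class TestLaunch:
    @pytest.mark.parametrize(
        "state, expected",
        [
            ("linear_minus45", [1, 0, -1, 0]),
            ("linear_plus45", [1, 0, 1, 0]),
            ("circular_right", [1, 0, 0, 1]),
            ("circular_left", [1, 0, 0, -1]),
        ],
    )
    def test_initial_stokes(self, state, expected):
        beam = BeamSpec(incident_state=state)
        packet = launch_packet(beam, np.random.default_rng(0))
        assert packet.stokes.as_array() == pytest.approx(expected)
        assert packet.n_scatter == 0
        assert packet.direction @ np.array([0.0, 0.0, 1.0]) == 1.0

    def test_uniform_disc_sampling(self):
        """1e5 launches: all within the 1.5 mm radius, uniform over annuli."""
        beam = BeamSpec(diameter_mm=3.0)
        xy = sample_beam_positions(beam, 100_000, np.random.default_rng(42))
        r = np.hypot(xy[:, 0], xy[:, 1])
        assert np.all(r <= beam.radius_cm + 1e-12)
        # equal-area annular bins => equal expected counts
        edges = beam.radius_cm * np.sqrt(np.linspace(0.0, 1.0, 11))
        obs, _ = np.histogram(r, bins=edges)
        _, p = stats.chisquare(obs)
        assert p > 0.01


class TestPropagation:
    def test_mean_free_path(self, phantom_medium):
        """Sampled steps average 1/mu_s = 0.04 cm (within 3 standard errors)."""
        rng = np.random.default_rng(3)
        beam = BeamSpec()
        steps = []
        for _ in range(30_000):
            p = launch_packet(beam, rng)
            z0 = p.position[2]
            propagate_step(p, phantom_medium, rng)
            steps.append(p.position[2] - z0)
        steps = np.asarray(steps)
        inside = steps[steps < phantom_medium.box_cm[2] - 1e-12]
        mean = inside.mean()
        se = inside.std() / math.sqrt(inside.size)
        assert abs(mean - 0.04) < 3 * se + 1e-4

    def test_boundary_exit_without_scatter_increment(self, phantom_medium):
        rng = np.random.default_rng(0)
        p = launch_packet(BeamSpec(), rng)
        p.direction = np.array([0.0, 0.0, -1.0])  # at the top face, moving out
        propagate_step(p, phantom_medium, rng)
        assert not p.alive
        assert p.exit_face == "top"
        assert p.n_scatter == 0
        assert p.pathlength_cm == 0.0


class TestScattering:
    def test_rotation_round_trip(self):
        s = StokesVector(1.0, 0.3, -0.5, 0.2)
        for phi in (0.3, 1.2, 2.9):
            back = rotate_stokes(rotate_stokes(s, phi), -phi)
            assert back.as_array() == pytest.approx(s.as_array(), abs=1e-12)

    def test_backscatter_flips_helicity(self, polystyrene_table):
        """One 180 deg event turns right-circular into left-circular light."""
        rng = np.random.default_rng(0)
        p = launch_packet(BeamSpec(incident_state="circular_right"), rng)
        scatter_event(p, polystyrene_table, rng, forced_angles=(math.pi, 0.0))
        assert p.stokes.v == pytest.approx(-1.0, abs=1e-9)
        assert p.direction[2] == pytest.approx(-1.0, abs=1e-12)

    def test_theta_marginal_matches_phase_function(self, polystyrene_table):
        """Sampled polar angles follow m11(theta) sin(theta) (chi-square)."""
        sampling = PhaseSamplingTable.from_table(polystyrene_table)
        rng = np.random.default_rng(11)
        theta = sampling.sample_theta(rng.random(200_000))
        edges = np.radians(np.linspace(0.0, 180.0, 37))
        obs, _ = np.histogram(theta, bins=edges)
        # independent oracle: bin masses of m11(theta) sin(theta)
        fine = np.linspace(0.0, np.pi, 72001)
        pdf = np.interp(
            np.degrees(fine), polystyrene_table.theta_deg, polystyrene_table.m11
        ) * np.sin(fine)
        cdf_fine = np.concatenate(
            [[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(fine))]
        )
        cdf_fine /= cdf_fine[-1]
        expected = np.diff(np.interp(edges, fine, cdf_fine)) * obs.sum()
        keep = expected > 5
        obs_k = np.append(obs[keep], obs[~keep].sum())
        exp_k = np.append(expected[keep], expected[~keep].sum())
        exp_k *= obs_k.sum() / exp_k.sum()
        _, p = stats.chisquare(obs_k, exp_k)
        assert p > 0.01

    def test_frame_stays_orthonormal_and_stokes_physical(self, polystyrene_table):
        rng = np.random.default_rng(5)
        p = launch_packet(BeamSpec(), rng)
        sampling = PhaseSamplingTable.from_table(polystyrene_table)
        for _ in range(500):
            scatter_event(p, polystyrene_table, rng, sampling=sampling)
            assert p.stokes.is_physical(rtol=1e-9)
        assert p.frame_orthonormality_error() < 1e-9
        assert p.n_scatter == 500


class TestDetection:
    def _exiting_packet(self, state="linear_minus45", theta=math.pi):
        rng = np.random.default_rng(1)
        p = launch_packet(BeamSpec(incident_state=state), rng)
        table = compute_mueller_table(POLYSTYRENE_PHANTOM)
        scatter_event(p, table, rng, forced_angles=(theta, 0.0))
        p.exit_face = "top"
        p.position = np.array([0.0, 0.0, 0.0])
        return p

    def test_single_backscatter_is_co_linear(self):
        """Orthogonalized single-backscatter light lands in the CO channel."""
        grid = DetectorGrid(DetectorConfig(), BeamSpec())
        p = self._exiting_packet()
        detect_packet(p, grid)
        co = grid.channels[0].sum()
        cross = grid.channels[1].sum()
        assert co == pytest.approx(1.0, abs=1e-9)
        assert cross == pytest.approx(0.0, abs=1e-9)

    def test_single_backscatter_is_cross_circular(self):
        grid = DetectorGrid(
            DetectorConfig(), BeamSpec(incident_state="circular_right")
        )
        p = self._exiting_packet(state="circular_right")
        detect_packet(p, grid)
        assert grid.channels[3].sum() == pytest.approx(1.0, abs=1e-9)  # cross
        assert grid.channels[2].sum() == pytest.approx(0.0, abs=1e-9)  # co

    def test_analyzer_pair_completeness_and_bookkeeping(self):
        grid = DetectorGrid(DetectorConfig(acceptance_deg=30.0), BeamSpec())
        p = self._exiting_packet(theta=2.8)
        n_before = p.n_scatter
        detect_packet(p, grid)
        total = grid.channels[0] + grid.channels[1]
        assert total.sum() == pytest.approx(p.stokes.i, rel=1e-12)
        assert grid.nscatter_total.sum() == n_before
        assert grid.photon_count.sum() == 1

    def test_off_grid_exit_counted_not_binned(self):
        grid = DetectorGrid(DetectorConfig(field_mm=2.0), BeamSpec())
        p = self._exiting_packet()
        p.position = np.array([0.5, 0.0, 0.0])  # 5 mm off-axis, 2 mm field
        assert grid.add(p) is False
        assert grid.n_missed == 1
        assert grid.photon_count.sum() == 0


class TestRunSimulation:
    def test_deterministic_given_seed(self, phantom_medium):
        kw = dict(n_packets=20_000, seed=99, detector=DetectorConfig(nx=21, ny=21))
        a = run_simulation(phantom_medium, BeamSpec(), **kw)
        b = run_simulation(phantom_medium, BeamSpec(), **kw)
        for name in a.channels:
            assert np.array_equal(a.channels[name], b.channels[name])
        assert np.array_equal(a.photon_count, b.photon_count)
        assert a.detected == b.detected

    def test_energy_split_per_pixel(self, phantom_result):
        """co + cross equals the detected intensity image, for both pairs."""
        res = phantom_result
        lin = res.channels["co_linear"] + res.channels["cross_linear"]
        cir = res.channels["co_circular"] + res.channels["cross_circular"]
        scale = max(res.photon_count.max(), 1.0)
        assert np.max(np.abs(lin - res.photon_count)) < 1e-9 * scale
        assert np.max(np.abs(cir - res.photon_count)) < 1e-9 * scale
        assert res.detected <= res.launched

    def test_near_transparent_medium_barely_backscatters(self):
        medium = MediumSpec(mie=POLYSTYRENE_PHANTOM, mus_per_cm=0.01)
        res = run_simulation(
            medium, BeamSpec(), DetectorConfig(acceptance_deg=60.0),
            n_packets=100_000, seed=4,
        )
        assert res.detected / res.launched < 0.01

    def test_validation(self, phantom_medium):
        with pytest.raises(ValueError):
            run_simulation(phantom_medium, BeamSpec(), n_packets=0)
        with pytest.raises(ValueError):
            BeamSpec(incident_state="elliptical")
        with pytest.raises(ValueError):
            MediumSpec(mie=POLYSTYRENE_PHANTOM, mus_per_cm=-1.0)
        with pytest.raises(ValueError):
            DetectorConfig(acceptance_deg=0.0)
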