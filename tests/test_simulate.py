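"""Agent-based egress simulator: emission, motility, proliferation,
coverage rasterisation and recording rendering."""

import math

import numpy as np
import pytest

from zspread import (
    ElectrodeLayout,
    PhenotypeParams,
    Recording,
    coverage_series,
    preset,
    render_recording,
    simulate_agents,
    simulate_recording,
)
from zspread.simulate import SimulationRun


def quiet(**kw):
    defaults = dict(
        spheroid_radius=250.0,
        egress_rate=0.0,
        migration_speed_mean=0.0,
        migration_speed_sd=0.0,
        persistence=0.5,
        proliferation_rate=0.0,
    )
    defaults.update(kw)
    return PhenotypeParams(**defaults)


class TestSimulateAgents:
    def test_nothing_emitted_when_rates_zero(self):
        run = simulate_agents(quiet(), duration=48.0, dt=0.5, seed=1)
        assert run.emitted == 0
        assert np.all(run.counts == 0)

    def test_conservation_without_proliferation(self):
        run = simulate_agents(
            quiet(egress_rate=3.0, migration_speed_mean=10.0, migration_speed_sd=4.0),
            duration=72.0,
            dt=0.5,
            seed=5,
        )
        assert run.counts[-1] == run.emitted
        assert np.all(np.diff(run.counts) >= 0)

    def test_reproducible_from_seed(self):
        p = preset("intermediate")
        a = simulate_agents(p, duration=48.0, dt=0.5, seed=42)
        b = simulate_agents(p, duration=48.0, dt=0.5, seed=42)
        assert np.array_equal(a.counts, b.counts)
        assert all(np.array_equal(x, y) for x, y in zip(a.positions, b.positions))
        c = simulate_agents(p, duration=48.0, dt=0.5, seed=43)
        assert not all(
            np.array_equal(x, y) for x, y in zip(a.positions, c.positions)
        )

    def test_ballistic_limit_matches_closed_form(self):
        # persistence -> 1 with constant speed: every agent travels
        # radially outward at exactly speed*dt per step, so the largest
        # distance from the centre is rim + speed * (T - first emission)
        p = quiet(
            egress_rate=2.0,
            migration_speed_mean=5.0,
            migration_speed_sd=0.0,
            persistence=1.0 - 1e-12,
        )
        T, dt = 96.0, 0.5
        run = simulate_agents(p, duration=T, dt=dt, seed=9)
        assert run.emitted > 0
        r = np.linalg.norm(run.positions[-1], axis=1)
        # first emission happens at the first step with a Poisson hit;
        # bound: no agent can exceed rim + speed*T, and the furthest
        # agent must be close to that for an early first emission
        assert r.max() <= p.spheroid_radius + 5.0 * T + 1e-6
        emit_step = next(
            k for k in range(len(run.counts)) if run.counts[k] > 0
        )
        t_first = run.times[emit_step]
        expected = p.spheroid_radius + 5.0 * (T - t_first) + 5.0 * dt
        assert r.max() == pytest.approx(expected, rel=1e-6)

    def test_expected_count_matches_branching_oracle(self):
        # discrete-time branching: an agent present at step k carries
        # multiplier g = 2 - exp(-lambda*dt) per remaining step
        lam, r_emit, T, dt = 0.05, 5.0, 30.0, 0.5
        p = quiet(
            egress_rate=r_emit,
            migration_speed_mean=8.0,
            migration_speed_sd=3.0,
            persistence=0.8,
            proliferation_rate=lam,
        )
        n_steps = int(T / dt)
        g = 2.0 - math.exp(-lam * dt)
        expected = sum(
            r_emit * dt * g ** (n_steps - k) for k in range(n_steps)
        )
        finals = np.array(
            [
                simulate_agents(p, duration=T, dt=dt, seed=s).counts[-1]
                for s in range(60)
            ],
            dtype=float,
        )
        se = finals.std(ddof=1) / math.sqrt(len(finals))
        assert abs(finals.mean() - expected) <= 4 * se

    def test_mitomycin_suppresses_division(self):
        p = quiet(egress_rate=4.0, proliferation_rate=0.1, mitomycin=True)
        run = simulate_agents(p, duration=48.0, dt=0.5, seed=2)
        assert run.counts[-1] == run.emitted

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeParams(egress_rate=-1.0)
        with pytest.raises(ValueError):
            PhenotypeParams(persistence=1.0)
        with pytest.raises(ValueError):
            PhenotypeParams(migration_speed_mean=float("nan"))
        with pytest.raises(ValueError):
            simulate_agents(quiet(), duration=-5.0)


class TestCoverageSeries:
    def test_empty_run_zero_coverage(self, layout):
        p = quiet(spheroid_radius=100.0)  # too small to reach an electrode
        run = simulate_agents(p, duration=24.0, dt=0.5, seed=0)
        _, theta = coverage_series(run, layout)
        assert np.all(theta == 0)

    def test_single_agent_at_electrode_center(self, layout):
        p = quiet(spheroid_radius=100.0, cell_footprint=400.0)
        times = np.array([0.0])
        center = layout.centers()[2, 3]
        run = SimulationRun(
            times=times,
            positions=[center[None, :]],
            counts=np.array([1]),
            emitted=1,
            seed=0,
            params=p,
        )
        _, theta = coverage_series(run, layout, times=times)
        expected = 400.0 / layout.electrode_area
        assert theta[2, 3, 0] == pytest.approx(expected)
        theta[2, 3, 0] = 0.0
        assert np.all(theta == 0)

    def test_ring_of_agents_covers_enumerated_electrodes(self, layout):
        # agents on a dense ring of radius 580 um: the covered set is,
        # by direct enumeration of grid centre distances, the eight
        # electrodes at d = 540.8 um (+-450,+-300) and d = 618.5 um
        # (+-150,+-600), the only distances within 50 um of the ring
        p = quiet(spheroid_radius=100.0)
        ang = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        ring = 580.0 * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        run = SimulationRun(
            times=np.array([0.0]),
            positions=[ring],
            counts=np.array([len(ring)]),
            emitted=len(ring),
            seed=0,
            params=p,
        )
        _, theta = coverage_series(run, layout, times=np.array([0.0]))
        covered = theta[:, :, 0] > 0
        d = np.linalg.norm(layout.centers(), axis=-1)
        expected = np.abs(d - 580.0) <= layout.electrode_radius
        assert expected.sum() == 8
        assert np.array_equal(covered, expected)

    def test_spheroid_body_saturates_until_disassembly(self, layout):
        p = quiet(spheroid_radius=250.0, disassembly_time=48.0)
        run = simulate_agents(p, duration=96.0, dt=0.5, seed=0)
        times = np.array([0.0, 24.0, 48.0, 96.0])
        _, theta = coverage_series(run, layout, times=times)
        d = np.linalg.norm(layout.centers(), axis=-1)
        under = d <= 250.0
        assert under.sum() == 2
        assert np.all(theta[under, 0] == 1.0)
        assert np.all(theta[under, 1] == 1.0)
        assert np.all(theta[:, :, 2] == 0.0)  # body gone at t >= 48 h
        assert np.all(theta[:, :, 3] == 0.0)

    def test_theta_monotone_for_non_motile_agents(self, layout):
        # sanity preset: cells leave the rim but never move; coverage
        # can only accumulate
        p = quiet(egress_rate=5.0, spheroid_radius=250.0)
        run = simulate_agents(p, duration=96.0, dt=0.5, seed=4)
        times = np.arange(0.0, 96.1, 12.0)
        _, theta = coverage_series(run, layout, times=times)
        assert np.all(np.diff(theta, axis=2) >= 0)


class TestRenderRecording:
    def test_noise_free_zero_coverage_equals_baseline(self, layout, acquisition, circuit):
        nt = len(acquisition.time_points_h)
        theta = np.zeros((layout.n_rows, layout.n_cols, nt))
        rec = render_recording(
            theta,
            np.asarray(acquisition.time_points_h),
            layout=layout,
            circuit=circuit,
            acquisition=acquisition,
            noise_sd=0.0,
        )
        for j in range(nt):
            assert np.array_equal(rec.zmag[:, :, j, :], rec.baseline)

    def test_noise_magnitude_calibrated(self, circuit, acquisition):
        # 50 replicate spectra at fixed coverage: per-frequency sample
        # sd of |Z| within 3.5 Monte-Carlo standard errors of 1% of |Z|
        lay = ElectrodeLayout(n_cols=1, n_rows=1, n_wells=1)
        theta = np.full((1, 1, 1), 0.5)
        reps = np.stack(
            [
                render_recording(
                    theta,
                    np.array([0.0]),
                    layout=lay,
                    circuit=circuit,
                    acquisition=acquisition,
                    noise_sd=0.01,
                    seed=s,
                ).zmag[0, 0, 0]
                for s in range(50)
            ]
        )
        target = reps.mean(axis=0) * 0.01
        se = target / math.sqrt(2 * (50 - 1))
        assert np.all(np.abs(reps.std(axis=0, ddof=1) - target) <= 3.5 * se)

    def test_negative_noise_rejected(self, layout, acquisition):
        with pytest.raises(ValueError):
            render_recording(
                np.zeros((7, 6, 1)), np.array([0.0]), noise_sd=-0.1
            )


class TestPresets:
    def test_mitomycin_variant_differs_only_by_suppression(self):
        for base in ("fast", "intermediate", "slow"):
            u, m = preset(base), preset(f"{base}+mitomycin")
            assert m.mitomycin and not u.mitomycin
            assert m.effective_proliferation_rate == 0.0
            assert u.effective_proliferation_rate > 0.0
            for f in (
                "spheroid_radius",
                "egress_rate",
                "egress_delay",
                "migration_speed_mean",
                "migration_speed_sd",
                "persistence",
                "proliferation_rate",
                "disassembly_time",
                "cell_footprint",
            ):
                assert getattr(m, f) == getattr(u, f)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset("sluggish")

    def test_end_to_end_recording_reproducible(self):
        a = simulate_recording("slow", seed=7)
        b = simulate_recording("slow", seed=7)
        assert a == b
        assert a.zmag.shape == (7, 6, 7, 41)
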