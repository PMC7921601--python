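"""Synthetic-data generator: trajectories, populations, movies, curves."""

import numpy as np
import pytest
from scipy import integrate

from smstoich import (
    BindingKineticsConfig,
    CameraModel,
    ComplexStoichiometry,
    FluorophorePhotophysics,
    correct_stack,
    curve_delta,
    detect_foci,
    percent_inhibition,
    render_two_color_movie,
    simulate_aggregation,
    simulate_complex_population,
    simulate_trajectory,
    thin_by_labeling,
)


class TestSimulateTrajectory:
    def test_zero_fluorophores_zero_trace(self):
        traj, truth = simulate_trajectory(
            0, FluorophorePhotophysics(100, 10, 0.05), 50, noise_sd=0.0, seed=0
        )
        assert np.all(traj.intensities == 0.0)
        assert truth.bleach_frames.size == 0

    def test_three_identical_fluorophores_exact_staircase(self):
        pp = FluorophorePhotophysics(100.0, 0.0, 1 / 20)
        for seed in range(50):
            traj, truth = simulate_trajectory(3, pp, 200, noise_sd=0.0,
                                              seed=seed)
            bf = np.sort(truth.bleach_frames)
            if bf.max() < 200 and np.unique(bf).size == 3:
                break
        else:
            pytest.fail("no seed with three distinct in-window bleach frames")
        assert traj.intensities[0] == pytest.approx(300.0)
        assert traj.intensities[-1] == 0.0
        drops = -np.diff(traj.intensities)
        steps = drops[drops > 0]
        assert steps == pytest.approx([100.0, 100.0, 100.0])

    def test_transitions_match_ground_truth_bleach_frames(self):
        pp = FluorophorePhotophysics(150.0, 40.0, 1 / 25)
        for seed in range(30):
            traj, truth = simulate_trajectory(5, pp, 120, noise_sd=0.0,
                                              seed=seed)
            n_trans = np.count_nonzero(np.diff(traj.intensities))
            in_window = truth.bleach_frames[truth.bleach_frames < 120]
            assert n_trans == np.unique(in_window).size

    def test_noise_free_trace_is_non_increasing(self):
        pp = FluorophorePhotophysics(200.0, 60.0, 1 / 30)
        for seed in range(30):
            traj, _ = simulate_trajectory(6, pp, 150, noise_sd=0.0, seed=seed)
            assert np.all(np.diff(traj.intensities) <= 1e-9)

    def test_argument_errors(self):
        pp = FluorophorePhotophysics(100, 10, 0.05)
        with pytest.raises(ValueError):
            simulate_trajectory(-1, pp, 50)
        with pytest.raises(ValueError):
            simulate_trajectory(1, pp, 0)


class TestThinByLabeling:
    def test_certain_labeling(self):
        assert thin_by_labeling(7, 1.0, seed=0) == 7

    def test_zero_labeling(self):
        assert thin_by_labeling(7, 0.0, seed=0) == 0

    def test_binomial_expectation_at_paper_efficiency(self):
        # 10 subunits at 86% labeling: mean over 1e4 draws ~ 8.6 within 3 SE
        rng = np.random.default_rng(1)
        draws = [thin_by_labeling(10, 0.86, rng) for _ in range(10_000)]
        se = np.sqrt(10 * 0.86 * 0.14 / 10_000)
        assert abs(np.mean(draws) - 8.6) < 3 * se

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            thin_by_labeling(5, 1.2)


class TestComplexPopulation:
    def test_no_capture_when_k_bind_zero(self):
        cfg = BindingKineticsConfig(k_bind=0.0)
        snaps = simulate_complex_population(cfg, [0, 1, 5], 100, seed=0)
        assert all(s.bound_fraction == 0.0 for s in snaps)

    def test_stoichiometry_frozen_without_accretion(self):
        cfg = BindingKineticsConfig(k_bind=50.0, k_accrete=0.0, k_off=0.0,
                                    plateau_bound_fraction=1.0)
        snaps = simulate_complex_population(cfg, [1.0, 20.0], 200, seed=1)
        seed_sizes = set(cfg.shsp_seed_dist)
        late = snaps[-1]
        assert late.bound_fraction == 1.0
        assert {c.n_chaperone for c in late.complexes} <= seed_sizes
        # chaperone counts unchanged between snapshots
        early = sorted(c.n_chaperone for c in snaps[0].complexes)
        assert sorted(c.n_chaperone for c in late.complexes) == early

    def test_bound_fraction_monotone(self):
        cfg = BindingKineticsConfig()
        snaps = simulate_complex_population(
            cfg, [0, 0.5, 1, 2, 4, 8], 300, seed=3
        )
        fracs = [s.bound_fraction for s in snaps]
        assert fracs == sorted(fracs)

    def test_mean_accretion_matches_ode_oracle(self):
        # linear-rate regime (instant capture, no dissociation): the free
        # pool decays as dS/dt = -k_accrete * S * N / S0, so the mean
        # subunits per complex follow a closed-form / ODE solution exactly
        k_acc = 0.5
        n_clients = 200
        cfg = BindingKineticsConfig(
            k_bind=500.0, k_accrete=k_acc, k_off=0.0,
            plateau_bound_fraction=1.0, molar_ratio=4.0,
        )
        tps = [0.5, 2.0, 6.0]
        reps = 40
        seed_mean = sum(k * p for k, p in cfg.shsp_seed_dist.items())
        means = np.empty((reps, len(tps)))
        for r in range(reps):
            snaps = simulate_complex_population(cfg, tps, n_clients, seed=100 + r)
            for j, s in enumerate(snaps):
                means[r, j] = np.mean([c.n_chaperone for c in s.complexes])
        s0 = 4.0 * n_clients
        s1 = s0 - seed_mean * n_clients  # pool left after instant capture

        def ode(t, s):
            return [-k_acc * s[0] * n_clients / s0]

        sol = integrate.solve_ivp(ode, (0, max(tps)), [s1], t_eval=tps,
                                  rtol=1e-9)
        expected = seed_mean + (s1 - sol.y[0]) / n_clients
        mc = means.mean(axis=0)
        se = means.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mc - expected) < 3 * se + 1e-9)

    def test_empty_timepoints_error(self):
        with pytest.raises(ValueError):
            simulate_complex_population(BindingKineticsConfig(), [], 10)


class TestRenderMovie:
    def test_blank_movie_equals_offset(self):
        cam = CameraModel(offset=120.0, read_noise_sd=0.0, shape=(32, 32))
        sa, sb, _ = render_two_color_movie(
            [], FluorophorePhotophysics(100, 0, 0.01),
            FluorophorePhotophysics(100, 0, 0.01), cam, 5, seed=0
        )
        assert np.all(sa.frames == 120.0)
        assert np.all(sb.frames == 120.0)

    def test_aperture_sum_matches_psf_integral_oracle(self):
        # one noise-free focus: the aperture-summed signal equals the
        # trajectory value times the numerically integrated PSF mass
        from scipy.integrate import dblquad

        cam = CameraModel(offset=0.0, read_noise_sd=0.0, psf_sigma=1.2,
                          shape=(33, 33))
        pp = FluorophorePhotophysics(500.0, 0.0, 1e-6)
        pos = np.array([[16.3, 15.8]])
        sa, _, gt = render_two_color_movie(
            [ComplexStoichiometry(1, 0)], pp, pp, cam, 3, seed=0,
            positions=pos,
        )
        frame = sa.frames[0]
        rows, cols = np.mgrid[:33, :33]
        aperture = (rows - 16.3) ** 2 + (cols - 15.8) ** 2 <= 4.0**2
        measured = frame[aperture].sum()
        sig = 1.2

        def gauss(y, x):
            return (
                np.exp(-((y - 16.3) ** 2 + (x - 15.8) ** 2) / (2 * sig**2))
                / (2 * np.pi * sig**2)
            )

        mass, _ = dblquad(gauss, 16.3 - 4.5, 16.3 + 4.5,
                          15.8 - 4.5, 15.8 + 4.5)
        assert measured == pytest.approx(500.0 * mass, rel=0.02)

    def test_photon_conservation_per_frame(self):
        # total signal (offset removed) equals the sum of active
        # trajectory values up to PSF truncation at the patch edge
        cam = CameraModel(offset=50.0, read_noise_sd=0.0, psf_sigma=1.0,
                          shape=(64, 64))
        pp = FluorophorePhotophysics(200.0, 30.0, 1 / 40)
        complexes = [ComplexStoichiometry(3, 2) for _ in range(4)]
        sa, sb, gt = render_two_color_movie(complexes, pp, pp, cam, 30,
                                            seed=5)
        for stack, ch in ((sa, "A"), (sb, "B")):
            signal = stack.frames - 50.0
            expected = np.sum(
                [t.intensities for t in gt.trajectories[ch]], axis=0
            )
            assert signal.sum(axis=(1, 2)) == pytest.approx(
                expected, rel=1e-3, abs=1e-6
            )

    def test_two_close_foci_resolved_by_detection(self):
        cam = CameraModel(offset=100.0, read_noise_sd=2.0, psf_sigma=1.2,
                          shape=(48, 48))
        pp = FluorophorePhotophysics(400.0, 0.0, 1 / 500)
        pos = np.array([[20.0, 18.0], [20.0, 28.0]])  # 10 px apart
        sa, _, _ = render_two_color_movie(
            [ComplexStoichiometry(2, 0)] * 2, pp, pp, cam, 12, seed=2,
            positions=pos,
        )
        foci = detect_foci(correct_stack(sa, 100.0))
        assert len(foci) == 2

    def test_off_grid_position_error(self):
        cam = CameraModel(shape=(32, 32))
        pp = FluorophorePhotophysics(100, 0, 0.01)
        with pytest.raises(ValueError, match="inside"):
            render_two_color_movie(
                [ComplexStoichiometry(1, 1)], pp, pp, cam, 5, seed=0,
                positions=np.array([[40.0, 10.0]]),
            )


class TestSimulateAggregation:
    def test_full_suppression_gives_hundred_percent(self):
        ctrl, treat = simulate_aggregation(suppression=1.0, seed=0)
        assert np.all(treat.intensities == 0.0)
        res = percent_inhibition(curve_delta(ctrl), curve_delta(treat))
        assert res.percent == 100.0

    def test_no_suppression_gives_zero_percent(self):
        ctrl, treat = simulate_aggregation(suppression=0.0, seed=0)
        assert treat.intensities == pytest.approx(ctrl.intensities)
        res = percent_inhibition(curve_delta(ctrl), curve_delta(treat))
        assert res.percent == 0.0

    @pytest.mark.parametrize("s", [0.25, 0.6, 0.9])
    def test_intermediate_suppression_exact(self, s):
        ctrl, treat = simulate_aggregation(suppression=s, seed=0)
        res = percent_inhibition(curve_delta(ctrl), curve_delta(treat))
        assert res.percent == pytest.approx(100.0 * s)

    def test_curves_monotone_non_decreasing(self):
        ctrl, treat = simulate_aggregation(suppression=0.4, seed=0)
        assert np.all(np.diff(ctrl.intensities) >= -1e-12)
        assert np.all(np.diff(treat.intensities) >= -1e-12)

    def test_ratio_dependent_suppression_callable(self):
        ctrl, treat = simulate_aggregation(
            chaperone_ratio=2.0, suppression=lambda r: r / (1 + r), seed=0
        )
        res = percent_inhibition(curve_delta(ctrl), curve_delta(treat))
        assert res.percent == pytest.approx(100 * 2 / 3)
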