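"""Generator-level oracles: stochastic dynamics, balloon model, cohorts."""

import numpy as np
import pytest

from tmsdcm.hemodynamics import HemodynamicParams, integrate_balloon
from tmsdcm.synthetic import (
    NCECM_REGIONS,
    CohortConfig,
    EffectiveConnectivityMatrix,
    FluctuationSpec,
    TreatmentEffect,
    UnstableConnectivityError,
    analytic_state_spectrum,
    default_population_matrix,
    embed_volume,
    generate_cohort,
    hemodynamic_forward,
    make_block_atlas,
    simulate_neuronal,
)


class TestNeuronalSimulation:
    def test_no_driving_input_gives_zero_trajectory(self):
        fl = FluctuationSpec(alpha_state=0.0, beta_state=0.0, alpha_obs=0.0)
        traj = simulate_neuronal(-0.5 * np.eye(3), fl, duration=50.0, seed=0)
        assert np.all(traj.states == 0.0)

    def test_stationary_variance_matches_lyapunov_solution(self, white_fluct):
        # dx = -0.5 x + v, white v with two-sided PSD a: Var(x) = a / (2 * 0.5)
        traj = simulate_neuronal(-0.5 * np.eye(2), white_fluct, dt=0.05,
                                 duration=2500.0, seed=3)
        expected = white_fluct.alpha_state / (2 * 0.5)
        assert np.allclose(traj.states.var(axis=0), expected, rtol=0.05)

    def test_directed_coupling_shifts_cross_correlation_peak(self, white_fluct):
        # region 0 drives region 1: the cross-correlation peaks with region 1
        # lagging region 0 (positive lag), by brute-force lagged correlation
        A = np.array([[-0.5, 0.0], [0.3, -0.5]])
        traj = simulate_neuronal(A, white_fluct, dt=0.05, duration=3000.0, seed=4)
        x = traj.states
        lags = np.arange(-60, 61)
        cc = [
            np.corrcoef(
                x[max(0, -l): x.shape[0] - max(0, l), 0],
                x[max(0, l): x.shape[0] - max(0, -l), 1],
            )[0, 1]
            for l in lags
        ]
        assert lags[int(np.argmax(cc))] > 0

    def test_unstable_matrix_rejected_with_eigenvalues(self, white_fluct):
        A = np.array([[0.1, 0.0], [0.0, -0.5]])
        with pytest.raises(UnstableConnectivityError, match="eigenvalues"):
            simulate_neuronal(A, white_fluct, duration=10.0, seed=0)

    def test_periodogram_matches_analytic_spectrum_in_band(self):
        from scipy.signal import welch

        A = default_population_matrix().values
        fl = FluctuationSpec(alpha_state=1e-4, beta_state=1.0, alpha_obs=0.0)
        traj = simulate_neuronal(A, fl, dt=0.05, duration=8000.0, seed=5)
        f, p0 = welch(traj.states[:, 0], fs=20.0, nperseg=4096)
        band = (f >= 0.01) & (f <= 0.1)
        S = analytic_state_spectrum(A, fl, f[band])
        # one-sided periodogram = 2 x two-sided analytic PSD, band-averaged
        ratio = p0[band].mean() / (2 * S[:, 0, 0].real.mean())
        assert abs(ratio - 1.0) < 0.10


class TestHemodynamics:
    def test_zero_input_is_fixed_point(self):
        y = integrate_balloon(np.zeros((200, 2)), HemodynamicParams(), 0.05)
        assert np.allclose(y, 0.0, atol=1e-12)

    def test_impulse_response_peaks_at_3_to_8_seconds(self):
        dt = 0.05
        u = np.zeros((int(30 / dt), 1))
        u[: int(1 / dt)] = 1.0
        y = integrate_balloon(u, HemodynamicParams(), dt)
        peak_s = np.argmax(y[:, 0]) * dt
        assert 3.0 <= peak_s <= 8.0
        assert abs(y[-1, 0]) < 0.1 * y.max()  # returns toward baseline

    def test_small_signal_response_is_linear_in_epsilon(self):
        dt = 0.05
        u = np.zeros((int(30 / dt), 1))
        u[: int(1 / dt)] = 0.01
        y1 = integrate_balloon(u, HemodynamicParams(epsilon=1.0), dt)
        y2 = integrate_balloon(u, HemodynamicParams(epsilon=2.0), dt)
        assert y2.max() / y1.max() == pytest.approx(2.0, rel=0.10)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            HemodynamicParams(tau=-1.0)
        with pytest.raises(ValueError):
            HemodynamicParams(alpha=1.5)

    def test_tr_must_be_multiple_of_dt(self, white_fluct):
        traj = simulate_neuronal(-0.5 * np.eye(2), white_fluct, duration=20.0, seed=0)
        with pytest.raises(ValueError, match="multiple"):
            hemodynamic_forward(traj, HemodynamicParams(), TR=0.13)


class TestVolumeEmbedding:
    def test_noise_free_embedding_reproduces_roi_series(self, block_atlas):
        labels, affine, label_map = block_atlas
        rng = np.random.default_rng(0)
        series = rng.normal(size=(40, 5))
        img, limg = embed_volume(series, labels, affine, label_map, NCECM_REGIONS, 0.0, 0)
        data = np.asanyarray(img.dataobj)
        for r, name in enumerate(NCECM_REGIONS):
            m = np.isin(labels, label_map[name])
            assert np.allclose(data[m].mean(axis=0), series[:, r])

    def test_background_voxels_are_null(self, block_atlas):
        labels, affine, label_map = block_atlas
        rng = np.random.default_rng(1)
        series = rng.normal(size=(350, 5))
        img, _ = embed_volume(series, labels, affine, label_map, NCECM_REGIONS, 1.0, 2)
        data = np.asanyarray(img.dataobj)
        bg = data[labels == 0]
        assert abs(bg.mean()) < 0.05
        sub = bg[:: max(1, bg.shape[0] // 200)]
        r = np.corrcoef(np.vstack([sub, series.T]))[: sub.shape[0], sub.shape[0]:]
        assert np.abs(r).max() < 0.3

    def test_volume_roundtrip_preserves_values(self, block_atlas, tmp_path):
        import nibabel as nib

        labels, affine, label_map = block_atlas
        series = np.random.default_rng(3).normal(size=(20, 5))
        img, _ = embed_volume(series, labels, affine, label_map, NCECM_REGIONS, 0.1, 4)
        path = tmp_path / "vol.nii"
        img.to_filename(str(path))
        back = np.asanyarray(nib.load(str(path)).dataobj)
        assert np.allclose(back, np.asanyarray(img.dataobj), atol=1e-6)

    def test_overlapping_labels_rejected(self, block_atlas):
        labels, affine, label_map = block_atlas
        bad = {k: list(v) for k, v in label_map.items()}
        bad["PCUN"] = bad["HIP"]
        with pytest.raises(ValueError, match="more than one region"):
            embed_volume(np.zeros((10, 5)), labels, affine, bad, NCECM_REGIONS, 0.0, 0)


class TestCohortGeneration:
    def test_subject_count_and_sessions(self):
        cfg = CohortConfig(n_subjects=26, timeseries=False, seed=1)
        cohort = generate_cohort(cfg)
        assert len(cohort) == 26
        assert all(set(r.sessions) == {"pre", "post"} for r in cohort)

    def test_identical_config_is_bit_reproducible(self):
        cfg = CohortConfig(n_subjects=4, n_volumes=60, seed=9)
        c1 = generate_cohort(cfg)
        c2 = generate_cohort(CohortConfig(n_subjects=4, n_volumes=60, seed=9))
        for a, b in zip(c1, c2):
            for s in ("pre", "post"):
                assert np.array_equal(a.sessions[s].roi_series, b.sessions[s].roi_series)
                assert np.array_equal(a.sessions[s].A_true, b.sessions[s].A_true)
            assert a.clinical.equals(b.clinical)

    def test_no_generated_matrix_is_unstable(self, small_cohort):
        for rec in small_cohort:
            for s in ("pre", "post"):
                ev = np.linalg.eigvals(rec.sessions[s].A_true)
                assert np.all(ev.real < 0)

    def test_zero_effect_zero_noise_gives_deterministic_reductions(self):
        from tmsdcm.synthetic import ClinicalEffect

        effects = {
            "BSI-CV": ClinicalEffect(18.0, 0.0, {"post": 0.65}, weights={}, noise_sd=0.0)
        }
        cfg = CohortConfig(
            n_subjects=6, timeseries=False, seed=2,
            treatment_effect=TreatmentEffect({}), clinical_effects=effects,
            n_missing_week4=0,
        )
        for rec in generate_cohort(cfg):
            wide = rec.clinical.pivot_table(index="scale", columns="timepoint", values="value")
            red = (wide.loc["BSI-CV", "baseline"] - wide.loc["BSI-CV", "post"]) / wide.loc["BSI-CV", "baseline"]
            assert red == pytest.approx(0.65, abs=1e-12)

    def test_planted_connectivity_outcome_correlation(self):
        # negative weight on the HIP->INS shift: correlation between the true
        # shift and the generated reduction must be reliably negative
        negatives = 0
        n_cohorts = 100
        for seed in range(n_cohorts):
            cfg = CohortConfig(n_subjects=26, timeseries=False, seed=1000 + seed,
                               n_missing_week4=0)
            cohort = generate_cohort(cfg)
            shifts = np.array([r.shifts[("INS", "HIP")] for r in cohort])
            reds = []
            for r in cohort:
                wide = r.clinical.pivot_table(index="scale", columns="timepoint", values="value")
                b, f = wide.loc["BSI-CV", "baseline"], wide.loc["BSI-CV", "post"]
                reds.append((b - f) / b)
            r_val = np.corrcoef(shifts, reds)[0, 1]
            if r_val < 0:
                negatives += 1
        assert negatives >= 95

    def test_unknown_connection_in_clinical_effect_rejected(self):
        from tmsdcm.synthetic import ClinicalEffect

        effects = {"BSI-CV": ClinicalEffect(18, 7, {"post": 0.6}, weights={("FOO", "BAR"): 1.0})}
        with pytest.raises(ValueError, match="unknown connection"):
            CohortConfig(n_subjects=2, clinical_effects=effects)

    def test_matrix_validation(self):
        with pytest.raises(ValueError, match="finite"):
            EffectiveConnectivityMatrix(np.array([[np.nan, 0], [0, -1.0]]), ("a", "b"))
        with pytest.raises(ValueError):
            CohortConfig(n_volumes=10)
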