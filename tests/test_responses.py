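"""ΔF/F, response amplitudes, significance calibration, selectivity t-scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bulbswitch as bw
from bulbswitch.responses import BaselineStats, frame_window
from bulbswitch.synthgen import trial_amplitudes

from conftest import noiseless_config


def _session_from_traces(traces, onsets, frame_rate=30.0, odours=None):
    n_rois, n_frames = traces.shape
    trials = []
    for i, onset in enumerate(onsets):
        odour = (odours or ["alpha"] * len(onsets))[i]
        trials.append(bw.TrialRecord(
            trial_id=i, epoch="Fine1", odour=odour,
            rewarded=odour == "alpha", probe=False, odour_onset=onset))
    return bw.SessionData(trials=trials, traces=traces, sniff=np.zeros(n_frames),
                          frame_rate=frame_rate)


class TestDff:
    def test_constant_trace_gives_zero(self):
        traces = np.full((2, 600), 80.0)
        session = _session_from_traces(traces, [10.0])
        dff, base = bw.compute_dff(session)
        np.testing.assert_allclose(dff, 0.0, atol=1e-14)
        np.testing.assert_allclose(base.f0, 80.0)

    def test_single_frame_closed_form(self):
        traces = np.full((1, 600), 100.0)
        traces[0, 310] = 150.0  # one frame at 1.5 x F0, outside the baseline window
        session = _session_from_traces(traces, [10.0])
        dff, _ = bw.compute_dff(session)
        assert np.isclose(dff[0, 310], 0.5)

    def test_matches_formula_oracle_elementwise(self):
        rng = np.random.default_rng(3)
        traces = 100.0 + rng.normal(0, 5, (3, 900))
        onsets = [10.0, 20.0]
        session = _session_from_traces(traces, onsets)
        dff, base = bw.compute_dff(session, baseline_window=2.0)
        fr = session.frame_rate
        for i, onset in enumerate(onsets):
            f0 = traces[:, frame_window(onset - 2.0, onset, fr)].mean(axis=1)
            np.testing.assert_allclose(base.f0[:, i], f0, atol=1e-12)
            win = frame_window(onset, onset + 1.0, fr)
            np.testing.assert_allclose(
                dff[:, win], (traces[:, win] - f0[:, None]) / f0[:, None], atol=1e-12)

    def test_nonpositive_f0_rejected_with_location(self):
        traces = np.full((2, 600), 100.0)
        traces[1, :] = -1.0
        session = _session_from_traces(traces, [10.0])
        with pytest.raises(ValueError, match="ROI 1"):
            bw.compute_dff(session)


class TestAmplitude:
    def test_zero_trace_zero_amplitude(self):
        session = _session_from_traces(np.full((1, 600), 50.0), [10.0])
        dff, base = bw.compute_dff(session)
        table = bw.response_amplitude(session, dff, base)
        assert table.amplitudes[0, 0] == 0.0

    def test_linear_ramp_matches_direct_mean_oracle(self):
        fr = 30.0
        traces = np.full((1, 600), 100.0)
        win = frame_window(10.0, 11.0, fr)
        ramp = np.linspace(0.0, 1.0, win.stop - win.start)
        traces[0, win] = 100.0 * (1.0 + ramp)
        session = _session_from_traces(traces, [10.0])
        dff, base = bw.compute_dff(session)
        table = bw.response_amplitude(session, dff, base)
        assert np.isclose(table.amplitudes[0, 0], ramp.mean(), atol=1e-12)
        assert abs(table.amplitudes[0, 0] - 0.5) < 0.02  # ~0.5 up to discretization

    def test_noiseless_generated_amplitudes_match_ground_truth(self, noiseless_session):
        session, gt = noiseless_session
        table = bw.compute_responses(session)
        rates = gt.trial_sniff_rate
        cfg = noiseless_config()
        expected = trial_amplitudes(session.trials, gt, rates, cfg, rng=None)
        np.testing.assert_allclose(table.amplitudes, expected, atol=1e-9)

    def test_truncated_window_dropped_with_warning(self):
        traces = np.full((1, 600), 100.0)
        session = _session_from_traces(traces, [10.0, 19.5])  # second window truncated
        dff, base = bw.compute_dff(session)
        with pytest.warns(UserWarning, match="truncated"):
            table = bw.response_amplitude(session, dff, base)
        assert table.n_trials == 1

    def test_amplitude_linearity_in_dff(self):
        rng = np.random.default_rng(0)
        traces = 100.0 * (1.0 + np.abs(rng.normal(0, 0.05, (2, 600))))
        session = _session_from_traces(traces, [10.0])
        dff, base = bw.compute_dff(session)
        t1 = bw.response_amplitude(session, dff, base)
        t3 = bw.response_amplitude(session, 3.0 * dff, base)
        np.testing.assert_allclose(t3.amplitudes, 3.0 * t1.amplitudes, atol=1e-12)


class TestSignificance:
    def _table(self, amps, sd):
        amps = np.asarray(amps, dtype=float)
        n_rois, n_trials = amps.shape
        import pandas as pd
        trials = pd.DataFrame({
            "trial_id": range(n_trials), "epoch": "Fine1", "task": "fine",
            "odour": "alpha", "rewarded": True, "probe": False,
            "odour_onset": 10.0 + 21.0 * np.arange(n_trials)})
        base = BaselineStats(f0=np.full(amps.shape, 100.0), sd=np.asarray(sd, float))
        return bw.ResponseTable(amplitudes=np.asarray(amps, float), trials=trials,
                                baseline=base)

    def test_zero_baseline_noise_flags_any_response(self):
        table = bw.detect_significant_response(self._table([[1e-6, 0.0]], [0.0]))
        assert table.significant.tolist() == [[True, False]]

    def test_boundary_is_strict(self):
        # |a| exactly equal to 3 sd is NOT significant (strict inequality)
        sd = 0.04
        table = bw.detect_significant_response(
            self._table([[3 * sd, 3 * sd + 1e-12, -3 * sd]], [sd]))
        assert table.significant.tolist() == [[False, True, False]]

    def test_monotone_in_magnitude(self):
        rng = np.random.default_rng(2)
        amps = rng.normal(0, 0.1, (1, 50))
        table = bw.detect_significant_response(self._table(amps, [0.05]))
        flagged = np.abs(amps[0])[table.significant[0]]
        unflagged = np.abs(amps[0])[~table.significant[0]]
        if flagged.size and unflagged.size:
            assert flagged.min() > unflagged.max() - 1e-12

    def test_pure_noise_rate_matches_monte_carlo_null(self):
        """On a response-free cohort the flagged fraction sits at the 3-sd
        two-sided Gaussian tail, checked against a Monte-Carlo oracle that
        replicates the statistic's geometry (30-frame window vs 60-frame F0,
        sd estimated from the session's own trials)."""
        cfg = noiseless_config(
            noise_sd=0.1, n_animals=1, rois_per_animal=120,
            epoch_length_range=(20, 20),
            base_amplitude_range=(0.0, 0.0), selectivity_gap_range=(0.0, 0.0),
            beta_amplitude_range=(0.0, 0.0), frac_modulated=0.0, modulation_delta=0.0)
        session, _ = bw.generate_session(cfg, seed=77, n_rois=120)
        table = bw.compute_responses(session)
        rate = table.significant.mean()

        rng = np.random.default_rng(99)
        n_trials = table.n_trials
        reps = 4000
        # each replicate: one ROI-session of pure noise amplitudes + sd estimate
        a = rng.normal(0, 1, (reps, n_trials)) / np.sqrt(30) \
            - rng.normal(0, 1, (reps, n_trials)) / np.sqrt(60)
        null = rng.normal(0, 1, (reps, n_trials)) / np.sqrt(30) \
            - rng.normal(0, 1, (reps, n_trials)) / np.sqrt(60)
        sd_hat = null.std(axis=1, ddof=1, keepdims=True)
        oracle = (np.abs(a) > 3 * sd_hat).mean()
        se = np.sqrt(oracle * (1 - oracle) / table.significant.size
                     + oracle * (1 - oracle) / (reps * n_trials))
        assert abs(rate - oracle) < 4 * se + 1e-3


class TestSelectivity:
    def _table_two_groups(self, alpha_vals, ap_vals):
        import pandas as pd
        amps = np.array([list(alpha_vals) + list(ap_vals)])
        n_a = len(alpha_vals)
        n = amps.shape[1]
        trials = pd.DataFrame({
            "trial_id": range(n), "epoch": "Fine1", "task": "fine",
            "odour": ["alpha"] * n_a + ["alphaprime"] * (n - n_a),
            "rewarded": [True] * n_a + [False] * (n - n_a),
            "probe": False, "odour_onset": 10.0 + 21.0 * np.arange(n)})
        return bw.ResponseTable(amplitudes=amps, trials=trials)

    def test_identical_groups_t_zero(self):
        res = bw.selectivity_tscore(self._table_two_groups([0.2, 0.3, 0.4], [0.2, 0.3, 0.4]))
        assert res.t[0] == 0.0 and res.s[0] == 0.0

    def test_swap_antisymmetry(self):
        a, b = [0.5, 0.6, 0.7], [0.1, 0.2, 0.3]
        r1 = bw.selectivity_tscore(self._table_two_groups(a, b))
        r2 = bw.selectivity_tscore(self._table_two_groups(b, a))
        assert np.isclose(r1.t[0], -r2.t[0])
        assert np.isclose(r1.s[0], r2.s[0])
        assert r1.preferred[0] == "alpha" and r2.preferred[0] == "alphaprime"

    def test_pooled_variance_formula_oracle(self):
        a = np.array([0.5, 0.6, 0.7])
        b = np.array([0.1, 0.2, 0.3])
        res = bw.selectivity_tscore(self._table_two_groups(a, b))
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert abs(res.t[0] - t_oracle) < 1e-10

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(scale=st.floats(0.1, 10.0), shift=st.floats(-5.0, 5.0))
    def test_t_invariant_to_common_affine_rescale(self, scale, shift):
        rng = np.random.default_rng(6)
        a = rng.normal(0.4, 0.1, 6).tolist()
        b = rng.normal(0.2, 0.1, 6).tolist()
        r1 = bw.selectivity_tscore(self._table_two_groups(a, b))
        r2 = bw.selectivity_tscore(self._table_two_groups(
            [scale * x + shift for x in a], [scale * x + shift for x in b]))
        assert np.isclose(r1.t[0], r2.t[0], atol=1e-8)

    def test_insufficient_trials_raise(self):
        with pytest.raises(ValueError):
            bw.selectivity_tscore(self._table_two_groups([0.1], [0.2, 0.3]))

    def test_noiseless_sign_matches_ground_truth(self):
        cohort = bw.generate_cohort(noiseless_config(), seed=31)
        for session, gt in cohort:
            table = bw.compute_responses(bw.equalize_fine_epochs(session))
            res = bw.selectivity_tscore(table)
            for r in range(table.n_rois):
                if gt.selectivity_class[r] == "alpha":
                    assert res.t[r] > 0
                elif gt.selectivity_class[r] == "alphaprime":
                    assert res.t[r] < 0
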