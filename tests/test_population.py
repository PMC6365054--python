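"""Pseudo-population assembly, PCA trajectories, correlation/removal, decoding,
selectivity enrichment — each against an independent oracle where one exists."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bulbswitch as bw
from bulbswitch.population import PseudoPopulation, _condition_mask
from bulbswitch.responses import compute_dff, frame_window

from conftest import small_config


def simple_table(alpha, alphaprime, animal="mA", session="mA_s1", beta=None,
                 coarse_alpha=None):
    """ResponseTable with per-ROI amplitude vectors repeated over a few trials."""
    alpha = np.asarray(alpha, float)
    alphaprime = np.asarray(alphaprime, float)
    blocks, odours, tasks, epochs, rewarded = [], [], [], [], []

    def add(vals, odour, task, epoch, rew, n=3):
        for k in range(n):
            blocks.append(vals + 0.0)
            odours.append(odour)
            tasks.append(task)
            epochs.append(epoch)
            rewarded.append(rew)

    add(alpha, "alpha", "fine", "Fine1", True)
    add(alphaprime, "alphaprime", "fine", "Fine1", False)
    if coarse_alpha is not None:
        add(np.asarray(coarse_alpha, float), "alpha", "coarse", "Coarse", True)
    if beta is not None:
        add(np.asarray(beta, float), "beta", "coarse", "Coarse", False)
    amps = np.column_stack(blocks)
    n = amps.shape[1]
    trials = pd.DataFrame({
        "trial_id": range(n), "epoch": epochs, "task": tasks, "odour": odours,
        "rewarded": rewarded, "probe": False,
        "odour_onset": 10.0 + 21.0 * np.arange(n)})
    return bw.ResponseTable(amplitudes=amps, trials=trials,
                            animal_id=animal, session_id=session)


class TestPseudoPopulation:
    def test_shape_and_row_order(self, small_session):
        session, _ = small_session
        pop = bw.build_pseudopopulation([bw.equalize_fine_epochs(session)])
        assert pop.matrix.shape == (session.n_rois, 4 * pop.n_timepoints)
        assert list(pop.provenance["roi"]) == list(range(session.n_rois))
        assert (pop.provenance["session_id"] == session.session_id).all()

    def test_condition_block_is_trial_mean_oracle(self, small_session):
        session, _ = small_session
        eq = bw.equalize_fine_epochs(session)
        pop = bw.build_pseudopopulation([eq], window=(-1.0, 2.0))
        dff, _ = compute_dff(eq)
        trials = eq.trials_frame()
        cols = np.flatnonzero(_condition_mask(trials, "alpha:coarse"))
        fr = eq.frame_rate
        segs = []
        for c in cols:
            onset = trials["odour_onset"].iloc[c]
            start = frame_window(onset - 1.0, onset + 2.0, fr).start
            segs.append(dff[:, start:start + pop.n_timepoints])
        np.testing.assert_allclose(pop.block("alpha:coarse"),
                                   np.mean(segs, axis=0), atol=1e-12)

    def test_missing_condition_excluded_with_warning(self, small_session):
        session, _ = small_session
        with pytest.warns(UserWarning, match="excluded"):
            with pytest.raises(ValueError):
                bw.build_pseudopopulation(
                    [session], conditions=("beta:fine",))  # beta never occurs in fine


class TestPca:
    def test_rank_one_data_pc1_explains_everything(self):
        t = np.linspace(0, 1, 40)
        direction = np.array([1.0, -2.0, 0.5, 3.0])
        matrix = np.outer(direction, t) + 0.3
        pop = PseudoPopulation(matrix=matrix, conditions=("c:fine",), n_timepoints=40,
                               times=t, provenance=pd.DataFrame({"roi": range(4)}))
        traj = bw.pca_trajectories(pop, n_components=2)
        assert traj.explained_variance_ratio[0] > 1.0 - 1e-9

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(12)
        matrix = rng.normal(0, 1, (5, 4))
        pop = PseudoPopulation(matrix=matrix, conditions=("c:fine",), n_timepoints=4,
                               times=np.arange(4.0), provenance=pd.DataFrame({"roi": range(5)}))
        traj = bw.pca_trajectories(pop, n_components=3)
        centred = matrix - matrix.mean(axis=1, keepdims=True)
        cov = centred @ centred.T / (matrix.shape[1] - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for k in range(3):
            comp = v[:, k]
            if comp[np.argmax(np.abs(comp))] < 0:
                comp = -comp
            np.testing.assert_allclose(traj.components[k], comp, atol=1e-8)
        evr_oracle = w / w.sum()
        np.testing.assert_allclose(traj.explained_variance_ratio, evr_oracle[:3], atol=1e-8)
        # projections: scores equal loadings . centred columns
        scores_oracle = (traj.components @ centred).T
        np.testing.assert_allclose(traj.coords["c:fine"], scores_oracle, atol=1e-8)

    def test_projected_scores_are_centred(self):
        rng = np.random.default_rng(3)
        matrix = rng.normal(0, 1, (6, 30))
        pop = PseudoPopulation(matrix=matrix, conditions=("c:fine",), n_timepoints=30,
                               times=np.arange(30.0), provenance=pd.DataFrame({"roi": range(6)}))
        traj = bw.pca_trajectories(pop)
        np.testing.assert_allclose(traj.coords["c:fine"].mean(axis=0), 0.0, atol=1e-10)

    def test_fewer_rois_than_components_warns(self):
        matrix = np.random.default_rng(0).normal(0, 1, (2, 10))
        pop = PseudoPopulation(matrix=matrix, conditions=("c:fine",), n_timepoints=10,
                               times=np.arange(10.0), provenance=pd.DataFrame({"roi": range(2)}))
        with pytest.warns(UserWarning, match="components"):
            traj = bw.pca_trajectories(pop, n_components=3)
        assert traj.components.shape[0] == 2


class TestCorrelation:
    def test_identical_vectors_r_one(self):
        v = [0.1, 0.4, 0.3, 0.8]
        df = bw.response_correlation([simple_table(v, v)])
        assert np.isclose(df["r"].iloc[0], 1.0)

    def test_antipodal_r_minus_one(self):
        a = np.array([0.1, 0.4, 0.3, 0.8])
        b = a.mean() - 2.0 * (a - a.mean())
        df = bw.response_correlation([simple_table(a, b)])
        assert np.isclose(df["r"].iloc[0], -1.0)

    def test_matches_textbook_pearson_oracle(self):
        a = np.array([0.12, 0.55, 0.31, 0.78])
        b = np.array([0.20, 0.49, 0.40, 0.61])
        df = bw.response_correlation([simple_table(a, b)])
        ac, bc = a - a.mean(), b - b.mean()
        r_oracle = (ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc))
        assert abs(df["r"].iloc[0] - r_oracle) < 1e-12

    def test_zero_variance_flagged_nan(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            df = bw.response_correlation([simple_table([0.2] * 4, [0.1, 0.2, 0.3, 0.4])])
        assert np.isnan(df["r"].iloc[0])


class TestRemovalChange:
    def test_empty_removal_change_zero(self):
        table = simple_table([0.1, 0.4, 0.3, 0.8], [0.2, 0.5, 0.4, 0.6])
        cc = bw.removal_correlation_change([table], [np.zeros(4, bool)],
                                           n_random_replicates=5, seed=0)
        assert cc.per_group["change_pct"].iloc[0] == 0.0
        assert np.all(cc.random_changes == 0.0)

    def test_six_roi_worked_example_matches_brute_force(self):
        a = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.9])
        b = np.array([0.12, 0.18, 0.33, 0.38, 0.52, 0.1])  # last ROI diverges
        mask = np.array([False] * 5 + [True])
        table = simple_table(a, b)
        cc = bw.removal_correlation_change([table], [mask], n_random_replicates=3, seed=1)

        def pearson(x, y):
            xc, yc = x - x.mean(), y - y.mean()
            return (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))

        r_full = pearson(a, b)
        r_removed = pearson(a[:5], b[:5])
        expected = 100.0 * (r_removed - r_full) / r_full
        assert abs(cc.per_group["change_pct"].iloc[0] - expected) < 1e-10

    def test_r_full_invariant_to_roi_order(self):
        rng = np.random.default_rng(8)
        a, b = rng.uniform(0, 1, 8), rng.uniform(0, 1, 8)
        perm = rng.permutation(8)
        c1 = bw.removal_correlation_change([simple_table(a, b)], [np.zeros(8, bool)],
                                           n_random_replicates=1, seed=0)
        c2 = bw.removal_correlation_change([simple_table(a[perm], b[perm])],
                                           [np.zeros(8, bool)], n_random_replicates=1, seed=0)
        assert np.isclose(c1.per_group["r_full"].iloc[0], c2.per_group["r_full"].iloc[0])

    def test_removal_set_must_be_proper_subset(self):
        table = simple_table([0.1, 0.2, 0.3], [0.2, 0.3, 0.4])
        with pytest.raises(ValueError):
            bw.removal_correlation_change([table], [np.ones(3, bool)])


class TestDecoder:
    def test_widely_separated_classes_decode_perfectly(self):
        # class means split by a margin far above the within-class spread
        rng = np.random.default_rng(1)
        n = 6
        labels = np.array([True] * n + [False] * n)
        means = np.where(labels, 1.0, -1.0)
        amps = means[None, :] + rng.normal(0, 0.01, (5, 2 * n))
        trials = pd.DataFrame({
            "trial_id": range(2 * n), "epoch": "Fine1", "task": "fine",
            "odour": np.where(labels, "alpha", "alphaprime"),
            "rewarded": labels, "probe": False,
            "odour_onset": 10.0 + 21.0 * np.arange(2 * n)})
        table = bw.ResponseTable(amplitudes=amps, trials=trials)
        rep = bw.train_eval_decoder(table, task="fine", n_repeats=10, seed=0)
        assert rep.accuracy == 100.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(2)
        n = 12
        amps = rng.normal(0.5, 0.2, (6, 2 * n))
        labels = rng.permutation([True] * n + [False] * n)
        trials = pd.DataFrame({
            "trial_id": range(2 * n), "epoch": "Fine1", "task": "fine",
            "odour": np.where(labels, "alpha", "alphaprime"),
            "rewarded": labels, "probe": False,
            "odour_onset": 10.0 + 21.0 * np.arange(2 * n)})
        table = bw.ResponseTable(amplitudes=amps, trials=trials)
        rep = bw.train_eval_decoder(table, task="fine", n_repeats=200, seed=3)
        assert 30.0 < rep.accuracy < 70.0

    def test_predictions_match_closed_form_lda_oracle(self):
        """Shared-covariance discriminant on a fixed 2-D dataset: w = S^-1 (m1 - m0)."""
        X0 = np.array([[0.0, 0.0], [0.2, 0.1], [0.1, 0.3], [0.3, 0.2], [-0.1, 0.1]])
        X1 = X0 + np.array([1.0, 0.6])
        X = np.vstack([X0, X1])
        y = np.array([0] * 5 + [1] * 5)
        m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
        S = ((X0 - m0).T @ (X0 - m0) + (X1 - m1).T @ (X1 - m1)) / (len(X) - 2)
        w = np.linalg.solve(S, m1 - m0)
        c = w @ (m0 + m1) / 2.0
        grid = np.array([[0.4, 0.2], [0.6, 0.5], [1.2, 0.4], [0.1, 0.9], [0.5, 0.3]])
        oracle = (grid @ w > c).astype(int)

        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=None, priors=[0.5, 0.5])
        clf.fit(X, y)
        np.testing.assert_array_equal(clf.predict(grid), oracle)
        decision = grid @ w - c
        np.testing.assert_allclose(
            clf.decision_function(grid) / np.abs(clf.decision_function(grid)),
            np.sign(decision), atol=1e-8)

    def test_too_few_trials_per_class(self):
        table = simple_table([0.1, 0.2], [0.3, 0.4])
        with pytest.raises(ValueError):
            bw.train_eval_decoder(table, task="coarse")


class TestEnrichment:
    @staticmethod
    def _selres(s_vals, p_vals=None):
        s_vals = np.asarray(s_vals, float)
        p = np.asarray(p_vals, float) if p_vals is not None else np.full(s_vals.size, 0.5)
        return bw.SelectivityResult(t=s_vals.copy(), p=p, s=np.abs(s_vals),
                                    preferred=np.where(s_vals > 0, "alpha",
                                                       "alphaprime").astype(object),
                                    n_alpha=5, n_alphaprime=5)

    @staticmethod
    def _modres(flags):
        flags = np.asarray(flags, bool)
        z = np.zeros(flags.size)
        return bw.ModulationResult(t=z, p=np.where(flags, 0.01, 0.5), modulated=flags,
                                   mean_fine_alpha=z, mean_coarse_alpha=z, delta=z)

    def test_identical_distributions_ks_zero(self):
        s = [0.5, 1.0, 1.5, 2.0]
        res = bw.selectivity_enrichment(
            [self._selres(s + s)], [self._modres([True] * 4 + [False] * 4)])
        assert res.ks_statistic == 0.0

    def test_ks_matches_ecdf_gap_oracle(self):
        mod_s = np.array([0.2, 0.9, 1.7, 2.4])
        non_s = np.array([0.1, 0.3, 0.5, 1.1, 1.3])
        res = bw.selectivity_enrichment(
            [self._selres(np.concatenate([mod_s, non_s]))],
            [self._modres([True] * 4 + [False] * 5)])
        grid = np.concatenate([mod_s, non_s])
        gaps = [abs((mod_s <= x).mean() - (non_s <= x).mean()) for x in grid]
        assert abs(res.ks_statistic - max(gaps)) < 1e-12

    def test_modulated_rois_have_larger_selectivity_on_default_cohort(
            self, default_tables, default_modulation):
        selectivity = [bw.selectivity_tscore(t) for t in default_tables]
        res = bw.selectivity_enrichment(selectivity, default_modulation)
        assert res.ks_p < 0.05
        s = np.concatenate([r.s for r in selectivity])
        mod = np.concatenate([m.modulated for m in default_modulation])
        assert np.median(s[mod]) > np.median(s[~mod])
        assert res.frac_selective_modulated > res.frac_modulated

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            bw.selectivity_enrichment([self._selres([1.0, 2.0])],
                                      [self._modres([True, True])])
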