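"""Per-ROI task-modulation testing with shuffle calibration and sniff control.

The core statistic: for each ROI, alpha-trial (S+) response amplitudes from
the fine epochs (Fine1 + Fine2, equalized) are compared with those from the
coarse epoch (probe trials excluded) by a two-tailed pooled-variance
two-sample t-test.  ROIs with p below the significance level are called
task-modulated.

The shuffle control permutes the fine/coarse task labels across each
session's S+ alpha trials (group sizes preserved) and re-runs the test,
calibrating the expected false-positive count.  The sniff control regresses
amplitudes on respiration features (rate, first-inhalation latency,
inhalation count in the odour window) pooled across tasks and re-runs the
task test on the residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .responses import ResponseTable
from .session_io import SessionData

__all__ = [
    "ModulationResult",
    "ShuffleCalibration",
    "SwitchingTimecourse",
    "task_modulation_test",
    "shuffle_control",
    "detect_inhalation_onsets",
    "extract_sniff_features",
    "residualize_on_sniff",
    "switching_timecourse",
]

ALPHA_LEVEL = 0.05  # two-tailed; pinned by the ~5% shuffle-control rate


@dataclass
class ModulationResult:
    """Per-ROI fine-vs-coarse test on alpha-trial amplitudes."""

    t: np.ndarray
    p: np.ndarray
    modulated: np.ndarray          # p < alpha_level
    mean_fine_alpha: np.ndarray
    mean_coarse_alpha: np.ndarray
    delta: np.ndarray              # mean_fine_alpha − mean_coarse_alpha
    alpha_level: float = ALPHA_LEVEL
    variant: str = "raw"
    animal_id: str = "animal0"
    session_id: str = "session0"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "roi": np.arange(len(self.t)),
            "t_task": self.t, "p_task": self.p, "modulated": self.modulated,
            "mean_fine_alpha": self.mean_fine_alpha,
            "mean_coarse_alpha": self.mean_coarse_alpha,
            "delta": self.delta, "variant": self.variant,
            "animal_id": self.animal_id, "session_id": self.session_id,
        })


def _alpha_pools(table: ResponseTable) -> tuple[np.ndarray, np.ndarray]:
    """Column masks for fine-task and coarse-task S+ alpha trials (no probes)."""
    fine = table.trial_mask(odour="alpha", task="fine", rewarded=True, probe=False)
    coarse = table.trial_mask(odour="alpha", task="coarse", rewarded=True, probe=False)
    return fine, coarse


def task_modulation_test(table: ResponseTable,
                         alpha_level: float = ALPHA_LEVEL) -> ModulationResult:
    """Two-tailed two-sample t per ROI: fine vs coarse alpha amplitudes."""
    fine_mask, coarse_mask = _alpha_pools(table)
    if fine_mask.sum() < 2 or coarse_mask.sum() < 2:
        raise ValueError(
            f"need >= 2 alpha trials per task (got {int(fine_mask.sum())} fine, "
            f"{int(coarse_mask.sum())} coarse)")
    fine = table.amplitudes[:, fine_mask]
    coarse = table.amplitudes[:, coarse_mask]
    t, p = stats.ttest_ind(fine, coarse, axis=1, equal_var=True)
    mf, mc = fine.mean(axis=1), coarse.mean(axis=1)
    return ModulationResult(
        t=np.asarray(t, float), p=np.asarray(p, float),
        modulated=np.asarray(p, float) < alpha_level,
        mean_fine_alpha=mf, mean_coarse_alpha=mc, delta=mf - mc,
        alpha_level=alpha_level, variant=table.variant,
        animal_id=table.animal_id, session_id=table.session_id)


@dataclass
class ShuffleCalibration:
    """Null calibration of the modulation call rate under label permutation."""

    counts: np.ndarray       # flagged ROIs per shuffle (summed over sessions)
    n_rois: int
    n_shuffles: int
    alpha_level: float

    @property
    def mean_count(self) -> float:
        return float(self.counts.mean())

    def to_dict(self) -> dict:
        return {
            "mean_count": self.mean_count,
            "counts": self.counts.tolist(),
            "n_rois": self.n_rois,
            "n_shuffles": self.n_shuffles,
            "alpha_level": self.alpha_level,
        }


def shuffle_control(tables: list[ResponseTable], alpha_level: float = ALPHA_LEVEL,
                    n_shuffles: int = 100, seed: int | None = 0) -> ShuffleCalibration:
    """Permute fine/coarse labels within each session's S+ alpha trials and re-test.

    Group sizes are preserved: each permutation reassigns which trials carry
    the "fine" label, keeping the original fine and coarse counts.  The same
    permutation applies to every ROI of a session (they share trials).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    pools = []
    for table in tables:
        fine_mask, coarse_mask = _alpha_pools(table)
        cols = np.flatnonzero(fine_mask | coarse_mask)
        pools.append((table.amplitudes[:, cols], int(fine_mask.sum())))

    counts = np.zeros(n_shuffles, dtype=int)
    for s in range(n_shuffles):
        flagged = 0
        for amps, n_fine in pools:
            perm = rng.permutation(amps.shape[1])
            fine = amps[:, perm[:n_fine]]
            coarse = amps[:, perm[n_fine:]]
            _, p = stats.ttest_ind(fine, coarse, axis=1, equal_var=True)
            flagged += int(np.count_nonzero(np.asarray(p, float) < alpha_level))
        counts[s] = flagged
    n_rois = sum(t.n_rois for t in tables)
    return ShuffleCalibration(counts=counts, n_rois=n_rois,
                              n_shuffles=n_shuffles, alpha_level=alpha_level)


# ---------------------------------------------------------------------------
# Sniff features and residualization
# ---------------------------------------------------------------------------

def detect_inhalation_onsets(sniff: np.ndarray, frame_rate: float,
                             inhalation_negative: bool = True) -> np.ndarray:
    """Inhalation onset times from the flow trace.

    Onsets are negative-going zero crossings of the mean-subtracted trace
    (flow-sensor polarity is rig-specific; set ``inhalation_negative=False``
    to use positive-going crossings).  Crossing times are refined to sub-frame
    precision by linear interpolation between the bracketing samples, so
    window counts do not inherit frame-grid quantization.  Returns times in
    seconds; an empty array for flat/degenerate traces.
    """
    x = np.asarray(sniff, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        return np.empty(0)
    x = x - x.mean()
    if not inhalation_negative:
        x = -x
    i = np.flatnonzero((x[:-1] >= 0) & (x[1:] < 0))
    frac = x[i] / (x[i] - x[i + 1])
    return (i + frac) / frame_rate


def extract_sniff_features(session: SessionData, window: float = 1.0,
                           inhalation_negative: bool = True) -> pd.DataFrame:
    """Per-trial respiration features over the odour window [onset, onset+window).

    Columns: ``rate`` (onsets per second), ``count``, ``latency`` (first
    inhalation after onset; NaN when no inhalation falls in the window).
    """
    onsets = detect_inhalation_onsets(session.sniff, session.frame_rate,
                                      inhalation_negative)
    rows = []
    for t in session.trials:
        if t.odour_onset + window > session.duration + 1e-9:
            raise ValueError(f"trial {t.trial_id}: sniff trace does not cover the odour window")
        in_win = onsets[(onsets >= t.odour_onset) & (onsets < t.odour_onset + window)]
        count = int(in_win.size)
        rows.append({
            "trial_id": t.trial_id,
            "rate": count / window,
            "latency": float(in_win[0] - t.odour_onset) if count else np.nan,
            "count": count,
        })
    return pd.DataFrame(rows)


def _design_matrix(features: pd.DataFrame, regressors: tuple[str, ...],
                   ) -> tuple[np.ndarray, list[str]]:
    """Intercept + regressors; NaNs mean-imputed; collinear columns dropped."""
    cols, names = [np.ones(len(features))], ["intercept"]
    for name in regressors:
        col = features[name].to_numpy(dtype=float)
        if np.isnan(col).all():
            warnings.warn(f"sniff regressor {name!r} is entirely absent; dropped",
                          stacklevel=3)
            continue
        if np.isnan(col).any():
            col = np.where(np.isnan(col), np.nanmean(col), col)
        cols.append(col)
        names.append(name)
    X = np.column_stack(cols)
    # Greedy rank check: drop later columns that add no rank (e.g. rate vs count
    # with a fixed window are exactly proportional).
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            warnings.warn(f"sniff regressor {names[j]!r} is collinear with earlier "
                          "regressors; dropped", stacklevel=3)
    return X[:, keep], [names[j] for j in keep]


def residualize_on_sniff(table: ResponseTable, features: pd.DataFrame,
                         regressors: tuple[str, ...] = ("rate", "latency", "count"),
                         ) -> ResponseTable:
    """Replace alpha-trial amplitudes with OLS residuals on sniff features.

    The fit pools all S+ alpha trials across tasks (one shared design matrix
    for every ROI of the session, since trials are shared).  Non-alpha trial
    columns are left untouched; the per-ROI trial count never changes.
    """
    fine_mask, coarse_mask = _alpha_pools(table)
    cols = np.flatnonzero(fine_mask | coarse_mask)
    feats = features.set_index("trial_id").loc[
        table.trials["trial_id"].iloc[cols].to_numpy()]
    X, kept = _design_matrix(feats.reset_index(), regressors)
    if len(cols) < X.shape[1] + 2:
        raise ValueError(
            f"need >= {X.shape[1] + 2} alpha trials to fit {X.shape[1]} regressors")
    Y = table.amplitudes[:, cols].T                  # [n_trials_alpha, n_rois]
    beta, *_ = linalg.lstsq(X, Y)
    resid = Y - X @ beta
    amps = table.amplitudes.copy()
    amps[:, cols] = resid.T
    return replace(table, amplitudes=amps, variant="sniff_residualized")


# ---------------------------------------------------------------------------
# Switch-aligned time-course
# ---------------------------------------------------------------------------

@dataclass
class SwitchingTimecourse:
    """Mean ± s.e.m. relative alpha response around the two task switches.

    Relative response = alpha-trial amplitude minus that ROI's Fine1 alpha
    mean, averaged across the given ROI set at each alpha-trial index relative
    to the switch (index 0 = first post-switch alpha trial).
    """

    curves: dict[str, pd.DataFrame]       # fine_to_coarse / coarse_to_fine
    first_coarse_change: float            # mean relative response, first coarse alpha trial
    first_coarse_t: float
    first_coarse_p: float
    recovery_index: int | None            # first Fine2 alpha index not differing from Fine1
    n_rois: int


def _alpha_columns(table: ResponseTable, epoch: str) -> np.ndarray:
    return np.flatnonzero(table.trial_mask(odour="alpha", epoch=epoch,
                                           rewarded=True, probe=False))


def switching_timecourse(tables: list[ResponseTable],
                         roi_sets: list[np.ndarray],
                         alpha_level: float = ALPHA_LEVEL) -> SwitchingTimecourse:
    """Switch-aligned relative response among a chosen (e.g. modulated) ROI set.

    ``roi_sets[k]`` gives the ROI indices of ``tables[k]`` to include.  Also
    reports the first-coarse-trial statistics (one-sample t of the per-ROI
    change vs 0) and the Fine2 recovery index (first alpha-trial index whose
    per-ROI amplitudes no longer differ from the Fine1 amplitudes by an
    unpaired two-sample t at ``alpha_level``).
    """
    if sum(len(r) for r in roi_sets) == 0:
        raise ValueError("the ROI set is empty")

    rel_fc: dict[int, list[float]] = {}   # fine_to_coarse alignment
    rel_cf: dict[int, list[float]] = {}   # coarse_to_fine alignment
    first_changes: list[float] = []
    fine2_by_index: dict[int, list[float]] = {}
    fine1_means: list[float] = []
    fine1_pooled: list[float] = []

    for table, rois in zip(tables, roi_sets):
        rois = np.asarray(rois, dtype=int)
        if rois.size == 0:
            continue
        c_f1 = _alpha_columns(table, "Fine1")
        c_co = _alpha_columns(table, "Coarse")
        c_f2 = _alpha_columns(table, "Fine2")
        if c_f1.size == 0:
            raise ValueError("no Fine1 alpha trials to reference against")
        ref = table.amplitudes[np.ix_(rois, c_f1)].mean(axis=1)   # per-ROI Fine1 mean
        fine1_means.extend(ref.tolist())
        fine1_pooled.extend(table.amplitudes[np.ix_(rois, c_f1)].reshape(-1).tolist())

        rel = table.amplitudes[np.ix_(rois, np.concatenate([c_f1, c_co, c_f2]))] - ref[:, None]
        n1, nc = c_f1.size, c_co.size
        for j in range(c_f1.size):            # pre-switch Fine1 trials: −n1 .. −1
            rel_fc.setdefault(j - n1, []).extend(rel[:, j].tolist())
        for j in range(nc):                   # Coarse trials: 0, 1, ...
            rel_fc.setdefault(j, []).extend(rel[:, n1 + j].tolist())
            rel_cf.setdefault(j - nc, []).extend(rel[:, n1 + j].tolist())
        for j in range(c_f2.size):            # Fine2 trials: 0, 1, ...
            rel_cf.setdefault(j, []).extend(rel[:, n1 + nc + j].tolist())
            fine2_by_index.setdefault(j, []).extend(
                table.amplitudes[np.ix_(rois, c_f2[[j]])].reshape(-1).tolist())
        if nc > 0:
            first_changes.extend(rel[:, n1].tolist())

    curves = {}
    for kind, pooled in (("fine_to_coarse", rel_fc), ("coarse_to_fine", rel_cf)):
        idx = sorted(pooled)
        curves[kind] = pd.DataFrame({
            "mean": [float(np.mean(pooled[i])) for i in idx],
            "sem": [float(np.std(pooled[i], ddof=1) / np.sqrt(len(pooled[i])))
                    if len(pooled[i]) > 1 else np.nan for i in idx],
            "n": [len(pooled[i]) for i in idx],
        }, index=pd.Index(idx, name="alpha_trial_from_switch"))

    fc = np.asarray(first_changes)
    t1, p1 = stats.ttest_1samp(fc, 0.0) if fc.size > 1 else (np.nan, np.nan)

    recovery = None
    f1 = np.asarray(fine1_pooled)
    for j in sorted(fine2_by_index):
        f2 = np.asarray(fine2_by_index[j])
        if f2.size < 2:
            continue
        _, p = stats.ttest_ind(f2, f1, equal_var=True)
        if p > alpha_level:
            recovery = j
            break

    return SwitchingTimecourse(
        curves=curves,
        first_coarse_change=float(fc.mean()) if fc.size else np.nan,
        first_coarse_t=float(t1), first_coarse_p=float(p1),
        recovery_index=recovery,
        n_rois=int(sum(len(r) for r in roi_sets)))
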