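"""Per-trial odour-response amplitudes, significance flags and stimulus selectivity.

The response currency is ΔF/F = (F − F0)/F0 with a per-trial F0 (mean raw F
over the 2 s immediately preceding odour onset).  The response amplitude is
the arithmetic mean of ΔF/F over the half-open 1-s odour window — 30 frames at
30 Hz.  A response is *significant* when its magnitude exceeds 3x the standard
deviation of the same window-mean statistic measured in the pre-odour baseline,
so the noise statistic is averaged exactly like the signal statistic.

Selectivity compares each ROI's alpha vs alphaprime amplitudes during fine
discrimination with a pooled-variance two-sample t-test; the selectivity index
is |t| and t > 0 means alpha-preferring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .session_io import SessionData

__all__ = [
    "BaselineStats",
    "ResponseTable",
    "SelectivityResult",
    "frame_window",
    "compute_dff",
    "response_amplitude",
    "detect_significant_response",
    "compute_responses",
    "selectivity_tscore",
]

BASELINE_WINDOW = 2.0   # seconds of pre-odour raw F averaged into F0
ODOUR_WINDOW = 1.0      # seconds of ΔF/F averaged into the response amplitude


def frame_window(t0: float, t1: float, frame_rate: float) -> slice:
    """Frame indices whose sample times fall in the half-open interval [t0, t1)."""
    eps = 1e-9
    return slice(int(np.ceil(t0 * frame_rate - eps)), int(np.ceil(t1 * frame_rate - eps)))


@dataclass
class BaselineStats:
    """Per-trial baseline mean F0 and the per-ROI null sd of the amplitude statistic.

    ``sd`` is the standard deviation, across trials, of a pseudo-amplitude
    computed in the quiescent pre-odour period with the same 1-s-window /
    2-s-F0 geometry as the real response amplitude.  It is therefore the
    correct null scale for the 3-sd significance rule.
    """

    f0: np.ndarray   # [n_rois, n_trials]
    sd: np.ndarray   # [n_rois]


@dataclass
class ResponseTable:
    """Per-(ROI, trial) odour-response amplitudes with trial metadata."""

    amplitudes: np.ndarray        # [n_rois, n_trials], ΔF/F
    trials: pd.DataFrame          # one row per retained trial
    significant: np.ndarray | None = None   # [n_rois, n_trials] bool
    baseline: BaselineStats | None = None
    animal_id: str = "animal0"
    session_id: str = "session0"
    variant: str = "raw"

    @property
    def n_rois(self) -> int:
        return int(self.amplitudes.shape[0])

    @property
    def n_trials(self) -> int:
        return int(self.amplitudes.shape[1])

    def trial_mask(self, odour: str | None = None, task: str | None = None,
                   epoch: str | None = None, rewarded: bool | None = None,
                   probe: bool | None = None) -> np.ndarray:
        """Boolean mask over trial columns matching all given criteria."""
        m = np.ones(self.n_trials, dtype=bool)
        if odour is not None:
            m &= (self.trials["odour"] == odour).to_numpy()
        if task is not None:
            m &= (self.trials["task"] == task).to_numpy()
        if epoch is not None:
            m &= (self.trials["epoch"] == epoch).to_numpy()
        if rewarded is not None:
            m &= (self.trials["rewarded"] == rewarded).to_numpy()
        if probe is not None:
            m &= (self.trials["probe"] == probe).to_numpy()
        return m

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: one row per (ROI, trial)."""
        n_r, n_t = self.amplitudes.shape
        base = self.trials.loc[self.trials.index.repeat(n_r)].reset_index(drop=True)
        out = base.assign(
            roi=np.tile(np.arange(n_r), n_t),
            amplitude=self.amplitudes.T.reshape(-1),
            animal_id=self.animal_id,
            session_id=self.session_id,
            variant=self.variant,
        )
        if self.significant is not None:
            out["significant"] = self.significant.T.reshape(-1)
        return out


def compute_dff(session: SessionData, baseline_window: float = BASELINE_WINDOW,
                per_session_baseline: bool = False,
                ) -> tuple[np.ndarray, BaselineStats]:
    """ΔF/F matrix for the whole session plus baseline statistics.

    With the default per-trial baseline, each trial's F0 is the mean raw F over
    ``baseline_window`` seconds before its odour onset, and that F0 normalizes
    all frames from that baseline's start up to the next trial's baseline
    start.  ``per_session_baseline`` instead uses one F0 per ROI (mean over all
    per-trial baseline windows).
    """
    fr = session.frame_rate
    traces = np.asarray(session.traces, dtype=np.float64)
    n_rois, n_frames = traces.shape
    if not session.trials:
        raise ValueError("cannot compute ΔF/F for a session with no trials")

    onsets = np.array([t.odour_onset for t in session.trials])
    if onsets.min() < baseline_window:
        raise ValueError(
            f"baseline window of {baseline_window} s does not fit before the first onset")

    n_trials = len(onsets)
    f0 = np.empty((n_rois, n_trials))
    for i, onset in enumerate(onsets):
        win = frame_window(onset - baseline_window, onset, fr)
        f0[:, i] = traces[:, win].mean(axis=1)
    bad = np.argwhere(f0 <= 0)
    if bad.size:
        r, i = bad[0]
        raise ValueError(f"non-positive baseline F0 for ROI {r}, trial {i}")

    if per_session_baseline:
        f0 = np.repeat(f0.mean(axis=1, keepdims=True), n_trials, axis=1)

    dff = np.empty_like(traces)
    starts = [frame_window(o - baseline_window, o, fr).start for o in onsets]
    bounds = starts[1:] + [n_frames]
    dff[:, :starts[0]] = traces[:, :starts[0]] / f0[:, [0]] - 1.0
    for i, (s, e) in enumerate(zip(starts, bounds)):
        dff[:, s:e] = traces[:, s:e] / f0[:, [i]] - 1.0

    sd = _baseline_amplitude_sd(traces, onsets, fr)
    return dff, BaselineStats(f0=f0, sd=sd)


def _baseline_amplitude_sd(traces: np.ndarray, onsets: np.ndarray,
                           frame_rate: float) -> np.ndarray:
    """Null sd of the window-mean amplitude, from pre-odour pseudo-amplitudes.

    For each trial, a pseudo-response is measured over [onset−1, onset) against
    a pseudo-F0 over [onset−3, onset−1); the per-ROI sd across trials estimates
    the amplitude statistic's null scale.  Requires 3 s of quiet pre-trial time
    (guaranteed by the >= 5 s session pre-roll and the 20-s ITI).
    """
    if onsets.min() < 3.0:
        raise ValueError("need >= 3 s before each onset to estimate baseline fluctuations")
    vals = np.empty((traces.shape[0], len(onsets)))
    for i, onset in enumerate(onsets):
        f0 = traces[:, frame_window(onset - 3.0, onset - 1.0, frame_rate)].mean(axis=1)
        w = traces[:, frame_window(onset - 1.0, onset, frame_rate)].mean(axis=1)
        vals[:, i] = w / f0 - 1.0
    if vals.shape[1] < 2:
        # a single trial cannot constrain the fluctuation scale; flagging
        # significance later will reject the NaN explicitly
        return np.full(traces.shape[0], np.nan)
    return vals.std(axis=1, ddof=1)


def response_amplitude(session: SessionData, dff: np.ndarray,
                       baseline: BaselineStats | None = None,
                       window: float = ODOUR_WINDOW) -> ResponseTable:
    """Mean ΔF/F over the half-open 1-s odour window for every (ROI, trial).

    Trials whose window would be truncated by the session end are dropped with
    a warning rather than imputed.
    """
    fr = session.frame_rate
    keep, amps = [], []
    for i, trial in enumerate(session.trials):
        win = frame_window(trial.odour_onset, trial.odour_onset + window, fr)
        if win.stop > session.n_frames:
            warnings.warn(
                f"trial {trial.trial_id}: odour window truncated by session end; dropped",
                stacklevel=2)
            continue
        keep.append(i)
        amps.append(dff[:, win].mean(axis=1))
    if not amps:
        raise ValueError("no trial has a complete odour window")
    trials_df = session.trials_frame().iloc[keep].reset_index(drop=True)
    base = None
    if baseline is not None:
        base = BaselineStats(f0=baseline.f0[:, keep], sd=baseline.sd)
    return ResponseTable(
        amplitudes=np.column_stack(amps), trials=trials_df, baseline=base,
        animal_id=session.animal_id, session_id=session.session_id)


def detect_significant_response(table: ResponseTable,
                                baseline: BaselineStats | None = None,
                                n_sd: float = 3.0) -> ResponseTable:
    """Flag |amplitude| strictly greater than ``n_sd`` x the baseline null sd."""
    baseline = baseline or table.baseline
    if baseline is None:
        raise ValueError("baseline statistics required to flag significant responses")
    if baseline.sd.shape[0] != table.n_rois:
        raise ValueError("baseline sd has wrong number of ROIs")
    if np.isnan(baseline.sd).any():
        raise ValueError("baseline fluctuation sd undefined (too few trials)")
    sig = np.abs(table.amplitudes) > n_sd * baseline.sd[:, None]
    return replace(table, significant=sig, baseline=baseline)


def compute_responses(session: SessionData, baseline_window: float = BASELINE_WINDOW,
                      per_session_baseline: bool = False,
                      window: float = ODOUR_WINDOW) -> ResponseTable:
    """Convenience chain: ΔF/F -> amplitudes -> significance flags."""
    dff, baseline = compute_dff(session, baseline_window, per_session_baseline)
    table = response_amplitude(session, dff, baseline, window)
    return detect_significant_response(table)


# ---------------------------------------------------------------------------
# Selectivity
# ---------------------------------------------------------------------------

@dataclass
class SelectivityResult:
    """Per-ROI alpha-vs-alphaprime selectivity from fine-discrimination trials."""

    t: np.ndarray            # two-sample t, alpha minus alphaprime
    p: np.ndarray
    s: np.ndarray            # selectivity index = |t|
    preferred: np.ndarray    # "alpha" where t > 0 else "alphaprime"
    n_alpha: int
    n_alphaprime: int
    animal_id: str = "animal0"
    session_id: str = "session0"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "roi": np.arange(len(self.t)),
            "t": self.t, "p": self.p, "selectivity_index": self.s,
            "preferred": self.preferred,
            "animal_id": self.animal_id, "session_id": self.session_id,
        })


def selectivity_tscore(table: ResponseTable) -> SelectivityResult:
    """Pooled-variance two-sample t on fine-epoch alpha vs alphaprime amplitudes.

    Call on a table built from an epoch-equalized session so Fine1 and Fine2
    contribute equally.  t > 0 means the ROI responds more to alpha.
    """
    a = table.amplitudes[:, table.trial_mask(odour="alpha", task="fine")]
    b = table.amplitudes[:, table.trial_mask(odour="alphaprime", task="fine")]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError(
            f"need >= 2 fine-epoch trials per odour (got {a.shape[1]} alpha, "
            f"{b.shape[1]} alphaprime)")
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    t = np.asarray(t, dtype=float)
    return SelectivityResult(
        t=t, p=np.asarray(p, dtype=float), s=np.abs(t),
        preferred=np.where(t > 0, "alpha", "alphaprime").astype(object),
        n_alpha=a.shape[1], n_alphaprime=b.shape[1],
        animal_id=table.animal_id, session_id=table.session_id)
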