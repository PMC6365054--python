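"""Session data model, on-disk format, behavioural scoring and epoch equalization.

A *session* is one head-fixed go/no-go run: a trial table (three task epochs,
Fine1 -> Coarse -> Fine2), an ROI x frame fluorescence matrix at ~30 Hz, and a
respiration (sniff) trace sampled on the same frame clock.

On disk a session is a directory::

    session_dir/
        trials.csv   one row per trial; lick times semicolon-joined seconds
        traces.h5    datasets "traces" [n_rois x n_frames] and "sniff" [n_frames]
        meta.yaml    frame_rate, animal_id, session_id

The round trip is lossless: traces bit-exact (HDF5 float64, no timestamps),
trial fields exact (Python float repr round-trips).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

EPOCHS = ("Fine1", "Coarse", "Fine2")
ODOURS = ("alpha", "alphaprime", "beta")
TASK_OF_EPOCH = {"Fine1": "fine", "Coarse": "coarse", "Fine2": "fine"}


class SessionValidationError(ValueError):
    """A session violated the data-model contract; the message names the field."""


@dataclass(frozen=True)
class TrialRecord:
    """One behavioural trial.

    ``odour_onset`` is the valve-opening time in seconds from session start;
    all response windows are measured from it.  ``probe`` marks the rare
    rewarded alphaprime presentations inserted during the Coarse epoch.
    """

    trial_id: int
    epoch: str
    odour: str
    rewarded: bool
    probe: bool
    odour_onset: float
    lick_times: tuple[float, ...] = ()
    outcome: str | None = None

    @property
    def task(self) -> str:
        return TASK_OF_EPOCH[self.epoch]


@dataclass
class SessionData:
    """Trial table + traces + sniff trace + acquisition metadata for one session."""

    trials: list[TrialRecord]
    traces: np.ndarray          # [n_rois, n_frames], raw fluorescence (a.u.)
    sniff: np.ndarray           # [n_frames], nasal flow (a.u.)
    frame_rate: float           # Hz
    animal_id: str = "animal0"
    session_id: str = "session0"

    @property
    def n_rois(self) -> int:
        return int(self.traces.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.traces.shape[1])

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def trials_frame(self) -> pd.DataFrame:
        """Trial metadata as a tidy DataFrame (one row per trial)."""
        return pd.DataFrame(
            {
                "trial_id": [t.trial_id for t in self.trials],
                "epoch": [t.epoch for t in self.trials],
                "task": [t.task for t in self.trials],
                "odour": [t.odour for t in self.trials],
                "rewarded": [t.rewarded for t in self.trials],
                "probe": [t.probe for t in self.trials],
                "odour_onset": [t.odour_onset for t in self.trials],
            }
        )


def validate_session(session: SessionData) -> None:
    """Raise :class:`SessionValidationError` naming the first offending field."""
    if session.frame_rate <= 0:
        raise SessionValidationError(f"frame_rate must be > 0, got {session.frame_rate}")
    if session.traces.ndim != 2:
        raise SessionValidationError("traces must be a 2-D [n_rois, n_frames] matrix")
    if session.n_rois < 1:
        raise SessionValidationError("traces: need n_rois >= 1")
    if session.sniff.shape != (session.n_frames,):
        raise SessionValidationError(
            f"sniff: length {session.sniff.shape} does not match n_frames {session.n_frames}"
        )
    last_onset = -np.inf
    for t in session.trials:
        if t.epoch not in EPOCHS:
            raise SessionValidationError(f"trial {t.trial_id}: epoch {t.epoch!r} not in {EPOCHS}")
        if t.odour not in ODOURS:
            raise SessionValidationError(f"trial {t.trial_id}: odour {t.odour!r} not in {ODOURS}")
        if t.probe and not (t.epoch == "Coarse" and t.odour == "alphaprime" and t.rewarded):
            raise SessionValidationError(
                f"trial {t.trial_id}: probe trials must be rewarded alphaprime in the Coarse epoch"
            )
        if t.odour_onset <= last_onset:
            raise SessionValidationError(
                f"trial {t.trial_id}: odour_onset not strictly increasing"
            )
        last_onset = t.odour_onset
        frame = int(np.floor(t.odour_onset * session.frame_rate))
        if not (0 <= frame < session.n_frames):
            raise SessionValidationError(
                f"trial {t.trial_id}: odour_onset {t.odour_onset} s maps outside the trace"
            )


# ---------------------------------------------------------------------------
# On-disk format
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = [
    "trial_id", "epoch", "odour", "rewarded", "probe", "odour_onset", "lick_times", "outcome",
]


def write_session(session: SessionData, path: str | Path) -> None:
    """Write a session directory (trials.csv, traces.h5, meta.yaml).

    Output is deterministic: identical sessions serialize to byte-identical
    files (HDF5 object timestamps are disabled).
    """
    validate_session(session)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for t in session.trials:
        rows.append(
            {
                "trial_id": t.trial_id,
                "epoch": t.epoch,
                "odour": t.odour,
                "rewarded": t.rewarded,
                "probe": t.probe,
                "odour_onset": repr(float(t.odour_onset)),
                "lick_times": ";".join(repr(float(x)) for x in t.lick_times),
                "outcome": t.outcome if t.outcome is not None else "",
            }
        )
    pd.DataFrame(rows, columns=_TRIAL_COLUMNS).to_csv(path / "trials.csv", index=False)

    with h5py.File(path / "traces.h5", "w") as f:
        f.create_dataset("traces", data=np.asarray(session.traces, dtype=np.float64),
                         track_times=False)
        f.create_dataset("sniff", data=np.asarray(session.sniff, dtype=np.float64),
                         track_times=False)

    meta = {
        "frame_rate": float(session.frame_rate),
        "animal_id": str(session.animal_id),
        "session_id": str(session.session_id),
    }
    (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_session(path: str | Path) -> SessionData:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    for name in ("trials.csv", "traces.h5", "meta.yaml"):
        if not (path / name).exists():
            raise SessionValidationError(f"missing session file: {path / name}")

    meta = yaml.safe_load((path / "meta.yaml").read_text())
    df = pd.read_csv(path / "trials.csv", dtype={"lick_times": str, "outcome": str},
                     keep_default_na=False)
    trials = []
    for _, row in df.iterrows():
        licks = tuple(float(x) for x in str(row["lick_times"]).split(";") if x)
        outcome = row["outcome"] or None
        trials.append(
            TrialRecord(
                trial_id=int(row["trial_id"]),
                epoch=str(row["epoch"]),
                odour=str(row["odour"]),
                rewarded=_parse_bool(row["rewarded"], "rewarded"),
                probe=_parse_bool(row["probe"], "probe"),
                odour_onset=float(row["odour_onset"]),
                lick_times=licks,
                outcome=outcome,
            )
        )
    with h5py.File(path / "traces.h5", "r") as f:
        traces = f["traces"][()]
        sniff = f["sniff"][()]
    session = SessionData(
        trials=trials,
        traces=traces,
        sniff=sniff,
        frame_rate=float(meta["frame_rate"]),
        animal_id=str(meta["animal_id"]),
        session_id=str(meta["session_id"]),
    )
    validate_session(session)
    return session


def _parse_bool(value, name: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise SessionValidationError(f"{name}: cannot parse boolean from {value!r}")


# ---------------------------------------------------------------------------
# Behaviour
# ---------------------------------------------------------------------------

RESPONSE_WINDOW = (1.0, 2.5)  # seconds after odour onset, half-open


@dataclass
class BehaviourReport:
    """Session-level behavioural score.

    ``percent_correct`` follows the standard go/no-go convention: an S+ trial
    is correct iff at least one lick falls in the response window, an S− trial
    iff none does.  ``curves`` (switch-aligned accuracy) is populated by
    :func:`switching_curve`.
    """

    percent_correct: float
    outcomes: np.ndarray                      # bool per trial
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)


def score_trial(trial: TrialRecord, window: tuple[float, float] = RESPONSE_WINDOW) -> bool:
    lo, hi = trial.odour_onset + window[0], trial.odour_onset + window[1]
    licked = any(lo <= lt < hi for lt in trial.lick_times)
    return licked if trial.rewarded else not licked


def score_behaviour(session: SessionData,
                    window: tuple[float, float] = RESPONSE_WINDOW) -> BehaviourReport:
    """Score every trial from its lick times; licks in [onset+1.0, onset+2.5) s count."""
    if not session.trials:
        raise SessionValidationError("trials: cannot score a session with no trials")
    outcomes = np.array([score_trial(t, window) for t in session.trials], dtype=bool)
    return BehaviourReport(percent_correct=100.0 * outcomes.mean(), outcomes=outcomes)


def _switch_indices(session: SessionData) -> dict[str, int]:
    """Positions (list indices) of the first Coarse trial and the first Fine2 trial."""
    out: dict[str, int] = {}
    for i, t in enumerate(session.trials):
        if t.epoch == "Coarse" and "fine_to_coarse" not in out:
            out["fine_to_coarse"] = i
        if t.epoch == "Fine2" and "coarse_to_fine" not in out:
            out["coarse_to_fine"] = i
    return out


def switching_curve(sessions: list[SessionData],
                    window: tuple[float, float] = RESPONSE_WINDOW) -> dict[str, pd.DataFrame]:
    """Trial-by-trial accuracy aligned to the two task switches, pooled over sessions.

    Returns one DataFrame per alignment (``fine_to_coarse``, ``coarse_to_fine``)
    indexed by trial index relative to the switch (0 = first post-switch trial)
    with columns ``mean``, ``sem``, ``n``.  s.e.m. is sample sd / sqrt(n).
    """
    if not sessions:
        raise SessionValidationError("sessions: need at least one session")
    pooled: dict[str, dict[int, list[float]]] = {"fine_to_coarse": {}, "coarse_to_fine": {}}
    any_switch = False
    for session in sessions:
        outcomes = score_behaviour(session, window).outcomes
        switches = _switch_indices(session)
        for kind, pos in switches.items():
            any_switch = True
            for i, ok in enumerate(outcomes):
                pooled[kind].setdefault(i - pos, []).append(float(ok))
    if not any_switch:
        raise SessionValidationError("trials: no task switch found in any session")

    curves = {}
    for kind, by_index in pooled.items():
        idx = sorted(by_index)
        mean = [float(np.mean(by_index[i])) for i in idx]
        n = [len(by_index[i]) for i in idx]
        sem = [float(np.std(by_index[i], ddof=1) / np.sqrt(len(by_index[i])))
               if len(by_index[i]) > 1 else np.nan for i in idx]
        curves[kind] = pd.DataFrame({"mean": mean, "sem": sem, "n": n},
                                    index=pd.Index(idx, name="trial_from_switch"))
    return curves


# ---------------------------------------------------------------------------
# Epoch equalization
# ---------------------------------------------------------------------------

def equalize_fine_epochs(session: SessionData) -> SessionData:
    """Truncate Fine2 from its end so both fine epochs contribute equal trial counts.

    Controls for slow within-session drift (e.g. bleaching) by analysing the
    same number of trials from each fine epoch.  Fine1 and Coarse are untouched;
    retained :class:`TrialRecord` objects are unmodified.  If Fine2 is already
    shorter than Fine1 both are kept whole (with a warning).  Returns a new
    :class:`SessionData` sharing the trace arrays (a view, not a copy).
    """
    n1 = sum(1 for t in session.trials if t.epoch == "Fine1")
    n2 = sum(1 for t in session.trials if t.epoch == "Fine2")
    if n1 == 0 or n2 == 0:
        raise SessionValidationError("epoch: both fine epochs must be present to equalize")
    if n2 < n1:
        warnings.warn(
            f"session {session.session_id}: Fine2 ({n2}) shorter than Fine1 ({n1}); "
            "keeping both whole", stacklevel=2)
        return replace(session, trials=list(session.trials))
    kept, seen_fine2 = [], 0
    for t in session.trials:
        if t.epoch == "Fine2":
            seen_fine2 += 1
            if seen_fine2 > n1:
                continue
        kept.append(t)
    return replace(session, trials=kept)
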