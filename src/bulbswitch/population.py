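"""Population-level analyses: trajectories, correlation, ROI removal, decoding.

ROIs recorded in different animals/sessions are stacked into a
pseudo-population: per ROI, the trial-averaged ΔF/F transient for each
(odour, task) condition over a peri-odour window, concatenated across
conditions.  Principal components are computed treating each timepoint as an
observation in ROI space, and each condition's column block is projected onto
the first three components to give its trajectory.

The decorrelation statistic: per animal, the vectors of per-ROI mean alpha and
alphaprime amplitudes are correlated (Pearson); removing a chosen ROI subset
and recomputing gives change = (r_removed − r_full)/r_full, compared against
size-matched random removals.  Decoding is a per-session linear discriminant
(shared covariance, analytic shrinkage) on per-trial population amplitude
vectors with stratified 2/3 train / 1/3 test splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedShuffleSplit

from .modulation import ModulationResult
from .responses import ResponseTable, SelectivityResult, compute_dff, frame_window
from .session_io import SessionData

__all__ = [
    "PseudoPopulation",
    "TrajectorySet",
    "CorrelationChange",
    "DecoderReport",
    "EnrichmentResult",
    "build_pseudopopulation",
    "pca_trajectories",
    "trajectory_separation",
    "response_correlation",
    "removal_correlation_change",
    "train_eval_decoder",
    "selectivity_enrichment",
]

DEFAULT_CONDITIONS = ("alpha:fine1", "alpha:fine2", "alphaprime:fine", "alpha:coarse")


def _condition_mask(trials: pd.DataFrame, condition: str) -> np.ndarray:
    """Parse "odour:scope" where scope is fine, fine1, fine2 or coarse."""
    odour, scope = condition.split(":")
    m = (trials["odour"] == odour).to_numpy() & (~trials["probe"]).to_numpy()
    if scope == "fine":
        m &= (trials["task"] == "fine").to_numpy()
    elif scope == "fine1":
        m &= (trials["epoch"] == "Fine1").to_numpy()
    elif scope == "fine2":
        m &= (trials["epoch"] == "Fine2").to_numpy()
    elif scope == "coarse":
        m &= (trials["task"] == "coarse").to_numpy()
    else:
        raise ValueError(f"unknown condition scope {scope!r} in {condition!r}")
    return m


@dataclass
class PseudoPopulation:
    """Condition-averaged transients, ROIs x (conditions x timepoints)."""

    matrix: np.ndarray                 # [n_rois_total, n_conditions * n_timepoints]
    conditions: tuple[str, ...]
    n_timepoints: int
    times: np.ndarray                  # seconds relative to odour onset
    provenance: pd.DataFrame           # animal_id, session_id, roi per row

    def block(self, condition: str) -> np.ndarray:
        j = self.conditions.index(condition)
        return self.matrix[:, j * self.n_timepoints:(j + 1) * self.n_timepoints]


def build_pseudopopulation(sessions: list[SessionData],
                           conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
                           window: tuple[float, float] = (-1.0, 3.0),
                           ) -> PseudoPopulation:
    """Average each ROI's ΔF/F transient per condition and concatenate blocks.

    ``window`` is seconds relative to odour onset (half-open).  Sessions (and
    all their ROIs) lacking a trial for some requested condition are excluded
    with a warning so column blocks stay aligned across ROIs.
    """
    fr = sessions[0].frame_rate
    n_tp = frame_window(window[0] + 10.0, window[1] + 10.0, fr)  # length only
    n_timepoints = n_tp.stop - n_tp.start
    times = window[0] + np.arange(n_timepoints) / fr

    rows, prov = [], []
    for session in sessions:
        if session.frame_rate != fr:
            raise ValueError("all sessions must share one frame rate")
        trials = session.trials_frame()
        masks = {c: _condition_mask(trials, c) for c in conditions}
        missing = [c for c, m in masks.items() if not m.any()]
        if missing:
            warnings.warn(
                f"session {session.session_id}: no trials for {missing}; "
                "its ROIs are excluded from the pseudo-population", stacklevel=2)
            continue
        dff, _ = compute_dff(session)
        blocks = []
        for c in conditions:
            cols = np.flatnonzero(masks[c])
            seg = np.zeros((session.n_rois, n_timepoints))
            for col in cols:
                onset = trials["odour_onset"].iloc[col]
                start = frame_window(onset + window[0], onset + window[1], fr).start
                seg += dff[:, start:start + n_timepoints]
            blocks.append(seg / len(cols))
        rows.append(np.concatenate(blocks, axis=1))
        prov.append(pd.DataFrame({
            "animal_id": session.animal_id, "session_id": session.session_id,
            "roi": np.arange(session.n_rois)}))
    if not rows:
        raise ValueError("no session provides every requested condition")
    return PseudoPopulation(
        matrix=np.concatenate(rows, axis=0), conditions=tuple(conditions),
        n_timepoints=n_timepoints, times=times,
        provenance=pd.concat(prov, ignore_index=True))


@dataclass
class TrajectorySet:
    """Per-condition trajectories in the first principal components."""

    coords: dict[str, np.ndarray]          # condition -> [n_timepoints, n_components]
    explained_variance_ratio: np.ndarray   # non-increasing, in [0, 1]
    times: np.ndarray
    components: np.ndarray                 # [n_components, n_rois] loadings

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for cond, xyz in self.coords.items():
            cols = {f"pc{k + 1}": xyz[:, k] for k in range(xyz.shape[1])}
            frames.append(pd.DataFrame({"condition": cond, "time": self.times, **cols}))
        return pd.concat(frames, ignore_index=True)


def pca_trajectories(pop: PseudoPopulation, n_components: int = 3) -> TrajectorySet:
    """Project condition blocks onto the leading principal components.

    Observations are the concatenated time-condition columns; variables are
    ROIs.  Each ROI is centred on its mean over all columns; no variance
    scaling (ΔF/F units are kept).  Component signs are fixed by making each
    component's largest-magnitude ROI loading positive.
    """
    n_rois = pop.matrix.shape[0]
    if n_rois < n_components:
        warnings.warn(f"only {n_rois} ROIs; returning {n_rois} components", stacklevel=2)
        n_components = n_rois
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(pop.matrix.T)        # [n_columns, n_components]
    components = pca.components_                    # [n_components, n_rois]
    for k in range(n_components):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] *= -1.0
            scores[:, k] *= -1.0
    coords = {}
    for i, cond in enumerate(pop.conditions):
        sl = slice(i * pop.n_timepoints, (i + 1) * pop.n_timepoints)
        coords[cond] = scores[sl]
    return TrajectorySet(coords=coords,
                         explained_variance_ratio=pca.explained_variance_ratio_,
                         times=pop.times, components=components)


def trajectory_separation(trajectories: TrajectorySet, cond_a: str, cond_b: str,
                          time_range: tuple[float, float] | None = None) -> float:
    """Mean Euclidean distance between two condition trajectories.

    ``time_range`` restricts the comparison (e.g. to the odour window) —
    outside stimulation both trajectories sit at the noise floor and their
    distance carries no signal.
    """
    a, b = trajectories.coords[cond_a], trajectories.coords[cond_b]
    d = np.linalg.norm(a - b, axis=1)
    if time_range is not None:
        m = (trajectories.times >= time_range[0]) & (trajectories.times < time_range[1])
        d = d[m]
    return float(d.mean())


# ---------------------------------------------------------------------------
# Correlation and ROI removal
# ---------------------------------------------------------------------------

def _mean_response_vectors(tables: list[ResponseTable], groupby: str = "animal",
                           ) -> dict[str, tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]]:
    """Per group: (mean alpha vector, mean alphaprime vector, roi provenance).

    Means are over fine-discrimination trials (where both odours occur and the
    task-modulation of interest is expressed); probes are excluded by task.
    """
    groups: dict[str, dict] = {}
    for table in tables:
        key = table.animal_id if groupby == "animal" else table.session_id
        a = table.amplitudes[:, table.trial_mask(odour="alpha", task="fine")].mean(axis=1)
        b = table.amplitudes[:, table.trial_mask(odour="alphaprime", task="fine")].mean(axis=1)
        g = groups.setdefault(key, {"a": [], "b": [], "prov": []})
        g["a"].append(a)
        g["b"].append(b)
        g["prov"].extend((table.session_id, r) for r in range(table.n_rois))
    return {k: (np.concatenate(v["a"]), np.concatenate(v["b"]), v["prov"])
            for k, v in groups.items()}


def response_correlation(tables: list[ResponseTable], groupby: str = "animal",
                         ) -> pd.DataFrame:
    """Pearson r between per-ROI mean alpha and alphaprime response vectors.

    One row per group (animal by default, imaging location/session via
    ``groupby="session"``).  Groups with < 3 ROIs or a zero-variance vector
    get r = NaN and a warning.
    """
    rows = []
    for key, (a, b, _) in _mean_response_vectors(tables, groupby).items():
        if a.size < 3:
            warnings.warn(f"group {key}: fewer than 3 ROIs; r undefined", stacklevel=2)
            r = np.nan
        elif np.std(a) == 0 or np.std(b) == 0:
            warnings.warn(f"group {key}: zero-variance response vector; r undefined",
                          stacklevel=2)
            r = np.nan
        else:
            r = float(stats.pearsonr(a, b).statistic)
        rows.append({"group": key, "r": r, "n_rois": int(a.size)})
    return pd.DataFrame(rows)


@dataclass
class CorrelationChange:
    """Fractional change in alpha/alphaprime correlation after ROI removal (%)."""

    per_group: pd.DataFrame            # group, r_full, r_removed, change_pct, n_removed
    random_changes: np.ndarray         # [n_replicates, n_groups], %
    removal_kind: str = "modulated"

    @property
    def mean_change(self) -> float:
        return float(self.per_group["change_pct"].mean())

    @property
    def mean_random_change(self) -> float:
        return float(self.random_changes.mean(axis=1).mean())


def removal_correlation_change(tables: list[ResponseTable],
                               removal_masks: list[np.ndarray],
                               groupby: str = "animal",
                               n_random_replicates: int = 100,
                               seed: int | None = 0,
                               removal_kind: str = "modulated") -> CorrelationChange:
    """Correlation change from removing a chosen ROI set vs size-matched random sets.

    ``removal_masks[k]`` is a boolean mask over the ROIs of ``tables[k]``.
    change = (r_removed − r_full)/r_full, reported in percent; an empty
    removal set gives exactly 0.  Random controls redraw a subset of the same
    size within each group.
    """
    rng = np.random.default_rng(seed)
    vectors = _mean_response_vectors(tables, groupby)
    rem_by_group: dict[str, list[np.ndarray]] = {}
    for table, mask in zip(tables, removal_masks):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[0] != table.n_rois:
            raise ValueError("removal mask length must equal the table's ROI count")
        key = table.animal_id if groupby == "animal" else table.session_id
        rem_by_group.setdefault(key, []).append(mask)

    def r_of(a: np.ndarray, b: np.ndarray) -> float:
        return float(stats.pearsonr(a, b).statistic)

    rows, rand_cols = [], []
    for key, (a, b, _) in vectors.items():
        mask = np.concatenate(rem_by_group[key])
        n_rem = int(mask.sum())
        if n_rem >= a.size:
            raise ValueError(f"group {key}: removal set must be strictly smaller than the group")
        r_full = r_of(a, b)
        if n_rem == 0:
            change = 0.0
            r_removed = r_full
        else:
            r_removed = r_of(a[~mask], b[~mask])
            change = 100.0 * (r_removed - r_full) / r_full
        rows.append({"group": key, "r_full": r_full, "r_removed": r_removed,
                     "change_pct": change, "n_removed": n_rem, "n_rois": int(a.size)})
        reps = np.zeros(n_random_replicates)
        if n_rem > 0:
            for rep in range(n_random_replicates):
                sub = rng.choice(a.size, size=n_rem, replace=False)
                keep = np.ones(a.size, dtype=bool)
                keep[sub] = False
                reps[rep] = 100.0 * (r_of(a[keep], b[keep]) - r_full) / r_full
        rand_cols.append(reps)
    return CorrelationChange(
        per_group=pd.DataFrame(rows),
        random_changes=np.column_stack(rand_cols) if rand_cols else np.zeros((0, 0)),
        removal_kind=removal_kind)


# ---------------------------------------------------------------------------
# Linear decoding
# ---------------------------------------------------------------------------

@dataclass
class DecoderReport:
    """Cross-validated S+/S− decoding accuracy for one session."""

    accuracy: float                 # percent of held-out trials correctly labelled
    per_split: np.ndarray
    task: str
    roi_set: str
    n_trials: int
    n_rois: int
    session_id: str = "session0"


def train_eval_decoder(table: ResponseTable, task: str = "fine",
                       roi_mask: np.ndarray | None = None,
                       n_repeats: int = 100, seed: int | None = 0,
                       shrinkage: str | float | None = "auto",
                       roi_set: str = "all") -> DecoderReport:
    """Linear-discriminant decoding of S+ vs S− from population amplitude vectors.

    Features are per-trial amplitude vectors over the kept ROIs; the classifier
    shares one covariance across classes, shrunk toward its diagonal
    analytically (Ledoit-Wolf) since ROI count can exceed trial count.
    Accuracy is averaged over ``n_repeats`` stratified 2/3 train / 1/3 test
    splits.  Probe trials are excluded (their odour/reward pairing is reversed).
    """
    mask = table.trial_mask(task=task, probe=False)
    X = table.amplitudes[:, mask].T
    y = table.trials["rewarded"].to_numpy()[mask].astype(int)
    if roi_mask is not None:
        X = X[:, np.asarray(roi_mask, dtype=bool)]
    counts = np.bincount(y, minlength=2)
    if counts.min() < 3:
        raise ValueError(f"need >= 3 trials per class, got {counts.tolist()}")
    splitter = StratifiedShuffleSplit(n_splits=n_repeats, test_size=1 / 3,
                                      random_state=None if seed is None else int(seed))
    accs = []
    for train, test in splitter.split(X, y):
        clf = LinearDiscriminantAnalysis(
            solver="lsqr" if shrinkage is not None else "svd",
            shrinkage=shrinkage, priors=[0.5, 0.5])
        clf.fit(X[train], y[train])
        accs.append(100.0 * float((clf.predict(X[test]) == y[test]).mean()))
    accs_arr = np.asarray(accs)
    return DecoderReport(accuracy=float(accs_arr.mean()), per_split=accs_arr,
                         task=task, roi_set=roi_set, n_trials=int(mask.sum()),
                         n_rois=int(X.shape[1]), session_id=table.session_id)


# ---------------------------------------------------------------------------
# Selectivity enrichment among modulated ROIs
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Are stimulus-selective ROIs over-represented among task-modulated ones?"""

    ks_statistic: float
    ks_p: float
    n_modulated: int
    n_non_modulated: int
    frac_selective_modulated: float    # modulated fraction among selective ROIs
    frac_modulated: float              # modulated fraction overall
    selectivity_alpha: float = 0.05


def selectivity_enrichment(selectivity: list[SelectivityResult],
                           modulation: list[ModulationResult],
                           selectivity_alpha: float = 0.05) -> EnrichmentResult:
    """Two-sample KS test on selectivity indices of modulated vs non-modulated ROIs.

    Also reports the modulated fraction among significantly selective ROIs
    (selectivity p < ``selectivity_alpha``) against the overall modulated
    fraction.
    """
    s = np.concatenate([r.s for r in selectivity])
    sel_p = np.concatenate([r.p for r in selectivity])
    mod = np.concatenate([m.modulated for m in modulation])
    if s.shape != mod.shape:
        raise ValueError("selectivity and modulation results must cover the same ROIs")
    if mod.all() or not mod.any():
        raise ValueError("both modulated and non-modulated groups must be non-empty")
    ks = stats.ks_2samp(s[mod], s[~mod])
    selective = sel_p < selectivity_alpha
    frac_sel_mod = float(mod[selective].mean()) if selective.any() else np.nan
    return EnrichmentResult(
        ks_statistic=float(ks.statistic), ks_p=float(ks.pvalue),
        n_modulated=int(mod.sum()), n_non_modulated=int((~mod).sum()),
        frac_selective_modulated=frac_sel_mod, frac_modulated=float(mod.mean()),
        selectivity_alpha=selectivity_alpha)
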