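"""Synthetic cohort generator with full ground truth.

Emulates the task-switching go/no-go imaging experiment: each session has three
epochs (Fine1 -> Coarse -> Fine2, 15-25 trials each), 1-s odour pulses, 20-s
inter-trial intervals, rare rewarded alphaprime "probe" trials during the
Coarse epoch, GCaMP6f-like somatic transients on a common frame clock, and a
quasi-periodic respiration trace whose per-trial rate couples linearly into
response amplitudes.

A modulated subpopulation (~12% of ROIs, drawn from the alpha-selective class)
has its alpha responses amplified by a fixed ΔF/F offset during the fine
epochs only — the generative claim the downstream statistics are meant to
recover.  Every stochastic choice is recorded in :class:`GroundTruth` so
parameter recovery can be scored exactly.

Amplitude model for trial *i*, ROI *r*::

    a[r, i] = A[r, odour_i]                       tuning (class-dependent)
            + delta[r] * 1[fine epoch & alpha]    task modulation
            + sniff_coupling * (rate_i - rate_mean)
            + N(0, amplitude_jitter_sd)           intrinsic trial variability

and the trace adds a double-exponential kernel scaled so that the mean ΔF/F
over the 1-s odour window equals a[r, i] exactly, plus i.i.d. Gaussian frame
noise of sd ``noise_sd`` (ΔF/F units).  Identical (config, seed) pairs produce
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .session_io import SessionData, TrialRecord, write_session

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_trial_sequence",
    "generate_sniff_trace",
    "generate_roi_traces",
    "generate_session",
    "generate_cohort",
    "write_cohort",
]


class InfeasibleDesignError(ValueError):
    """Trial-sequence constraints cannot be satisfied; never silently relaxed."""


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic experiment.

    Defaults are the study conditions: 5 animals totalling 353 ROIs, epochs of
    15-25 trials, 1-s odour / 20-s ITI, probe trials at a long-run mean of 1.6
    per session, ~12% modulated ROIs amplified by 0.17 ΔF/F during fine
    discrimination, GCaMP6f-like kinetics (rise 0.05 s, decay 0.5 s).
    """

    n_animals: int = 5
    rois_per_animal: tuple[int, ...] | int = (71, 71, 71, 70, 70)
    frame_rate: float = 30.0
    epoch_length_range: tuple[int, int] = (15, 25)
    odour_duration: float = 1.0
    iti: float = 20.0
    probe_rate: float = 1.6
    kernel_rise: float = 0.05
    kernel_decay: float = 0.5
    baseline_f: float = 100.0
    noise_sd: float = 0.1                 # per-frame ΔF/F noise
    amplitude_jitter_sd: float = 0.08     # per-trial intrinsic amplitude variability (ΔF/F)
    frac_alpha_selective: float = 0.25
    frac_alphaprime_selective: float = 0.20
    frac_modulated: float = 0.12
    modulation_delta: float = 0.17        # ΔF/F, fine > coarse on alpha responses
    base_amplitude_range: tuple[float, float] = (0.05, 0.5)
    selectivity_gap_range: tuple[float, float] = (0.01, 0.10)
    beta_amplitude_range: tuple[float, float] = (0.0, 0.5)
    sniff_rate_mean: float = 4.0          # Hz
    sniff_rate_sd: float = 0.5            # Hz, per-cycle jitter
    sniff_coupling: float = 0.05          # ΔF/F per Hz of trial sniff rate
    lapse_rate: float = 0.05              # behavioural error probability per trial
    pre_time: float = 5.0                 # seconds before the first odour onset
    post_time: float = 5.0                # seconds after the last odour offset
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fracs = (self.frac_alpha_selective, self.frac_alphaprime_selective)
        if any(not (0.0 <= f <= 1.0) for f in fracs + (self.frac_modulated,)):
            raise ValueError("all proportions must lie in [0, 1]")
        if sum(fracs) > 1.0:
            raise ValueError("selectivity class proportions must sum to <= 1")
        if self.frac_modulated > self.frac_alpha_selective:
            raise ValueError(
                "frac_modulated cannot exceed frac_alpha_selective: modulation is "
                "confined to alpha-selective ROIs")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.modulation_delta < 0:
            raise ValueError("modulation_delta must be >= 0")
        if self.kernel_rise <= 0 or self.kernel_decay <= 0:
            raise ValueError("kernel time constants must be > 0")
        if self.kernel_rise >= self.kernel_decay:
            raise ValueError("kernel_rise must be shorter than kernel_decay")
        lo, hi = self.epoch_length_range
        if lo > hi or lo < 5:
            raise InfeasibleDesignError(
                f"epoch_length_range {self.epoch_length_range}: epochs need >= 5 trials "
                "to host >= 4 rewarded trials under the run-length bound")

    def roi_counts(self) -> list[int]:
        if isinstance(self.rois_per_animal, int):
            return [self.rois_per_animal] * self.n_animals
        counts = list(self.rois_per_animal)
        if len(counts) != self.n_animals:
            raise ValueError("rois_per_animal length must equal n_animals")
        return counts

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("rois_per_animal", "epoch_length_range", "base_amplitude_range",
                    "selectivity_gap_range", "beta_amplitude_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Generator-side labels for one session (arrays indexed by ROI)."""

    selectivity_class: np.ndarray      # {"alpha", "alphaprime", "none"}
    true_amplitude_alpha: np.ndarray   # ΔF/F
    true_amplitude_alphaprime: np.ndarray
    true_amplitude_beta: np.ndarray
    is_modulated: np.ndarray           # bool
    true_delta: np.ndarray             # ΔF/F; 0 wherever not modulated
    sniff_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    trial_sniff_rate: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if np.any(self.true_delta[~self.is_modulated] != 0.0):
            raise ValueError("true_delta must be 0 for unmodulated ROIs")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Trial sequencing
# ---------------------------------------------------------------------------

def _max_run(x: np.ndarray) -> int:
    best = run = 1
    for i in range(1, len(x)):
        run = run + 1 if x[i] == x[i - 1] else 1
        best = max(best, run)
    return best


def _epoch_types(rng: np.random.Generator, length: int, max_tries: int = 10_000) -> np.ndarray:
    """Random S+/S− sequence: fair draws, max same-type run <= 3, >= 4 S+."""
    if length - length // 4 < 4:
        raise InfeasibleDesignError(
            f"epoch of {length} trials cannot host 4 rewarded trials with run length <= 3")
    for _ in range(max_tries):
        types = rng.random(length) < 0.5
        if types.sum() >= 4 and _max_run(types) <= 3:
            return types
    raise InfeasibleDesignError(
        f"could not sample a feasible {length}-trial epoch in {max_tries} tries")


def generate_trial_sequence(config: GeneratorConfig, seed) -> list[TrialRecord]:
    """Draw the three-epoch trial sequence (stubs: no licks/outcome yet).

    Fine epochs present alpha (S+) vs alphaprime (S−); the Coarse epoch
    presents alpha (S+) vs beta (S−) with a Poisson(probe_rate) number of S+
    slots converted to rewarded alphaprime probes (capped so that at least two
    plain alpha S+ trials survive).  No more than three consecutive trials
    share a type and every epoch has >= 4 rewarded trials.
    """
    rng = _as_rng(seed)
    lo, hi = config.epoch_length_range
    trials: list[TrialRecord] = []
    trial_id = 0
    step = config.odour_duration + config.iti
    fr = config.frame_rate

    for epoch in ("Fine1", "Coarse", "Fine2"):
        length = int(rng.integers(lo, hi + 1))
        types = _epoch_types(rng, length)  # True = S+
        probe_slots: set[int] = set()
        if epoch == "Coarse":
            splus_idx = np.flatnonzero(types)
            n_probe = min(int(rng.poisson(config.probe_rate)), max(len(splus_idx) - 2, 0))
            if n_probe > 0:
                probe_slots = set(rng.choice(splus_idx, size=n_probe, replace=False).tolist())
        for i, splus in enumerate(types):
            if epoch in ("Fine1", "Fine2"):
                odour = "alpha" if splus else "alphaprime"
                probe = False
            else:
                if splus:
                    probe = i in probe_slots
                    odour = "alphaprime" if probe else "alpha"
                else:
                    odour, probe = "beta", False
            onset = config.pre_time + trial_id * step
            onset = round(onset * fr) / fr  # snap to the frame grid
            trials.append(TrialRecord(
                trial_id=trial_id, epoch=epoch, odour=odour,
                rewarded=bool(splus), probe=probe, odour_onset=onset))
            trial_id += 1
    return trials


# ---------------------------------------------------------------------------
# Respiration
# ---------------------------------------------------------------------------

def generate_sniff_trace(config: GeneratorConfig, duration: float,
                         seed) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-periodic nasal-flow trace plus exact inhalation onset times.

    Each cycle's rate is drawn N(sniff_rate_mean, sniff_rate_sd), floored at
    0.5 Hz; the trace is -sin(2*pi*phase) within each cycle so an inhalation
    onset is a negative-going zero crossing.  The stretch before the first
    onset is filled with the tail of a virtual preceding cycle so detection is
    well defined from frame 0.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    rng = _as_rng(seed)
    n = int(round(duration * config.frame_rate))

    def draw_rate() -> float:
        return max(float(rng.normal(config.sniff_rate_mean, config.sniff_rate_sd)), 0.5)

    onsets, periods = [], []
    t = 0.1  # first onset a few frames in so its zero crossing is observable
    while t < duration:
        rate = draw_rate()
        onsets.append(t)
        periods.append(1.0 / rate)
        t += periods[-1]
    onsets_arr = np.asarray(onsets)
    periods_arr = np.asarray(periods)

    times = np.arange(n) / config.frame_rate
    idx = np.searchsorted(onsets_arr, times, side="right") - 1
    phase = np.empty(n)
    pre = idx < 0  # before the first onset: virtual preceding cycle, same period
    phase[pre] = (times[pre] - (onsets_arr[0] - periods_arr[0])) / periods_arr[0]
    phase[~pre] = (times[~pre] - onsets_arr[idx[~pre]]) / periods_arr[idx[~pre]]
    trace = -np.sin(2.0 * np.pi * phase)
    return trace, onsets_arr


def _trial_sniff_rates(trials: list[TrialRecord], onsets: np.ndarray,
                       odour_duration: float) -> np.ndarray:
    """Inhalation-onset count per odour window divided by the window length (Hz)."""
    rates = np.empty(len(trials))
    for i, t in enumerate(trials):
        count = int(np.count_nonzero(
            (onsets >= t.odour_onset) & (onsets < t.odour_onset + odour_duration)))
        rates[i] = count / odour_duration
    return rates


# ---------------------------------------------------------------------------
# Ground truth and traces
# ---------------------------------------------------------------------------

def sample_ground_truth(config: GeneratorConfig, n_rois: int,
                        seed) -> GroundTruth:
    """Draw per-ROI tuning classes, amplitudes and modulation flags."""
    rng = _as_rng(seed)
    u = rng.random(n_rois)
    cls = np.where(u < config.frac_alpha_selective, "alpha",
                   np.where(u < config.frac_alpha_selective + config.frac_alphaprime_selective,
                            "alphaprime", "none")).astype(object)
    base = rng.uniform(*config.base_amplitude_range, n_rois)
    gap = rng.uniform(*config.selectivity_gap_range, n_rois)
    amp_a = base + np.where(cls == "alpha", gap, 0.0)
    amp_ap = base + np.where(cls == "alphaprime", gap, 0.0)
    amp_b = rng.uniform(*config.beta_amplitude_range, n_rois)
    # Modulation lives inside the alpha-selective class; conditional rate chosen
    # so the marginal modulated fraction equals frac_modulated.
    p_mod = (config.frac_modulated / config.frac_alpha_selective
             if config.frac_alpha_selective > 0 else 0.0)
    is_mod = (cls == "alpha") & (rng.random(n_rois) < p_mod)
    delta = np.where(is_mod, config.modulation_delta, 0.0)
    return GroundTruth(
        selectivity_class=cls,
        true_amplitude_alpha=amp_a,
        true_amplitude_alphaprime=amp_ap,
        true_amplitude_beta=amp_b,
        is_modulated=is_mod,
        true_delta=delta,
    )


def _response_kernel(config: GeneratorConfig) -> np.ndarray:
    """Difference-of-exponentials kernel sampled on the frame grid.

    Normalized so the mean over the frames of the 1-s odour window is exactly 1:
    scaling by a trial amplitude then makes the window-mean ΔF/F equal that
    amplitude by construction.  Support is truncated where the tail is far
    below numerical relevance (well before the next trial's baseline).
    """
    if config.kernel_rise <= 0 or config.kernel_decay <= 0:
        raise ValueError("kernel time constants must be positive")
    fr = config.frame_rate
    support = int(round((config.odour_duration + 24.0 * config.kernel_decay) * fr))
    t = np.arange(support) / fr
    k = np.exp(-t / config.kernel_decay) - np.exp(-t / config.kernel_rise)
    n_win = int(round(config.odour_duration * fr))
    k /= k[:n_win].mean()
    return k


def trial_amplitudes(trials: list[TrialRecord], ground_truth: GroundTruth,
                     sniff_rates: np.ndarray, config: GeneratorConfig,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """True per-(ROI, trial) window-mean amplitudes, including jitter if rng given."""
    n_rois = len(ground_truth.true_amplitude_alpha)
    amps = np.empty((n_rois, len(trials)))
    for i, trial in enumerate(trials):
        if trial.odour == "alpha":
            a = ground_truth.true_amplitude_alpha.copy()
            if trial.task == "fine":
                a = a + ground_truth.true_delta
        elif trial.odour == "alphaprime":
            a = ground_truth.true_amplitude_alphaprime.copy()
        else:
            a = ground_truth.true_amplitude_beta.copy()
        a = a + config.sniff_coupling * (sniff_rates[i] - config.sniff_rate_mean)
        if rng is not None and config.amplitude_jitter_sd > 0:
            a = a + rng.normal(0.0, config.amplitude_jitter_sd, n_rois)
        amps[:, i] = a
    return amps


def generate_roi_traces(trials: list[TrialRecord], ground_truth: GroundTruth,
                        sniff_rates: np.ndarray, config: GeneratorConfig,
                        seed, n_frames: int | None = None) -> np.ndarray:
    """Raw fluorescence matrix [n_rois, n_frames] for one session.

    F = baseline_f * (1 + signal + noise) where signal is the kernel model and
    noise is i.i.d. N(0, noise_sd) per frame in ΔF/F units.
    """
    rng = _as_rng(seed)
    fr = config.frame_rate
    if n_frames is None:
        last = max(t.odour_onset for t in trials) if trials else 0.0
        n_frames = int(round((last + config.odour_duration + config.post_time) * fr))
    n_rois = len(ground_truth.true_amplitude_alpha)
    kernel = _response_kernel(config)

    amps = trial_amplitudes(trials, ground_truth, sniff_rates, config, rng=rng)
    dff = np.zeros((n_rois, n_frames))
    for i, trial in enumerate(trials):
        f0 = int(round(trial.odour_onset * fr))
        if f0 + int(round(config.odour_duration * fr)) > n_frames:
            raise ValueError(f"trial {trial.trial_id} does not fit in the session duration")
        span = min(len(kernel), n_frames - f0)
        dff[:, f0:f0 + span] += amps[:, [i]] * kernel[None, :span]
    if config.noise_sd > 0:
        dff += rng.normal(0.0, config.noise_sd, size=dff.shape)
    return config.baseline_f * (1.0 + dff)


# ---------------------------------------------------------------------------
# Sessions and cohorts
# ---------------------------------------------------------------------------

def _simulate_licks(trials: list[TrialRecord], config: GeneratorConfig,
                    rng: np.random.Generator) -> list[TrialRecord]:
    """Bernoulli correct/incorrect agent: lapse applies independently per trial."""
    out = []
    for t in trials:
        correct = bool(rng.random() >= config.lapse_rate)
        lick = t.rewarded == correct  # lick iff (S+ and correct) or (S− and incorrect)
        licks = tuple(t.odour_onset + 1.1 + 0.2 * k for k in range(3)) if lick else ()
        out.append(TrialRecord(
            trial_id=t.trial_id, epoch=t.epoch, odour=t.odour, rewarded=t.rewarded,
            probe=t.probe, odour_onset=t.odour_onset, lick_times=licks,
            outcome="correct" if correct else "incorrect"))
    return out


def generate_session(config: GeneratorConfig, seed, n_rois: int | None = None,
                     animal_id: str = "m1", session_id: str | None = None,
                     ) -> tuple[SessionData, GroundTruth]:
    """Assemble one complete session (trials, licks, sniff, traces) + ground truth."""
    rng = _as_rng(seed)
    if n_rois is None:
        n_rois = config.roi_counts()[0]
    trials = generate_trial_sequence(config, rng)
    trials = _simulate_licks(trials, config, rng)
    last = max(t.odour_onset for t in trials)
    duration = last + config.odour_duration + config.post_time
    sniff, onsets = generate_sniff_trace(config, duration, rng)
    rates = _trial_sniff_rates(trials, onsets, config.odour_duration)
    gt = sample_ground_truth(config, n_rois, rng)
    gt.sniff_onsets = onsets
    gt.trial_sniff_rate = rates
    traces = generate_roi_traces(trials, gt, rates, config, rng,
                                 n_frames=int(round(duration * config.frame_rate)))
    session = SessionData(
        trials=trials, traces=traces, sniff=sniff, frame_rate=config.frame_rate,
        animal_id=animal_id, session_id=session_id or f"{animal_id}_s1")
    return session, gt


def generate_cohort(config: GeneratorConfig, seed=None,
                    ) -> list[tuple[SessionData, GroundTruth]]:
    """One session per animal; per-animal seeds spawned from the master seed."""
    if config.n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(config.n_animals)
    cohort = []
    for a, (child, n_rois) in enumerate(zip(children, config.roi_counts())):
        animal = f"m{a + 1}"
        cohort.append(generate_session(
            config, np.random.default_rng(child), n_rois=n_rois,
            animal_id=animal, session_id=f"{animal}_s1"))
    return cohort


def write_cohort(cohort: list[tuple[SessionData, GroundTruth]], out_dir: str | Path) -> None:
    """Write each session into ``out_dir/<session_id>/`` plus ground-truth CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import pandas as pd  # local import keeps module import light

    for session, gt in cohort:
        sdir = out_dir / session.session_id
        write_session(session, sdir)
        pd.DataFrame({
            "roi": np.arange(len(gt.selectivity_class)),
            "selectivity_class": gt.selectivity_class,
            "true_amplitude_alpha": gt.true_amplitude_alpha,
            "true_amplitude_alphaprime": gt.true_amplitude_alphaprime,
            "true_amplitude_beta": gt.true_amplitude_beta,
            "is_modulated": gt.is_modulated,
            "true_delta": gt.true_delta,
        }).to_csv(sdir / "ground_truth.csv", index=False)
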