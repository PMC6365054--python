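"""End-to-end orchestration: generate/load -> validate -> analyse -> report.

`run_pipeline` executes every analysis stage on a cohort and writes a bundle
of CSV/JSON artifacts into the output directory; `make_report` renders a
human-readable summary (markdown + figures) from an existing bundle.  All
randomness derives deterministically from the master seed, so two runs with
identical config + seed produce byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import modulation as mod
from . import population as pop
from . import responses as resp
from . import session_io as sio
from . import synthgen as gen

log = logging.getLogger("bulbswitch")

__all__ = ["RunConfig", "run_pipeline", "make_report", "load_cohort"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    generator: gen.GeneratorConfig = field(default_factory=gen.GeneratorConfig)
    alpha_level: float = 0.05
    baseline_window: float = 2.0
    n_shuffles: int = 100
    decoder_repeats: int = 100
    n_random_removals: int = 100
    grouping: str = "animal"
    out_dir: str = "bulbswitch_run"
    seed: int = 0
    cohort_dir: str | None = None     # analyse an existing cohort instead of generating

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen_cfg = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen_cfg:
            for key in ("rois_per_animal", "epoch_length_range", "base_amplitude_range",
                        "selectivity_gap_range", "beta_amplitude_range"):
                if key in gen_cfg and isinstance(gen_cfg[key], list):
                    gen_cfg[key] = tuple(gen_cfg[key])
            cfg.generator = gen.GeneratorConfig(**gen_cfg)
        return cfg

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_cohort(cohort_dir: str | Path) -> list[tuple[sio.SessionData, gen.GroundTruth | None]]:
    """Read every session directory under ``cohort_dir`` (sorted by name)."""
    cohort = []
    for sdir in sorted(Path(cohort_dir).iterdir()):
        if not (sdir / "meta.yaml").exists():
            continue
        session = sio.read_session(sdir)
        gt = None
        gt_path = sdir / "ground_truth.csv"
        if gt_path.exists():
            df = pd.read_csv(gt_path)
            gt = gen.GroundTruth(
                selectivity_class=df["selectivity_class"].to_numpy(dtype=object),
                true_amplitude_alpha=df["true_amplitude_alpha"].to_numpy(),
                true_amplitude_alphaprime=df["true_amplitude_alphaprime"].to_numpy(),
                true_amplitude_beta=df["true_amplitude_beta"].to_numpy(),
                is_modulated=df["is_modulated"].to_numpy(dtype=bool),
                true_delta=df["true_delta"].to_numpy(),
            )
        cohort.append((session, gt))
    if not cohort:
        raise FileNotFoundError(f"no session directories found under {cohort_dir}")
    return cohort


def _recovery_summary(results: list[mod.ModulationResult],
                      truths: list[gen.GroundTruth]) -> dict:
    called = np.concatenate([r.modulated for r in results])
    true = np.concatenate([g.is_modulated for g in truths])
    tp = int((called & true).sum())
    fp = int((called & ~true).sum())
    sens = tp / true.sum() if true.sum() else np.nan
    fpr = fp / (~true).sum() if (~true).sum() else np.nan
    return {
        "n_rois": int(true.size),
        "n_true_modulated": int(true.sum()),
        "n_called_modulated": int(called.sum()),
        "sensitivity": float(sens),
        "false_positive_rate": float(fpr),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; write the bundle; return it in memory.

    Stages: cohort (generate or load), behaviour scoring + switching curves,
    epoch equalization, response tables, selectivity, task modulation (raw and
    sniff-residualized), shuffle calibration, PCA trajectories, alpha/alphaprime
    correlation with modulated-vs-random ROI removal, per-session decoding, and
    a ground-truth recovery summary when ground truth is available.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(s) for name, s in zip(
        ("cohort", "shuffle", "removal", "decoder"),
        rng.integers(0, 2**31, size=4))}
    (out / "seeds.json").write_text(json.dumps(seeds, indent=1))

    stage = "generate"
    try:
        if config.cohort_dir:
            log.info("loading cohort from %s", config.cohort_dir)
            cohort = load_cohort(config.cohort_dir)
        else:
            log.info("generating cohort (seed %d)", seeds["cohort"])
            cohort = gen.generate_cohort(config.generator, seed=seeds["cohort"])
        sessions = [s for s, _ in cohort]
        truths = [g for _, g in cohort]
        for s in sessions:
            sio.validate_session(s)

        stage = "behaviour"
        behaviour = [sio.score_behaviour(s) for s in sessions]
        curves = sio.switching_curve(sessions)
        pd.DataFrame({
            "session_id": [s.session_id for s in sessions],
            "animal_id": [s.animal_id for s in sessions],
            "percent_correct": [b.percent_correct for b in behaviour],
        }).to_csv(out / "behaviour.csv", index=False)
        pd.concat({k: v for k, v in curves.items()},
                  names=["alignment"]).to_csv(out / "switching_curve.csv")

        stage = "responses"
        equalized = [sio.equalize_fine_epochs(s) for s in sessions]
        tables = [resp.compute_responses(s, config.baseline_window) for s in equalized]
        pd.concat([t.to_frame() for t in tables], ignore_index=True
                  ).to_csv(out / "responses.csv", index=False)

        stage = "selectivity"
        selectivity = [resp.selectivity_tscore(t) for t in tables]
        pd.concat([r.to_frame() for r in selectivity], ignore_index=True
                  ).to_csv(out / "selectivity.csv", index=False)

        stage = "modulation"
        raw_mod = [mod.task_modulation_test(t, config.alpha_level) for t in tables]
        sniff_tables = []
        for s, t in zip(equalized, tables):
            feats = mod.extract_sniff_features(s)
            sniff_tables.append(mod.residualize_on_sniff(t, feats))
        sniff_mod = [mod.task_modulation_test(t, config.alpha_level) for t in sniff_tables]
        pd.concat([m.to_frame() for m in raw_mod + sniff_mod], ignore_index=True
                  ).to_csv(out / "modulation.csv", index=False)

        stage = "shuffle"
        calib = mod.shuffle_control(tables, config.alpha_level,
                                    n_shuffles=config.n_shuffles, seed=seeds["shuffle"])
        (out / "shuffle.json").write_text(json.dumps(calib.to_dict(), indent=1))

        stage = "trajectories"
        ppop = pop.build_pseudopopulation(equalized)
        traj = pop.pca_trajectories(ppop)
        traj.to_frame().to_csv(out / "trajectories.csv", index=False)
        (out / "explained_variance.json").write_text(json.dumps(
            {"explained_variance_ratio": traj.explained_variance_ratio.tolist()}, indent=1))

        stage = "correlation"
        removal_masks = [r.modulated for r in raw_mod]
        change = pop.removal_correlation_change(
            tables, removal_masks, groupby=config.grouping,
            n_random_replicates=config.n_random_removals, seed=seeds["removal"])
        change.per_group.to_csv(out / "correlation_change.csv", index=False)
        (out / "correlation_change.json").write_text(json.dumps({
            "mean_change_pct_modulated_removed": change.mean_change,
            "mean_change_pct_random_removed": change.mean_random_change,
        }, indent=1))

        stage = "decoder"
        decoder_rows = []
        for t, m in zip(tables, raw_mod):
            for task in ("fine", "coarse"):
                for roi_set, mask in (("all", None),
                                      ("modulated_removed", ~m.modulated)):
                    try:
                        rep = pop.train_eval_decoder(
                            t, task=task, roi_mask=mask, n_repeats=config.decoder_repeats,
                            seed=seeds["decoder"], roi_set=roi_set)
                    except ValueError as err:
                        warnings.warn(f"decoder skipped for {t.session_id}/{task}: {err}",
                                      stacklevel=2)
                        continue
                    decoder_rows.append({
                        "session_id": rep.session_id, "task": rep.task,
                        "roi_set": rep.roi_set, "accuracy_pct": rep.accuracy,
                        "n_rois": rep.n_rois, "n_trials": rep.n_trials})
        pd.DataFrame(decoder_rows).to_csv(out / "decoder.csv", index=False)

        stage = "enrichment"
        enr = pop.selectivity_enrichment(selectivity, raw_mod, config.alpha_level)
        (out / "enrichment.json").write_text(json.dumps({
            "ks_statistic": enr.ks_statistic, "ks_p": enr.ks_p,
            "n_modulated": enr.n_modulated, "n_non_modulated": enr.n_non_modulated,
            "frac_selective_modulated": enr.frac_selective_modulated,
            "frac_modulated": enr.frac_modulated}, indent=1))

        stage = "recovery"
        recovery = None
        if all(g is not None for g in truths):
            recovery = _recovery_summary(raw_mod, truths)
            (out / "recovery.json").write_text(json.dumps(recovery, indent=1))
    except Exception as err:
        (out / "INCOMPLETE").write_text(f"failed at stage: {stage}\n{err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    bundle = {
        "config": config, "config_hash": config.config_hash(), "sessions": sessions,
        "behaviour": behaviour, "switching_curves": curves, "tables": tables,
        "selectivity": selectivity, "modulation_raw": raw_mod,
        "modulation_sniff": sniff_mod, "shuffle": calib, "trajectories": traj,
        "correlation_change": change, "decoder": pd.DataFrame(decoder_rows),
        "enrichment": enr, "recovery": recovery,
    }
    (out / "manifest.json").write_text(json.dumps({
        "config_hash": config.config_hash(),
        "stages": ["behaviour", "responses", "selectivity", "modulation", "shuffle",
                   "trajectories", "correlation", "decoder", "enrichment", "recovery"],
    }, indent=1))
    log.info("pipeline complete: %s", out)
    return bundle


def make_report(out_dir: str | Path) -> Path:
    """Render summary.md plus figures from a completed bundle directory.

    Idempotent: regenerating from the same bundle rewrites identical content.
    """
    out = Path(out_dir)
    if (out / "INCOMPLETE").exists():
        raise RuntimeError(f"bundle {out} is marked incomplete")
    needed = ["config.yaml", "behaviour.csv", "modulation.csv", "shuffle.json",
              "trajectories.csv", "correlation_change.json", "decoder.csv",
              "enrichment.json", "manifest.json"]
    for name in needed:
        if not (out / name).exists():
            raise FileNotFoundError(f"bundle member missing: {out / name}")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    manifest = json.loads((out / "manifest.json").read_text())
    behaviour = pd.read_csv(out / "behaviour.csv")
    modulation_df = pd.read_csv(out / "modulation.csv")
    shuffle = json.loads((out / "shuffle.json").read_text())
    corr = json.loads((out / "correlation_change.json").read_text())
    enr = json.loads((out / "enrichment.json").read_text())
    decoder = pd.read_csv(out / "decoder.csv")
    traj = pd.read_csv(out / "trajectories.csv")
    curves = pd.read_csv(out / "switching_curve.csv")

    figures = out / "figures"
    figures.mkdir(exist_ok=True)

    fig, ax = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
    for k, kind in enumerate(("fine_to_coarse", "coarse_to_fine")):
        sub = curves[curves["alignment"] == kind]
        ax[k].errorbar(sub["trial_from_switch"], 100 * sub["mean"],
                       yerr=100 * sub["sem"], fmt="-o", ms=3)
        ax[k].axvline(0, color="grey", ls=":")
        ax[k].set_title(kind.replace("_", " "))
        ax[k].set_xlabel("trial from switch")
    ax[0].set_ylabel("% correct")
    fig.tight_layout()
    fig.savefig(figures / "switching_curve.png", dpi=120)
    plt.close(fig)

    fig = plt.figure(figsize=(5, 4))
    ax3 = fig.add_subplot(projection="3d")
    for cond, sub in traj.groupby("condition"):
        ax3.plot(sub["pc1"], sub["pc2"], sub["pc3"], label=cond)
    ax3.legend(fontsize=7)
    fig.savefig(figures / "trajectories.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 3))
    raw = modulation_df[modulation_df["variant"] == "raw"]
    ax.hist(raw["delta"], bins=40)
    ax.set_xlabel("fine − coarse alpha response (ΔF/F)")
    ax.set_ylabel("ROIs")
    fig.tight_layout()
    fig.savefig(figures / "modulation_hist.png", dpi=120)
    plt.close(fig)

    n_mod_raw = int(raw["modulated"].sum())
    n_rois = int(raw.shape[0])
    sniff = modulation_df[modulation_df["variant"] == "sniff_residualized"]
    lines = [
        "# Task-switching analysis report",
        "",
        f"Config hash: `{manifest['config_hash']}`",
        "",
        "## Behaviour",
        f"- mean session accuracy: {behaviour['percent_correct'].mean():.1f}% "
        f"over {len(behaviour)} sessions",
        "",
        "## Task modulation",
        f"- modulated ROIs (raw): {n_mod_raw}/{n_rois}",
        f"- modulated ROIs (sniff-residualized): {int(sniff['modulated'].sum())}/{n_rois}",
        f"- shuffle control: {shuffle['mean_count']:.1f}/{shuffle['n_rois']} "
        f"expected by chance at alpha={shuffle['alpha_level']}",
        "",
        "## Population",
        f"- correlation change, modulated removed: "
        f"{corr['mean_change_pct_modulated_removed']:.2f}% "
        f"(random removed: {corr['mean_change_pct_random_removed']:.2f}%)",
        f"- selectivity enrichment: KS={enr['ks_statistic']:.2f}, p={enr['ks_p']:.3g}",
        "",
        "## Decoding (% correct, mean over sessions)",
        decoder.groupby(["task", "roi_set"])["accuracy_pct"].mean().round(1)
        .to_frame().to_markdown(),
        "",
        "Figures: `figures/switching_curve.png`, `figures/trajectories.png`, "
        "`figures/modulation_hist.png`.",
        "",
    ]
    report = out / "summary.md"
    report.write_text("\n".join(lines))
    return report
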