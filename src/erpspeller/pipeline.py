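"""End-to-end experiment orchestration.

One subject's run: simulate a training and an online session, build k-sub-
average training inputs from the training session, fit the CNN, decode every
online trial from its k=20 per-icon averages, and summarise — trial accuracy,
per-icon confusion metrics, ROC/AUC, ERP detection rate and H/L group, plus
the feature-map statistics (PSNR of L1, PeT of L2) computed on the wrapped
grand-average target ERP over all sessions.

Seeding: a single master seed determines everything.  Per-stage generators
derive from ``SeedSequence([master_seed, crc32(stage), index])``, so stages
are decoupled and any subject can be re-run in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnn, decoder, epochs, featuremaps, metrics, synthetic
from .montage import N_REPETITIONS, TRIALS_PER_SESSION

__all__ = ["RunConfig", "stage_seed", "run_subject", "run_experiment",
           "metrics_frame", "group_anova"]


def stage_seed(master_seed: int, stage: str, index: int = 0) -> np.random.SeedSequence:
    """Documented derivation of per-stage seeds from the master seed."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode()), int(index)])


@dataclass(frozen=True)
class RunConfig:
    """Cohort-level experiment configuration."""

    n_h: int = 10                    # H-like subjects
    n_l: int = 10                    # L-like subjects
    n_trials: int = TRIALS_PER_SESSION
    k: int = 5                       # training sub-average size
    master_seed: int = 0
    profile: str = "desk"            # desk (2000 iters) | full (10,000)
    spec_overrides: dict = field(default_factory=dict)
    out_dir: str | None = None

    def cnn_spec(self, seed: int) -> cnn.CnnSpec:
        maker = {"desk": cnn.desk_spec, "full": cnn.full_spec}
        if self.profile not in maker:
            raise ValueError(f"unknown profile {self.profile!r}; expected desk|full")
        return maker[self.profile](seed=seed, **self.spec_overrides)


@dataclass
class SubjectRun:
    """Everything produced for one subject."""

    profile: synthetic.SubjectProfile
    model: cnn.TrainedCnn
    decisions: list[decoder.TrialDecision]
    counts: metrics.ConfusionCounts
    l1_maps: list[featuremaps.FeatureMap]
    l2_maps: list[featuremaps.FeatureMap]
    summary: metrics.SubjectMetrics


def run_subject(group_label: str, subject_index: int, config: RunConfig,
                subject_id: str | None = None) -> SubjectRun:
    """Simulate, train, decode and analyse a single synthetic subject."""
    if subject_id is None:
        tag = "H" if group_label == synthetic.GROUP_H else "L"
        subject_id = f"{tag}{subject_index:02d}"

    prof_rng = np.random.default_rng(
        stage_seed(config.master_seed, "profile:" + group_label, subject_index))
    profile = synthetic.make_profile(group_label,
                                     int(prof_rng.integers(0, 2 ** 31)))

    train_epochs = synthetic.simulate_session(
        profile, config.n_trials,
        stage_seed(config.master_seed, "simulate:train:" + group_label, subject_index),
        subject_id=subject_id, session_id=0)
    online_epochs = synthetic.simulate_session(
        profile, config.n_trials,
        stage_seed(config.master_seed, "simulate:online:" + group_label, subject_index),
        subject_id=subject_id, session_id=1)

    x_train, y_train = epochs.training_inputs(train_epochs, config.k)
    train_seed = int(np.random.default_rng(
        stage_seed(config.master_seed, "train:" + group_label, subject_index)
    ).integers(0, 2 ** 31))
    model = cnn.train(config.cnn_spec(train_seed), x_train, y_train)

    # trial-level decoding on the online session, full (k=20) averages
    decisions = []
    all_labels, all_truth, all_scores = [], [], []
    for trial in sorted({ep.trial_id for ep in online_epochs}):
        inputs, target = epochs.build_trial_inputs(online_epochs, trial,
                                                   k=N_REPETITIONS)
        dec = decoder.decide_trial(model, inputs, target, trial_id=trial)
        decisions.append(dec)
        all_labels.extend(dec.labels)
        all_scores.extend(dec.target_scores)
        all_truth.extend(icon == target for icon in range(len(dec.labels)))

    counts = metrics.ConfusionCounts.from_labels(all_labels, all_truth)
    det = decoder.detection_rate(decisions)

    grand_avg = epochs.grand_average_target(train_epochs + online_epochs)
    l1_maps = featuremaps.extract_maps(model, grand_avg, "L1")
    l2_maps = featuremaps.extract_maps(model, grand_avg, "L2")

    sens = metrics.sensitivity(counts)
    prec = metrics.precision(counts)
    summary = metrics.SubjectMetrics(
        subject_id=subject_id,
        group_label=group_label,
        group=metrics.assign_group(det),
        detection_rate=det,
        accuracy=metrics.trial_accuracy(decisions),
        sensitivity=sens,
        precision=prec,
        f1=metrics.f1_measure(sens, prec),
        auc=metrics.roc_auc(all_scores, all_truth),
        psnr_db=featuremaps.subject_psnr(l1_maps),
        pet_s=featuremaps.peak_time(l2_maps),
    )
    return SubjectRun(profile=profile, model=model, decisions=decisions,
                      counts=counts, l1_maps=l1_maps, l2_maps=l2_maps,
                      summary=summary)


def metrics_frame(runs: list[SubjectRun]) -> pd.DataFrame:
    """Cohort report table, one row per subject (3-decimal rounding)."""
    rows = []
    for run in runs:
        s = run.summary
        rows.append({
            "subject": s.subject_id, "phenotype": s.group_label,
            "group": s.group, "detection_rate": metrics.round3(s.detection_rate),
            "accuracy": metrics.round3(s.accuracy),
            "sensitivity": metrics.round3(s.sensitivity),
            "precision": metrics.round3(s.precision),
            "f1": metrics.round3(s.f1), "auc": metrics.round3(s.auc),
            "psnr_db": metrics.round3(s.psnr_db),
            "pet_s": metrics.round3(s.pet_s),
            "dominant_latency_s": metrics.round3(
                synthetic.dominant_latency(run.profile)),
        })
    return pd.DataFrame(rows)


def group_anova(frame: pd.DataFrame, column: str,
                by: str = "phenotype") -> tuple[float, float]:
    """One-way ANOVA of a metric between the two groups in ``by``."""
    groups = [g[column].dropna().to_numpy() for _, g in frame.groupby(by)]
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups in {by!r}")
    return metrics.anova_oneway(*groups)


def run_experiment(config: RunConfig, progress: bool = False):
    """Run the full synthetic cohort; returns (metrics frame, subject runs).

    With ``config.out_dir`` set, writes ``metrics.csv``, ``decisions.csv``
    and ``anova.csv`` there, each preceded by a provenance comment line
    (config as JSON).
    """
    runs: list[SubjectRun] = []
    for group, count in ((synthetic.GROUP_H, config.n_h),
                         (synthetic.GROUP_L, config.n_l)):
        for i in range(count):
            run = run_subject(group, i, config)
            runs.append(run)
            if progress:
                s = run.summary
                print(f"  {s.subject_id}: acc={s.accuracy:.3f} "
                      f"auc={s.auc:.3f} det={s.detection_rate:.2f} "
                      f"group={s.group} PeT={s.pet_s:.3f}s", flush=True)

    frame = metrics_frame(runs)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        prov = "# config: " + json.dumps(
            {k: v for k, v in vars(config).items() if k != "out_dir"}) + "\n"

        def write(df: pd.DataFrame, name: str) -> None:
            with open(out / name, "w") as fh:
                fh.write(prov)
                df.to_csv(fh, index=False)

        write(frame, "metrics.csv")
        dec_rows = []
        for run in runs:
            for d in run.decisions:
                row = {"subject": run.summary.subject_id, "trial": d.trial_id,
                       "true_target": d.true_target,
                       "selected_icon": d.selected_icon, "rule": d.rule_used,
                       "erp_detected": d.erp_detected}
                row.update({f"score_icon{i}": round(s, 6)
                            for i, s in enumerate(d.target_scores)})
                dec_rows.append(row)
        write(pd.DataFrame(dec_rows), "decisions.csv")
        anova_rows = []
        for col in ("accuracy", "auc", "sensitivity", "precision", "f1",
                    "psnr_db", "pet_s"):
            try:
                f_stat, p_val = group_anova(frame, col)
            except ValueError:   # a group smaller than 2 after NaN removal
                f_stat, p_val = float("nan"), float("nan")
            anova_rows.append({"metric": col, "F": f_stat, "p": p_val})
        write(pd.DataFrame(anova_rows), "anova.csv")
    return frame, runs
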