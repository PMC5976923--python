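"""Train one CNN per demo subject and decode the online sessions.

Reads the epoch tables written by ``01_simulate_cohort.py`` (session 0 for
training, session 1 for decoding), fits the desk-profile network (2000 Adam
steps) on k=5 sub-averages, then decodes each online trial from its k=20
per-icon averages with the tie-breaking rules.  Writes
``results/decisions.csv`` and ``results/subject_metrics.csv`` and stores
model checkpoints under ``scratch/demo_cohort/``.

Run after 01:  python analysis/02_train_decode.py
"""

from pathlib import Path

import pandas as pd

from erpspeller import cnn, decoder, epochs, featuremaps, metrics, synthetic
from erpspeller.montage import N_REPETITIONS

MASTER_SEED = 20
DATA = Path("scratch/demo_cohort")
RESULTS = Path("results")
K_TRAIN = 5


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    tables = sorted(DATA.glob("*_session0.tsv"))
    if not tables:
        raise SystemExit("no epoch tables found - run 01_simulate_cohort.py first")
    decision_rows, metric_rows = [], []
    for table in tables:
        tag = table.name.split("_")[0]
        train_eps = synthetic.read_epoch_table(table)
        online_eps = synthetic.read_epoch_table(DATA / f"{tag}_session1.tsv")

        x, y = epochs.training_inputs(train_eps, K_TRAIN)
        model = cnn.train(cnn.desk_spec(seed=MASTER_SEED), x, y)
        cnn.save_checkpoint(model, DATA / f"{tag}.ckpt")

        decisions, labels, truth, scores = [], [], [], []
        for trial in sorted({ep.trial_id for ep in online_eps}):
            inputs, target = epochs.build_trial_inputs(online_eps, trial,
                                                       k=N_REPETITIONS)
            d = decoder.decide_trial(model, inputs, target, trial_id=trial)
            decisions.append(d)
            labels.extend(d.labels)
            scores.extend(d.target_scores)
            truth.extend(i == target for i in range(6))
            decision_rows.append({
                "subject": tag, "trial": trial, "true_target": d.true_target,
                "selected_icon": d.selected_icon, "rule": d.rule_used,
                "erp_detected": d.erp_detected,
                **{f"score_icon{i}": round(s, 5)
                   for i, s in enumerate(d.target_scores)}})

        counts = metrics.ConfusionCounts.from_labels(labels, truth)
        det = decoder.detection_rate(decisions)
        ga = epochs.grand_average_target(train_eps + online_eps)
        sens, prec = metrics.sensitivity(counts), metrics.precision(counts)
        row = {
            "subject": tag,
            "group": metrics.assign_group(det),
            "detection_rate": metrics.round3(det),
            "accuracy": metrics.round3(metrics.trial_accuracy(decisions)),
            "sensitivity": metrics.round3(sens),
            "precision": metrics.round3(prec),
            "f1": metrics.round3(metrics.f1_measure(sens, prec)),
            "auc": metrics.round3(metrics.roc_auc(scores, truth)),
            "psnr_db": metrics.round3(featuremaps.subject_psnr(
                featuremaps.extract_maps(model, ga, "L1"))),
            "pet_s": metrics.round3(featuremaps.peak_time(
                featuremaps.extract_maps(model, ga, "L2"))),
        }
        metric_rows.append(row)
        print(f"{tag}: detection={row['detection_rate']} -> group "
              f"{row['group']}, accuracy={row['accuracy']}, "
              f"AUC={row['auc']}, PeT={row['pet_s']} s")

    pd.DataFrame(decision_rows).to_csv(RESULTS / "decisions.csv", index=False)
    pd.DataFrame(metric_rows).to_csv(RESULTS / "subject_metrics.csv", index=False)
    print(f"\nwrote {RESULTS/'decisions.csv'} and {RESULTS/'subject_metrics.csv'}")


if __name__ == "__main__":
    main()
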