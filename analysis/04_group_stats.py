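"""Group-level statistics: worked metric identities on the published cohort
and ANOVA on a simulated cohort.

Part 1 re-derives F1 from the published per-subject sensitivity/precision
pairs and checks the H/L split of the 33-subject reported cohort (19 H).
Part 2 loads ``results/subject_metrics.csv`` from script 02 and, when both
phenotypes have at least two subjects, runs the one-way ANOVA comparisons.
Writes ``results/f1_identity.csv`` and ``results/group_anova.csv``.

Run after 02 (part 1 works standalone):  python analysis/04_group_stats.py
"""

from pathlib import Path

import pandas as pd

from erpspeller import metrics

RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    reported = metrics.load_reported_cohort()
    reported["f1_recomputed"] = [
        metrics.round3(metrics.f1_measure(s, p))
        for s, p in zip(reported["sensitivity"], reported["precision"])]
    reported["f1_abs_diff"] = (reported["f1"] - reported["f1_recomputed"]).abs().round(3)
    reported.to_csv(RESULTS / "f1_identity.csv", index=False)
    consistent = int((reported["f1_abs_diff"] <= 0.001).sum())
    n_h = int((reported["group"] == "H").sum())
    print(f"published cohort: {n_h} of {len(reported)} subjects in the H group")
    print(f"F1 recomputed from sensitivity/precision matches the printed "
          f"value within 0.001 for {consistent}/{len(reported)} subjects "
          f"(the printed inputs are themselves 3-decimal roundings)")

    sim_path = RESULTS / "subject_metrics.csv"
    if not sim_path.exists():
        print("\nno simulated metrics yet - run 02_train_decode.py for part 2")
        return
    sim = pd.read_csv(sim_path)
    sim["phenotype"] = sim["subject"].str[0].map({"H": "H-like", "L": "L-like"})
    rows = []
    print("\nsimulated cohort group comparison (phenotype means):")
    for col in ("accuracy", "auc", "sensitivity", "precision", "psnr_db", "pet_s"):
        means = sim.groupby("phenotype")[col].mean()
        try:
            f, p = metrics.anova_oneway(
                sim.loc[sim.phenotype == "H-like", col].dropna(),
                sim.loc[sim.phenotype == "L-like", col].dropna())
        except ValueError:
            f, p = float("nan"), float("nan")
        rows.append({"metric": col,
                     "mean_H_like": round(means.get("H-like", float("nan")), 3),
                     "mean_L_like": round(means.get("L-like", float("nan")), 3),
                     "F": round(f, 3), "p": round(p, 4)})
        print(f"  {col:>11}: H-like {rows[-1]['mean_H_like']} vs "
              f"L-like {rows[-1]['mean_L_like']} (F={rows[-1]['F']}, "
              f"p={rows[-1]['p']})")
    pd.DataFrame(rows).to_csv(RESULTS / "group_anova.csv", index=False)
    print(f"wrote {RESULTS/'group_anova.csv'}")


if __name__ == "__main__":
    main()
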