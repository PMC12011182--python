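"""Screen PAL and single-gene biomarkers against survival.

For every (biomarker, endpoint) pair: optimal log-rank cutpoint, Cox hazard
ratio with 95% CI and stars, plus the OS/PFS-averaged summary row and the
selection-corrected cutpoint p.  Clusters the endpoint HR profiles and
writes the verdict table, heatmap and dendrogram under results/survival/.

Run after 03_score_pal.py.
"""

import json
from pathlib import Path

import pandas as pd

from palscreen import io as pio
from palscreen.survival_stats import biomarker_screen, cluster_hr_profiles

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"


def main() -> None:
    pal = pd.read_csv(ROOT / "results" / "pal.tsv", sep="\t", index_col=0)
    clinical = pio.read_clinical(DATA / "clinical.csv")
    truth = json.loads((DATA / "ground_truth.json").read_text())

    out = ROOT / "results" / "survival"
    out.mkdir(parents=True, exist_ok=True)
    table = biomarker_screen(pal, clinical)
    table.to_csv(out / "verdicts.tsv", sep="\t", index=False)

    cells = table[table["endpoint"].isin(clinical)]
    print("per-cell verdicts (naive minimum-p stars):")
    for _, row in cells.iterrows():
        print(
            f"  {row['biomarker']:<14} {row['endpoint']:<4} HR {row['hr']:.2f} "
            f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}] {row['stars']:<3} "
            f"corrected p {row['p_logrank_adj']:.3f} -> {row['direction']}"
        )
    summary = table[table["endpoint"] == "OS+PFS_mean"]
    flagged = summary[summary["flagged"].astype(bool)]
    print("biomarker-level flags (consistent direction, corrected p < 0.05 on both endpoints):")
    for _, row in flagged.iterrows():
        print(f"  {row['biomarker']}: {row['direction']} (mean HR {row['hr']:.2f})")
    central = truth["central_gene"]
    verdict = "recovered" if central in set(flagged["biomarker"]) else "NOT recovered"
    print(f"ground-truth pathway {central}: {verdict}")

    hr = cells.pivot_table(index="endpoint", columns="biomarker", values="hr", dropna=False)
    if hr.shape[0] >= 2:
        order, labels, _ = cluster_hr_profiles(hr)
        print(f"HR-profile clustering: leaf order {order}, labels {labels.to_dict()}")


if __name__ == "__main__":
    main()
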