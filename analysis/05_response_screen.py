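"""Compare pathway activation between RECIST response groups.

Applies the cohort inclusion rules (therapy groups of >= 20 patients, lines
1-3, best response, response groups of >= 3), then runs the normality-driven
decision tree per pathway and reports group medians and the direction of any
significant effect.  The report goes to results/response_report.tsv.

Run after 03_score_pal.py.
"""

from pathlib import Path

import pandas as pd

from palscreen.response_stats import filter_response_cohort, response_effect_screen

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"


def main() -> None:
    pal = pd.read_csv(ROOT / "results" / "pal.tsv", sep="\t", index_col=0)
    response = pd.read_csv(DATA / "response.csv")

    groups = filter_response_cohort(response)
    print(f"response cohort after filtering: {groups.counts()}")
    for item, rule, detail in groups.exclusions:
        print(f"  excluded [{rule}] {item}: {detail}")
    if groups.empty:
        print("nothing to test")
        return

    report = response_effect_screen(pal, groups)
    report.to_csv(ROOT / "results" / "response_report.tsv", sep="\t", index=False)
    for _, row in report.iterrows():
        direction = row["direction"] or "no significant direction"
        print(
            f"  {row['pathway']:<14} {row['test']:<18} p {row['p']:.4f}  "
            f"medians R {row['median_R']:+.1f} / NR {row['median_NR']:+.1f} -> {direction}"
        )


if __name__ == "__main__":
    main()
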