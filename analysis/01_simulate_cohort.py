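"""Generate the synthetic study cohort.

Writes the pathway collection (one genecentric star pathway with a known
activator/repressor composition plus decoy pathways), a negative-binomial
expression matrix whose "activated" sample stratum carries a 2-log2-unit
shift on the true pathway's members, clinical OS/PFS follow-up with a
2-fold hazard for activated samples, RECIST response labels, and the
ground truth, under results/data/.

Run:  python analysis/01_simulate_cohort.py [--seed 1]
"""

import argparse
from pathlib import Path

import numpy as np

from palscreen import io as pio
from palscreen.synthetic_data import (
    SimulationConfig,
    simulate_clinical,
    simulate_expression_cohort,
    simulate_pathway_collection,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    config = SimulationConfig(seed=args.seed, pal_effect_logfc=2.0, survival_beta=float(np.log(2)))
    out = ROOT / "results" / "data"
    out.mkdir(parents=True, exist_ok=True)

    collection, truth = simulate_pathway_collection(config)
    matrix, activated = simulate_expression_cohort(config, truth)
    clinical, response = simulate_clinical(config, activated)

    pio.write_pathway_collection(collection, out / "pathways.tsv")
    pio.write_expression(matrix, out / "expression.tsv")
    pio.write_clinical(clinical, out / "clinical.csv")
    response.to_csv(out / "response.csv", index=False)
    pio.write_ground_truth(
        {
            "arr": truth,
            "activated": {s: bool(v) for s, v in activated.items()},
            "central_gene": config.central_gene,
            "n_decoy_pathways": config.n_decoy_pathways,
            "seed": config.seed,
        },
        out / "ground_truth.json",
    )
    n_act = int(activated.sum())
    print(f"cohort: {matrix.shape[0]} genes x {matrix.shape[1]} samples ({n_act} activated)")
    print(f"pathways: {len(collection)} ({config.n_pathway_members} members each); written to {out}")


if __name__ == "__main__":
    main()
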