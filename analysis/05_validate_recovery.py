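#!/usr/bin/env python
"""Score the pipeline against the generator's ground truth.

Computes linkage precision/recall against the identity labels, attributes
every false match to its cause in the event log, and measures per-species
growth-rate bias and RMSE over the correctly matched retained trees.
"""

import json
from pathlib import Path


ROOT = Path(__file__).resolve().parents[1]

from treegrowth.census import read_table
from treegrowth.synthetic import evaluate_linkage, evaluate_recovery

CITY = ROOT / "scratch" / "city"
RES = ROOT / "results"


def main() -> None:
    growth = read_table(CITY / "growth.csv")
    truth = read_table(CITY / "ground_truth.csv", low_memory=False)

    ev = evaluate_linkage(growth, truth)
    rec = evaluate_recovery(growth, truth)

    with open(RES / "linkage_evaluation.json", "w") as fh:
        json.dump(
            {
                "precision": ev.precision,
                "recall": ev.recall,
                "n_reported_pairs": ev.n_reported,
                "n_true_pairs": ev.n_true_pairs,
                "false_match_causes": ev.false_match_causes,
            },
            fh,
            indent=2,
        )
    rec.per_species.round(4).to_csv(RES / "recovery_by_species.csv", index=False)

    print(f"linkage precision {ev.precision:.3f}, recall {ev.recall:.3f} "
          f"({ev.n_reported} reported pairs)")
    print(f"false matches by cause: {ev.false_match_causes} "
          "(same-species replacement is the designed failure mode; the -5 in "
          "QC cutoff removes the large-swap cases downstream)")
    print(f"rate recovery over correct matches: bias {rec.overall_bias:+.4f}, "
          f"RMSE {rec.overall_rmse:.4f} in/yr")
    print(rec.per_species.head(5).round(3).to_string(index=False))


if __name__ == "__main__":
    main()
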