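#!/usr/bin/env python
"""Apply the WT/KO modulated-interactor filter to the simulated proximity
tables and score it against the planted truth.

Filter: probability-score change > 0.25 and pseudocounted spectral-count fold
change > 1.5 (or < 1/1.5 for lost), consistent in direction, in at least 2 of
3 cell lines.  Writes results/interactome_candidates.tsv.
"""

import json
from pathlib import Path

import pandas as pd

import coessence as ce

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = pd.read_csv(ROOT / "data" / "interactome.tsv", sep="\t")
    truth = set(json.loads((ROOT / "data" / "interactome_truth.json").read_text())["modulated_preys"])

    cand = ce.modulated_interactors(table, prob_delta_min=0.25, fc_min=1.5, min_lines=2)
    out = pd.DataFrame(
        [{"prey_gene": p, "direction": d} for p, d in sorted(cand.members.items())])
    out.to_csv(ROOT / "interactome_candidates.tsv", sep="\t", index=False)

    found = set(cand.preys)
    print(f"candidates ({len(found)}): {sorted(found)}")
    print(f"planted   ({len(truth)}): {sorted(truth)}")
    tp, fp, fn = len(found & truth), len(found - truth), len(truth - found)
    print(f"recall {tp}/{len(truth)}, false positives {fp}, misses {fn}")
    directions = set(cand.members.values())
    print(f"directions: {directions} (planted preys gain bait proximity in KO)")


if __name__ == "__main__":
    main()
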