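#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Emulates the three experiments: a pooled in-vivo CRISPR screen (6 genes x 83
guides + 500 non-targeting controls, 14 tumors plus a baseline pool) with one
planted co-essential gene pair and one essential gene; MST titrations for an
in-range binder, a weak out-of-range binder, and a non-binder; and WT/KO
proximity-interactome tables with 5 of 50 preys modulated.

Writes everything under results/data/.
"""

import json
import math
from pathlib import Path

import pandas as pd

import coessence as ce

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # --- pooled screen: planted co-essential pair + one essential gene -----
    cfg = ce.ScreenSimConfig(
        coessential_pairs=[("GENE01", "GENE02", 0.9)],
        gene_effects={"GENE05": -2.0},
        seed=SEED,
    )
    lib, counts, truth = ce.simulate_screen(cfg)
    lib.records.to_csv(OUT / "library.tsv", sep="\t", index=False)
    counts.to_tsv(OUT / "counts.tsv", OUT / "manifest.json")
    truth.realized_effects.rename_axis("gene").to_csv(OUT / "truth_effects.tsv", sep="\t")
    (OUT / "truth.json").write_text(json.dumps({
        "coessential_pairs": truth.coessential_pairs,
        "essential_genes": {"GENE05": -2.0},
        "seed": SEED,
    }, indent=1))
    print(f"screen: {counts.counts.shape[0]} guides x {counts.counts.shape[1]} samples; "
          f"planted pair GENE01-GENE02 (latent sd 0.9), essential GENE05 (effect -2)")

    # --- MST titrations ----------------------------------------------------
    mst_cases = {
        "binder_kd177": 177.0,      # SNARE-affinity regime
        "binder_kd34": 34.0,        # strong positive-control regime
        "out_of_range_kd5e5": 5e5,  # Kd at 100x the top concentration
        "nonbinder": math.inf,
    }
    for name, kd in mst_cases.items():
        series = ce.simulate_isotherm(kd, a0_nM=20.0, top_ligand_nM=5000.0,
                                      noise_sd=0.01, seed=SEED)
        pd.DataFrame({"concentration_nM": series.T0_values,
                      "response": series.responses}).to_csv(
            OUT / f"mst_{name}.tsv", sep="\t", index=False)
    (OUT / "mst_truth.json").write_text(json.dumps(
        {k: (None if math.isinf(v) else v) for k, v in mst_cases.items()}, indent=1))
    print(f"mst: {len(mst_cases)} titrations (16-point, 2-fold, A0 = 20 nM)")

    # --- WT/KO interactome tables ------------------------------------------
    table, modulated = ce.simulate_interactome(n_preys=50, modulated_preys=5, seed=SEED)
    table.to_csv(OUT / "interactome.tsv", sep="\t", index=False)
    (OUT / "interactome_truth.json").write_text(
        json.dumps({"modulated_preys": modulated}, indent=1))
    print(f"interactome: {len(table)} records over 3 lines; planted {modulated}")


if __name__ == "__main__":
    main()
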