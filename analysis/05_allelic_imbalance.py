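#!/usr/bin/env python
"""Chromatin allelic-imbalance analysis: 50-bp window consensus peaks,
per-individual overdispersion by copy-number decile, beta-binomial LRTs
per group, differential imbalance between ccRCC and pRCC, and the
group-specific classification; check recovery of planted imbalance.

Writes results/ai_peaks.tsv and results/rho_table.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from rcc_regulome import pipeline
from rcc_regulome.synthetic_data import SimConfig, simulate_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    bundle = simulate_cohort(SimConfig(seed=args.seed))
    ai_out = pipeline.run_allelic_imbalance(bundle)

    per_group = ai_out["per_group"]
    table = pd.DataFrame({
        "q_ccRCC": per_group["ccRCC"]["q_value"],
        "q_pRCC": per_group["pRCC"]["q_value"],
        "q_combined": per_group["combined"]["q_value"],
        "pi_ccRCC": ai_out["differential"]["pi_g1"],
        "pi_pRCC": ai_out["differential"]["pi_g2"],
        "diff_padj": ai_out["differential"]["diff_padj"],
        "label": ai_out["labels"],
    })
    table.to_csv(outdir / "ai_peaks.tsv", sep="\t")
    ai_out["rho_table"].to_csv(outdir / "rho_table.tsv", sep="\t")

    print(f"consensus peak universe: {len(ai_out['universe'])} regions "
          f"(50-bp windows, >= 2 samples)")
    for g in ("ccRCC", "pRCC", "combined"):
        n = int(per_group[g]["imbalanced"].sum())
        print(f"  {g}: {n} imbalanced peaks at q < 0.05 "
              f"of {len(per_group[g])} tested")
    print("  classification:", ai_out["labels"].value_counts().to_dict())

    rec = pipeline.ai_recovery(bundle, ai_out)
    print(f"planted-imbalance recall {rec['recall']:.3f} "
          f"(n = {rec['n_planted_imbalanced']}); balanced false-positive "
          f"rate {rec['false_positive_rate_balanced']:.3f}")


if __name__ == "__main__":
    main()
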