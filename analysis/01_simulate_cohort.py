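#!/usr/bin/env python
"""Generate the synthetic multi-histology RCC cohort and write every
artifact (peak calls, count matrix, expression, motifs, allelic counts,
GWAS catalog, truth labels) under results/cohort/.

All downstream analysis steps regenerate the same cohort from the seed,
so this step exists to materialize the artifacts in their standard
on-disk formats for inspection.
"""

import argparse

from rcc_regulome.synthetic_data import SimConfig, simulate_cohort, write_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/cohort")
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed)
    bundle = simulate_cohort(cfg)
    write_cohort(bundle, args.out)

    truth = bundle.truth
    print(f"cohort written to {args.out}")
    print(f"  samples: {len(bundle.sample_ids)} "
          f"({bundle.sample_labels.value_counts().to_dict()})")
    print(f"  peaks: {len(bundle.peak_table)} "
          f"({(truth.specific_peak_labels != 'common').sum()} histology-specific)")
    print(f"  TFs: {len(bundle.tf_list)} ({len(truth.master_tf_labels)} planted masters)")
    print(f"  SNP-bearing peaks: {len(truth.ai_peak_classes)} "
          f"({(truth.ai_peak_classes != 'balanced').sum()} imbalanced)")
    print(f"  GWAS SNPs: {len(bundle.gwas_catalog)} "
          f"({truth.gwas_snp_in_ai_peak.sum()} placed in imbalanced peaks)")


if __name__ == "__main__":
    main()
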