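#!/usr/bin/env python
"""Cross-species differential dendritic expression at the study design.

Simulates normalized log expression for two species at the real replicate
design (9 vs 14 arrays) with a planted 20% divergent fraction at a 2σ shift,
runs the per-gene Welch t-test with Benjamini–Hochberg control at
FDR q = 0.1%, and reports how much of the planted divergence that stringent
threshold recovers.

Writes results/divergence_table.tsv.
"""

import argparse
from pathlib import Path

from dendrodiv import divergence_stats as dvs
from dendrodiv import synthetic_data as sd


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-genes", type=int, default=5000)
    ap.add_argument("--fdr", type=float, default=0.001)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    spec = sd.ExpressionSimSpec(n_genes=args.n_genes, seed=args.seed)
    expr_a, expr_b, planted = sd.simulate_two_species_expression(spec)
    table = dvs.welch_ttest_table(expr_a, expr_b, q=args.fdr)
    flagged = set(table.index[table["q_flag"]])
    tp = len(flagged & planted)
    jaccard = tp / len(flagged | planted)

    print(f"genes: {args.n_genes}, replicates: {spec.n_reps_a} vs {spec.n_reps_b}")
    print(f"planted divergent: {len(planted)} "
          f"(fraction {spec.divergent_fraction}, shift {spec.effect_size} sigma)")
    print(f"flagged at FDR {args.fdr:g}: {len(flagged)} "
          f"({tp} true, {len(flagged) - tp} false)")
    print(f"Jaccard overlap with planted set: {jaccard:.3f}")
    print("note: at delta = 2 sigma with 9 vs 14 replicates the per-gene power "
          "at this threshold is ~0.4, so the flagged set is conservative")

    out = args.outdir / "divergence_table.tsv"
    table.to_csv(out, sep="\t", index_label="metagene_id")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
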