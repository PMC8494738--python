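#!/usr/bin/env python
"""Generate the synthetic 14-tissue cohort and write its raw inputs.

Produces per-tissue segmentation BEDs, the gene expression matrix, GWAS and
FST tables, and the two-species orthology setting, with the planted truth
serialized next to them.  Raw data goes under scratch/sim/ (it is
regenerated on demand); a one-row-per-tissue summary goes to results/.
"""

import argparse
import os

import pandas as pd

from chromdyn.io import write_segmentation
from chromdyn.simulate import (
    SimulationConfig,
    simulate_enhancer_signal_and_loops,
    simulate_expression,
    simulate_gwas_and_fst,
    simulate_orthology_pair,
    simulate_segmentations,
)

ROOT = os.path.join(os.path.dirname(__file__), "..")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    outdir = os.path.join(ROOT, "scratch", "sim")
    os.makedirs(os.path.join(outdir, "segmentations"), exist_ok=True)

    segs, truth, genes = simulate_segmentations(cfg)
    for t, seg in segs.items():
        write_segmentation(seg, os.path.join(outdir, "segmentations", f"{t}.bed"))
    genes.genes.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False)

    expr = simulate_expression(cfg, truth, genes)
    expr.tpm.to_csv(os.path.join(outdir, "expression_tpm.tsv"), sep="\t")

    signal, motif_df, _ = simulate_enhancer_signal_and_loops(cfg, truth, expr, genes)
    signal.to_csv(os.path.join(outdir, "enhancer_signal.tsv"), sep="\t")
    motif_df.to_csv(os.path.join(outdir, "ctcf_motifs.tsv"), sep="\t", index=False)

    snps, fst_windows, freqs = simulate_gwas_and_fst(cfg, truth)
    snps.to_csv(os.path.join(outdir, "gwas_snps.tsv"), sep="\t", index=False)
    fst_windows.to_csv(os.path.join(outdir, "fst_windows.tsv"), sep="\t", index=False)
    freqs.to_csv(os.path.join(outdir, "allele_freqs.tsv"), sep="\t", index=False)

    src, tgt, omap, track, otruth = simulate_orthology_pair(cfg)
    write_segmentation(src, os.path.join(outdir, "source_species.bed"))
    write_segmentation(tgt, os.path.join(outdir, "target_species.bed"))
    omap.write(os.path.join(outdir, "orthology_map.tsv"))
    track.to_csv(os.path.join(outdir, "conservation_track.bedgraph"),
                 sep="\t", index=False, header=False)
    truth.write(os.path.join(outdir, "truth"))
    otruth.write(os.path.join(outdir, "truth_orthology"))

    summary = pd.DataFrame(
        {
            "tissue": list(segs),
            "n_intervals": [len(s.intervals) for s in segs.values()],
            "enhancer_bp": [
                int(s.state_coverage()["EnhA"]) for s in segs.values()
            ],
            "quiescent_fraction": [
                s.state_coverage()["Qui"] / s.assembly.total_length for s in segs.values()
            ],
        }
    )
    os.makedirs(os.path.join(ROOT, "results"), exist_ok=True)
    summary.to_csv(os.path.join(ROOT, "results", "01_cohort_summary.tsv"),
                   sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nplanted elements: {len(truth.elements)}; "
          f"TSE genes: {sum(len(v) for v in truth.tse_genes.values())}; "
          f"links: {len(truth.links)}")
    print("raw inputs under scratch/sim/, summary in results/01_cohort_summary.tsv")


if __name__ == "__main__":
    main()
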