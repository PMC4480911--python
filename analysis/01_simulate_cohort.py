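#!/usr/bin/env python
"""Generate the study cohorts used by the downstream analysis scripts.

Writes two synthetic cohorts under results/data/:

* ``four_types`` — split-thickness grafts (SG), early- and late-passage
  keratinocytes (EKC, LKC) and the HaCaT line, 2 donors x 3 technical
  replicates per type, with per-type polyA+ content EKC(2.0) > LKC = HaCaT
  (1.4) > SG(1.0) and planted type-specific expression programs.
* ``outlier_demo`` — the two-group SG/EKC design with one EKC replicate whose
  endogenous counts are inflated 5x (a content outlier), spikes untouched.
"""

from pathlib import Path

from spikeflow import write_counts, write_gmt, write_metadata
from spikeflow.simulate import preset, simulate, truth_gene_sets

OUT = Path("results/data")


def main() -> None:
    for name in ("four_types", "outlier_demo"):
        outdir = OUT / name
        outdir.mkdir(parents=True, exist_ok=True)
        matrix, meta, truth = simulate(preset(name))
        write_counts(matrix, outdir / "counts.tsv")
        write_metadata(meta, outdir / "meta.tsv")
        truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        truth.samples.to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)
        if name == "four_types":
            write_gmt(truth_gene_sets(truth, seed=0), outdir / "truth_sets.gmt")
        print(
            f"{name}: {matrix.n_genes} features ({int(matrix.is_spike.sum())} spike-ins) "
            f"x {matrix.n_samples} samples -> {outdir}"
        )


if __name__ == "__main__":
    main()
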