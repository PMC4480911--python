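#!/usr/bin/env python
"""Contrast spike-in-based against endogenous (total-count) normalization.

Finding: with a real 2x difference in polyA+ content between EKC and SG,
total-count normalization makes the truly constant spike-ins appear ~2-fold
downregulated (median fold ~0.5), while spike-in normalization keeps them at
fold ~1 and instead exposes the genuine global upregulation of endogenous
genes.
"""

from dataclasses import replace
from pathlib import Path

import pandas as pd

from spikeflow import normalize
from spikeflow.simulate import preset, simulate

OUT = Path("results/normalization")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix, meta, _ = simulate(replace(preset("sg_vs_ekc"), de_fraction=0.0))
    types = meta.set_index("sample_id")["sample_type"]
    ekc = types[types == "EKC"].index
    sg = types[types == "SG"].index

    rows = []
    for mode in ("endogenous", "spike"):
        norm = normalize(matrix, mode)
        for feature, mask in (("spike-in", matrix.is_spike), ("endogenous", ~matrix.is_spike)):
            sub = norm.loc[mask]
            fold = (sub[ekc].mean(axis=1) / sub[sg].mean(axis=1)).median()
            rows.append({"norm_mode": mode, "feature_class": feature,
                         "median_fold_ekc_vs_sg": round(float(fold), 4)})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "fold_contrast.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print("\nspike-in normalization keeps spikes at fold ~1 and shows the real "
          "~2x endogenous shift; total-count normalization does the opposite.")


if __name__ == "__main__":
    main()
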