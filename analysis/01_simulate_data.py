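#!/usr/bin/env python
"""Generate the synthetic study datasets.

Writes the default benchmark (166 planted proprioceptor-like cells in
proportions 51/31/28/28/28 plus 10 low-depth and 8 satellite-contaminated
cells) as MatrixMarket + sidecars with its planted truth, and a
four-stage developmental time course in which adult marker co-expression
decays toward earlier stages.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import scproprio as sp
from scproprio import io as sio

STAGES = ["e14", "p0", "p12", "adult"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    counts, truth = sp.simulate_counts(sp.SyntheticSpec(seed=args.seed))
    sio.write_counts(counts, args.out / "benchmark", dialect="mtx")
    sio.write_truth(truth, args.out / "benchmark" / "truth.json")
    print(
        f"benchmark: {counts.n_genes} genes x {counts.n_cells} cells "
        f"({len(truth.flagged_lowdepth)} low-depth, "
        f"{len(truth.flagged_contaminant)} contaminated) -> {args.out / 'benchmark'}"
    )

    base = sp.SyntheticSpec(
        n_genes=1000, cluster_sizes=(60, 60), marker_genes_per_cluster=15,
        n_lowdepth_cells=0, n_contaminant_cells=0,
    )
    specs = [replace(base, seed=args.seed + 100 + i) for i in range(len(STAGES))]
    stages = sp.simulate_timecourse(specs, coexpression_decay=0.5, stage_names=STAGES)
    for (matrix, struth), name in zip(stages, STAGES):
        sio.write_counts(matrix, args.out / f"stage_{name}", dialect="mtx")
        sio.write_truth(struth, args.out / f"stage_{name}" / "truth.json")
    print(f"time course: {len(STAGES)} stages (decay 0.5) -> {args.out}/stage_*")


if __name__ == "__main__":
    main()
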