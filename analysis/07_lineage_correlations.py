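#!/usr/bin/env python
"""Developmental gene-gene correlation panels.

For the adult marker genes, computes the pairwise Pearson correlation of
log(CPM+1) at each developmental stage, ordered by average-linkage
clustering of the adult matrix, and reports the per-stage mean
within-module |r| (expected to rise toward the adult stage).
"""

import argparse
import json
from pathlib import Path

import scproprio as sp
from scproprio import io as sio
from scproprio.qc import cpm_normalize

STAGES = ["e14", "p0", "p12", "adult"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/lineage"))
    ap.add_argument("--heatmaps", action="store_true", help="also write PNG heatmaps")
    args = ap.parse_args()

    datasets, truths = {}, {}
    for name in STAGES:
        d = args.data / f"stage_{name}"
        datasets[name] = cpm_normalize(sio.read_counts(d))
        truths[name] = sio.read_truth(d / "truth.json")

    adult = truths["adult"]
    genes = [g for v in adult.marker_map.values() for g in v]
    panel = sp.build_panel(
        datasets, genes, "adult", stage_order=STAGES,
        scoring_groups=list(adult.marker_map.values()),
    )

    args.out.mkdir(parents=True, exist_ok=True)
    for stage, mat in panel.matrices.items():
        mat.to_csv(args.out / f"correlation_{stage}.tsv", sep="\t")
    manifest = {
        "stages": panel.stages,
        "reference_stage": panel.reference_stage,
        "gene_order": panel.gene_order,
        "mean_abs_within_module_r": panel.summary.round(4).to_dict(),
    }
    (args.out / "panel.json").write_text(json.dumps(manifest, indent=2))

    if args.heatmaps:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(STAGES), figsize=(4 * len(STAGES), 4))
        for ax, stage in zip(axes, STAGES):
            im = ax.imshow(panel.matrices[stage], vmin=-1, vmax=1, cmap="RdBu_r")
            ax.set_title(stage)
            ax.set_xticks([])
            ax.set_yticks([])
        fig.colorbar(im, ax=axes, shrink=0.8, label="Pearson r")
        fig.savefig(args.out / "panel.png", dpi=150)

    trend = " < ".join(f"{panel.summary[s]:.3f} ({s})" for s in STAGES)
    print(f"mean within-module |r| by stage: {trend}")


if __name__ == "__main__":
    main()
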