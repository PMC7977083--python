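#!/usr/bin/env python
"""Gene-set enrichment of the selected markers (classic + elim Fisher).

No ontology ships with the package, so this driver builds a synthetic
two-level gene-set hierarchy from the planted marker modules (each
cluster's marker set, plus parent sets pooling pairs of them and random
background sets) and tests the selected marker list against it. With
real data, supply a GMT file and a child/parent table instead.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import scproprio as sp
from scproprio import io as sio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--filtered", type=Path, default=Path("results/qc/filtered"))
    ap.add_argument("--markers", type=Path, default=Path("results/markers/markers.tsv"))
    ap.add_argument("--truth", type=Path, default=Path("results/data/benchmark/truth.json"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/enrichment"))
    args = ap.parse_args()

    counts = sio.read_counts(args.filtered)
    truth = sio.read_truth(args.truth)
    study = pd.read_csv(args.markers, sep="\t", index_col=0).index.tolist()

    # synthetic hierarchy: leaf sets = planted marker modules; parents pool pairs
    rng = np.random.default_rng(args.seed)
    universe = list(counts.gene_ids)
    sets: dict[str, list[str]] = {}
    parents: dict[str, list[str]] = {}
    clusters = sorted(truth.marker_map)
    for cid in clusters:
        sets[f"module_{cid}"] = list(truth.marker_map[cid])
    for a, b in zip(clusters[::2], clusters[1::2]):
        pname = f"module_{a}_{b}_parent"
        sets[pname] = list(truth.marker_map[a]) + list(truth.marker_map[b])
        parents[f"module_{a}"] = [pname]
        parents[f"module_{b}"] = [pname]
    for i in range(5):
        sets[f"background_{i}"] = [
            universe[j] for j in rng.choice(len(universe), 30, replace=False)
        ]
    coll = sp.GeneSetCollection(sets, universe, parents)

    classic = sp.enrich_classic(study, coll)
    elim = sp.enrich_elim(study, coll)
    merged = classic.table[["overlap", "p_classic", "adj_p_classic"]].join(
        elim.table[["overlap_elim", "p_elim", "adj_p_elim", "passes_filters"]]
    )
    args.out.mkdir(parents=True, exist_ok=True)
    merged.to_csv(args.out / "enrichment.tsv", sep="\t")
    sio.write_gmt(sets, args.out / "gene_sets.gmt")

    sig = merged[merged["passes_filters"].fillna(False)]
    print(f"{len(sig)}/{len(merged)} sets pass all filters: {sorted(sig.index)}")


if __name__ == "__main__":
    main()
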