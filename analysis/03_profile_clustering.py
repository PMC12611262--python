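#!/usr/bin/env python
"""Cluster and project the genome-wide compartment profiles.

Reads the called compartment tracks, assembles the cell-type x bin profile,
computes the 1 - Pearson distance matrix, Ward dendrogram, PCA scores and
loadings, and the top-100 positive/negative PC1 bins with their genes.
Writes the tables under results/profile/.
"""

import json
from pathlib import Path

import pandas as pd

from oto import io_formats as io
from oto.genome import BinIndex
from oto.profiles import (
    assemble_profile,
    bins_to_genes,
    pearson_distance,
    profile_pca,
    top_loading_bins,
    ward_cluster,
)

ROOT = Path(__file__).resolve().parents[1]
CALLS = ROOT / "scratch" / "calls"
RESULTS = ROOT / "results"
OUT = RESULTS / "profile"


def genome_bins(manifest) -> list[BinIndex]:
    bins = []
    cfg = manifest["config"]
    per_chrom = manifest["n_bins"] // manifest["n_chromosomes"]
    i = 0
    for c in range(manifest["n_chromosomes"]):
        for j in range(per_chrom):
            bins.append(
                BinIndex(
                    f"chr{c + 1}",
                    j * cfg["bin_size"],
                    (j + 1) * cfg["bin_size"],
                    i,
                )
            )
            i += 1
    return bins


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = json.loads((RESULTS / "data" / "truth_manifest.json").read_text())
    names = [ct["name"] for ct in manifest["cell_types"]]
    bins = genome_bins(manifest)
    tracks = {
        name: io.read_bedgraph_track(CALLS / f"{name}.track.bedGraph", bins)
        for name in names
    }
    profile = assemble_profile(tracks)
    print(f"profile: {len(names)} cell types x {profile.values.shape[1]} bins "
          f"({profile.n_dropped} masked bins dropped)")

    distance = pearson_distance(profile)
    pd.DataFrame(distance, index=names, columns=names).to_csv(
        OUT / "pearson_distance.tsv", sep="\t", float_format="%.6g"
    )
    linkage, leaves = ward_cluster(distance)
    pd.DataFrame(
        linkage, columns=["left", "right", "height", "size"]
    ).to_csv(OUT / "ward_merges.tsv", sep="\t", index=False, float_format="%.6g")
    print("dendrogram leaf order:", " | ".join(names[i] for i in leaves))

    pca = profile_pca(profile, n_components=3)
    pd.DataFrame(
        pca.scores, index=names, columns=["PC1", "PC2", "PC3"]
    ).to_csv(OUT / "pca_scores.tsv", sep="\t", float_format="%.6g")
    pd.DataFrame(
        pca.loadings, index=profile.feature_ids, columns=["PC1", "PC2", "PC3"]
    ).to_csv(OUT / "pca_loadings.tsv", sep="\t", float_format="%.6g")
    print(
        "explained variance:",
        ", ".join(f"PC{i + 1} {v:.1%}" for i, v in enumerate(pca.explained_variance_ratio)),
    )

    emt = {ct["name"]: ct["emt_parameter"] for ct in manifest["cell_types"]}
    scores = pd.Series(pca.scores[:, 0], index=names)
    print("PC1 ordering vs planted EMT parameter:")
    for name in scores.sort_values().index:
        print(f"  {name:<16} PC1 {scores[name]:+.3f}  emt {emt[name]:.2f}")

    selection = top_loading_bins(pca, profile, component=0, k=100)
    genes = io.read_bed_genes(RESULTS / "data" / "genes.bed")
    for side, feats in (
        ("positive", selection.positive_features),
        ("negative", selection.negative_features),
    ):
        with open(OUT / f"pc1_top100_{side}_bins.bed", "w") as fh:
            for i in feats:
                b = bins[i]
                fh.write(f"{b.chromosome}\t{b.start}\t{b.end}\tPC1_{side}\n")
        gene_list = bins_to_genes(feats, genes, bins)
        (OUT / f"pc1_top100_{side}_genes.txt").write_text("\n".join(gene_list) + "\n")
        print(f"PC1 {side}: 100 bins -> {len(gene_list)} genes")


if __name__ == "__main__":
    main()
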