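#!/usr/bin/env python
"""Generate the synthetic study system and write it to disk.

A three-chromosome genome (400 x 250 kb bins each) for a panel of eleven
cell types: breast normal epithelium, localized and lung-metastatic breast
cancer lines spanning a planted EMT gradient, lung and brain (decoy organ)
normals with their localized cancers. Writes dense contact matrices and
truth tracks under scratch/data/ (large, regenerable) and the gene
annotation, gene sets, expression table and truth manifest under
results/data/.
"""

import json
from pathlib import Path

from oto import io_formats as io
from oto.containers import CompartmentTrack, StateTrack
from oto.synthetic import (
    SimulationConfig,
    simulate_contact_matrix,
    simulate_expression,
    simulate_genes,
    substream,
)
from oto.workflows import simulate_genome

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "data"
RESULTS = ROOT / "results" / "data"
N_CHROMOSOMES = 3

CONFIG = SimulationConfig(seed=0, include_decoy_organ=True)


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    genome, panels = simulate_genome(CONFIG, N_CHROMOSOMES)

    n_matrices = 0
    for panel in panels:
        chrom = panel.bins[0].chromosome
        for ct in panel.cell_types:
            rng = substream(CONFIG.seed, chrom, "contacts", ct.name)
            matrix = simulate_contact_matrix(
                StateTrack.from_signs(ct.states, panel.bins), CONFIG, rng
            )
            io.write_dense_matrix(matrix, SCRATCH / f"{ct.name}.{chrom}.matrix.txt")
            n_matrices += 1
    for ct in genome.cell_types:
        # planted truth as a +-1 bedGraph; downstream scripts use it both as
        # orientation covariate and as the accuracy reference
        truth = CompartmentTrack(
            ct.states.astype(float), genome.bins, oriented=True, orientation_r=1.0
        )
        io.write_bedgraph_track(truth, SCRATCH / f"{ct.name}.truth.bedGraph")

    genes, sets, gene_truth = simulate_genes(genome, CONFIG)
    io.write_bed_genes(genes, RESULTS / "genes.bed")
    io.write_gmt(sets, RESULTS / "emt_sets.gmt")
    expression = simulate_expression(genome, genes, sets, CONFIG)
    io.write_expression_tsv(expression, RESULTS / "expression.tsv")
    gene_truth.to_csv(RESULTS / "gene_truth.tsv", sep="\t")

    manifest = {
        "n_chromosomes": N_CHROMOSOMES,
        "n_bins": len(genome.bins),
        "cell_types": [
            {
                "name": ct.name,
                "organ": ct.organ,
                "status": ct.status,
                "emt_parameter": ct.emt_parameter,
            }
            for ct in genome.cell_types
        ],
        "eligible_bins": {k: v.tolist() for k, v in genome.divergent_bins.items()},
        "emt_bins": genome.emt_bins.tolist(),
        "config": {
            k: v for k, v in vars(CONFIG).items() if not isinstance(v, (list, dict))
        },
    }
    (RESULTS / "truth_manifest.json").write_text(json.dumps(manifest, indent=2))

    print(f"wrote {n_matrices} contact matrices to {SCRATCH}")
    print(f"panel: {', '.join(ct.name for ct in genome.cell_types)}")
    print(
        f"{len(genome.bins)} bins; "
        f"{genome.emt_bins.size} EMT bins; "
        + "; ".join(f"{k}: {v.size} divergent bins" for k, v in genome.divergent_bins.items())
    )
    print(f"expression: {expression.shape[0]} genes x {expression.shape[1]} cell types")


if __name__ == "__main__":
    main()
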