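#!/usr/bin/env python
"""Quantify organ-permissive compartment switches from the called states.

For the metastatic and localized breast cancer groups: the 16-category
cross-state table against the lung system, permissive fractions, the
lung-vs-brain (decoy) comparison with the stability-probability
adjustment, and a BED of consensus permissive bins for gene extraction.
Writes results/organotropism/*.
"""

import json
from dataclasses import replace
from pathlib import Path

import pandas as pd

from oto import io_formats as io
from oto.compartments import call_states
from oto.organotropism import (
    PERMISSIVE_LABELS,
    compare_target_organs,
    consensus_pair_states,
    cross_states,
    summary_table,
)
from oto.profiles import bins_to_genes

import importlib.util

spec = importlib.util.spec_from_file_location(
    "profile_helpers", Path(__file__).with_name("03_profile_clustering.py")
)
helpers = importlib.util.module_from_spec(spec)
spec.loader.exec_module(helpers)

ROOT = Path(__file__).resolve().parents[1]
CALLS = ROOT / "scratch" / "calls"
RESULTS = ROOT / "results"
OUT = RESULTS / "organotropism"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = json.loads((RESULTS / "data" / "truth_manifest.json").read_text())
    bins = helpers.genome_bins(manifest)
    by_status: dict[str, list[str]] = {}
    by_organ: dict[str, dict] = {}
    for ct in manifest["cell_types"]:
        by_organ.setdefault(ct["organ"], {"normal": None, "cancers": []})
        if ct["status"] == "normal":
            by_organ[ct["organ"]]["normal"] = ct["name"]
        else:
            by_organ[ct["organ"]]["cancers"].append(ct["name"])
        if ct["organ"] == "breast" and ct["status"] != "normal":
            by_status.setdefault(ct["status"], []).append(ct["name"])

    states = {}
    for ct in manifest["cell_types"]:
        track = io.read_bedgraph_track(CALLS / f"{ct['name']}.track.bedGraph", bins)
        # tracks on disk were written post-orientation by 02_call_compartments
        track = replace(track, oriented=True, orientation_r=1.0)
        states[ct["name"]] = call_states(track)

    # per-group cross-state tables against the lung system
    lung_normal = states[by_organ["lung"]["normal"]]
    lung_cancers = [states[n] for n in by_organ["lung"]["cancers"]]
    breast_normal = states[by_organ["breast"]["normal"]]
    tables = {}
    for status, names in sorted(by_status.items()):
        primary = consensus_pair_states(breast_normal, [states[n] for n in names])
        secondary = consensus_pair_states(lung_normal, lung_cancers)
        cross = cross_states(primary, secondary)
        from oto.organotropism import permissive_summary

        summary = permissive_summary(cross)
        tables[status] = summary
        print(
            f"{status}: {summary.n_informative_bins} informative bins, "
            f"permissive fraction {summary.permissive_fraction:.3f}"
        )
        if status == "metastatic":
            permissive_bins = [
                i for i, lbl in enumerate(cross.labels) if lbl in PERMISSIVE_LABELS
            ]
            with open(OUT / "metastatic_permissive_bins.bed", "w") as fh:
                for i in permissive_bins:
                    b = bins[i]
                    fh.write(f"{b.chromosome}\t{b.start}\t{b.end}\t{cross.labels[i]}\n")
            genes = io.read_bed_genes(RESULTS / "data" / "genes.bed")
            gene_list = bins_to_genes(permissive_bins, genes, bins)
            (OUT / "metastatic_permissive_genes.txt").write_text(
                "\n".join(gene_list) + "\n"
            )
            print(
                f"  {len(permissive_bins)} consensus permissive bins -> "
                f"{len(gene_list)} genes"
            )

    counts = pd.DataFrame(
        {status: s.category_counts for status, s in tables.items()}
    )
    counts.to_csv(OUT / "cross_state_counts.tsv", sep="\t")

    # lung vs decoy (brain) with the stability-probability adjustment
    met = [states[n] for n in by_status["metastatic"]]
    organ_panels = {
        organ: (states[info["normal"]], [states[n] for n in info["cancers"]])
        for organ, info in by_organ.items()
        if organ != "breast"
    }
    results = compare_target_organs(breast_normal, met, organ_panels)
    tab = summary_table(results)
    tab.to_csv(OUT / "cross_organ_adjusted.tsv", sep="\t", float_format="%.6g")
    print("\nmetastatic group, per candidate target organ:")
    print(tab.to_string(float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
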