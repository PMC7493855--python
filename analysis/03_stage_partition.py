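#!/usr/bin/env python
"""Stage-resolved expression analysis of the filtered interactome.

Computes RPKM and OL-vs-OPC differential expression (FDR < 0.05,
|log2FC| > 1), partitions the two stage interactomes into shared and
stage-specific sets, cross-tabulates the stage-specific interactors by
expression class, builds the clustered log2 heatmap matrix for
own-stage-upregulated interactors, and intersects the interactomes with
the transcription-factor list.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from ipmsflow import tables_io
from ipmsflow.stage_expression import (DEConfig, compute_rpkm, de_test,
                                       heatmap_matrix, intersect_tf,
                                       stage_crosstab, venn_partition)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    inputs = args.outdir / "inputs"

    matrix = tables_io.read_expression_matrix(inputs / "counts.tsv")
    de = de_test(matrix, DEConfig())
    de.to_csv(args.outdir / "de_table.tsv", sep="\t", index=False)
    n_opc = int((de.de_class == "OPC_up").sum())
    n_ol = int((de.de_class == "OL_up").sum())
    print(f"differential expression: {n_opc} OPC-higher, {n_ol} OL-higher "
          f"of {len(de)} genes")

    calls = pd.read_csv(args.outdir / "interactor_calls.tsv", sep="\t")
    final = calls[calls.final_pass]
    interactomes = {s: set(final[final.stage == s].gene_symbol)
                    for s in ("OPC", "OL")}
    venn = venn_partition(interactomes["OPC"], interactomes["OL"])
    (args.outdir / "venn.json").write_text(json.dumps(venn.to_dict(), indent=2))
    print(f"venn: {len(venn.shared)} shared, {len(venn.a_specific)} "
          f"OPC-specific, {len(venn.b_specific)} OL-specific "
          f"(interactomes {venn.size_a} / {venn.size_b})")

    specific = {"OPC": set(venn.a_specific), "OL": set(venn.b_specific)}
    cts = stage_crosstab(specific, de)
    (args.outdir / "crosstab.json").write_text(
        json.dumps({s: c.to_dict() for s, c in cts.items()}, indent=2))
    for s, ct in cts.items():
        print(f"  {s}-specific: {ct.n_ns}/{ct.total} ({ct.percent_ns():.2f}%) "
              "without stage expression priority")

    de_class = dict(zip(de.gene_id, de.de_class))
    heat_genes = sorted(
        [g for g in specific["OPC"] if de_class.get(g) == "OPC_up"]
        + [g for g in specific["OL"] if de_class.get(g) == "OL_up"])
    if heat_genes:
        rpkm = compute_rpkm(matrix)
        mat, _, _, display = heatmap_matrix(rpkm, heat_genes)
        mat.to_csv(args.outdir / "heatmap_matrix.tsv", sep="\t")
        display.to_csv(args.outdir / "heatmap_display.tsv", sep="\t")
        print(f"heatmap: {len(heat_genes)} stage-specific upregulated "
              "interactors, clustered")

    tfs = tables_io.read_tf_list(inputs / "tf_list.txt")
    tf = intersect_tf(interactomes, tfs)
    (args.outdir / "tf_intersection.json").write_text(json.dumps(
        {s: sorted(v) for s, v in tf["per_stage"].items()}, indent=2))
    for s, v in tf["per_stage"].items():
        print(f"  {len(v)} of {len(interactomes[s])} {s} partners are TFs")


if __name__ == "__main__":
    main()
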