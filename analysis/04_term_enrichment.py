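#!/usr/bin/env python
"""Term enrichment and kappa networks for the stage interactomes.

For each stage, tests every gene set for over-representation in the
filtered interactome against the stage-expressed background
(hypergeometric, significant at p < 0.01, BH FDR reported), selects the
top-20 terms, reports the terms shared between stages, and builds the
term / term-protein network with kappa >= 0.4 edges.
"""

import argparse
from pathlib import Path

import pandas as pd

from ipmsflow import tables_io
from ipmsflow.enrichment_network import (build_term_network, enrich_terms,
                                         results_to_frame, shared_terms,
                                         top_terms)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--top", type=int, default=20)
    args = ap.parse_args()
    inputs = args.outdir / "inputs"

    collection = tables_io.read_gmt(inputs / "genesets.gmt")
    matrix = tables_io.read_expression_matrix(inputs / "counts.tsv")
    calls = pd.read_csv(args.outdir / "interactor_calls.tsv", sep="\t")
    final = calls[calls.final_pass]

    per_stage = {}
    for stage in ("OPC", "OL"):
        universe = matrix.expressed_genes(stage)
        query = set(final[final.stage == stage].gene_symbol) & universe
        results = enrich_terms(query, collection, universe, alpha=0.01)
        per_stage[stage] = results
        results_to_frame(results).to_csv(
            args.outdir / f"enrichment_{stage}.tsv", sep="\t", index=False)
        top = top_terms(results, min(args.top, len(results)))
        results_to_frame(top).to_csv(
            args.outdir / f"top_terms_{stage}.tsv", sep="\t", index=False)
        network = build_term_network(results, collection, query,
                                     kappa_threshold=0.4)
        tables_io.write_network(network,
                                args.outdir / f"term_network_{stage}.graphml")
        n_terms = sum(1 for _, d in network.nodes(data=True)
                      if d["kind"] == "term")
        n_edges = sum(1 for *_, d in network.edges(data=True)
                      if d["kind"] == "kappa")
        print(f"{stage}: query {len(query)} genes, "
              f"{sum(r.enriched for r in results)}/{len(results)} terms "
              f"enriched (p < 0.01); network {n_terms} term nodes, "
              f"{n_edges} kappa edges")
        best = top[0]
        print(f"  top term {best.term_id} ({best.term_name}): "
              f"k={best.k}/{best.K}, p={best.p_value:.2e}")

    m = min(args.top, *(len(r) for r in per_stage.values()))
    shared = shared_terms(per_stage["OPC"], per_stage["OL"], m)
    print(f"{len(shared)} of the top-{m} terms shared between stages")


if __name__ == "__main__":
    main()
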