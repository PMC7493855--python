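#!/usr/bin/env python
"""Generate the synthetic study inputs.

Emulates the study design: two replicate bait pulldowns with IgG controls
per differentiation stage, a contaminant repository, a 2x3 stage
transcriptome, gene-set annotations with planted interactor-enriched terms,
and a transcription-factor list.  Writes every table in the dialect the
pipeline readers consume, plus the ground-truth labels, under
``<outdir>/inputs``.
"""

import argparse
from pathlib import Path

from ipmsflow.pipeline import _write_inputs
from ipmsflow.synthetic_data import SimulationParams, simulate_all


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    params = SimulationParams(seed=args.seed)
    sim = simulate_all(params)
    args.outdir.mkdir(parents=True, exist_ok=True)
    _write_inputs(args.outdir, sim)
    truth = sim["truth"]
    (args.outdir / "inputs" / "truth_labels.tsv").write_text(
        "gene_symbol\tlabel\n" + "\n".join(
            f"{g}\t{l}" for g, l in sorted(truth.protein_labels.items())) + "\n")

    labels = truth.protein_labels.values()
    print(f"wrote inputs to {args.outdir / 'inputs'}")
    print(f"  {params.n_proteins} proteins: "
          f"{sum(l == 'true_interactor' for l in labels)} true interactors, "
          f"{sum(l == 'contaminant' for l in labels)} contaminants, "
          f"{sum(l == 'non_lineage' for l in labels)} non-lineage")
    n_de = sum(c != "NS" for c in truth.gene_de_class.values())
    print(f"  {params.n_genes} genes, {n_de} DE planted; "
          f"{len(truth.planted_terms)} enriched terms planted")


if __name__ == "__main__":
    main()
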