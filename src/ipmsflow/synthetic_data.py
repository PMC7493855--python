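"""Ground-truth-labeled synthetic inputs for the whole pipeline.

The generator emulates the study design end to end: two replicate bait
pulldowns per differentiation stage with a matched IgG control channel,
log-normal LFQ intensities with bait-specific enrichment for true
interactors, abundant carry-over contaminants present equally in both
channels, a contaminant-repository table, a negative-binomial two-stage
transcriptome in triplicate with a planted fraction of DE genes, gene-set
annotations with planted enriched terms, and a transcription-factor list.

Proteins and genes share one namespace (gene symbols double as protein
accessions with a ``P:`` prefix) so quantification, transcriptome and
annotations join without a mapping file.  Every generator is fully
deterministic under a fixed seed; independent substreams keep the outputs
stable when only one generator's parameters change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .tables_io import (CrapomeTable, ExpressionMatrix, GeneSet,
                        GeneSetCollection, QuantTable, STAGES)

__all__ = ["SimulationParams", "GroundTruth", "simulate_quant",
           "simulate_crapome", "simulate_transcriptome",
           "simulate_annotations", "simulate_tf_list", "simulate_all"]

LABELS = ("true_interactor", "background", "contaminant", "non_lineage")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study; defaults mirror the emulated design.

    Two IP replicates per stage and a 2 x 3 transcriptome follow the study
    layout; fractions and effect sizes are chosen so that every filter branch
    of the cascade is exercised.
    """

    n_proteins: int = 600
    frac_true_interactors: float = 0.25
    frac_contaminants: float = 0.08
    frac_non_lineage: float = 0.07
    bait_enrichment_log2_mean: float = 3.5
    bait_enrichment_log2_sd: float = 0.8
    background_lfq_log10_mean: float = 5.0
    background_lfq_log10_sd: float = 0.5
    contaminant_lfq_log10_mean: float = 7.5
    contaminant_lfq_log10_sd: float = 0.3
    channel_noise_log2_sd: float = 0.4
    frac_control_undetected: float = 0.3
    frac_contaminant_control_undetected: float = 0.15
    n_replicates: int = 2
    n_genes: int = 3000
    n_rna_replicates: int = 3
    frac_de: float = 0.12
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    baseline_log10_mean: float = 1.8
    baseline_log10_sd: float = 0.6
    n_terms: int = 40
    n_planted_terms: int = 4
    planted_term_size: int = 20
    planted_interactor_frac: float = 0.7
    planted_term_pool: int = 25
    n_tfs: int = 30
    seed: int = 0

    def __post_init__(self):
        fracs = (self.frac_true_interactors, self.frac_contaminants,
                 self.frac_non_lineage, self.frac_de,
                 self.frac_control_undetected,
                 self.frac_contaminant_control_undetected,
                 self.planted_interactor_frac)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if (self.frac_true_interactors + self.frac_contaminants
                + self.frac_non_lineage) > 1:
            raise ValueError("protein label fractions must sum to <= 1")
        for name in ("bait_enrichment_log2_sd", "background_lfq_log10_sd",
                     "contaminant_lfq_log10_sd", "channel_noise_log2_sd",
                     "nb_dispersion", "de_log2fc", "baseline_log10_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_proteins > self.n_genes:
            raise ValueError("n_proteins cannot exceed n_genes")
        if self.planted_interactor_frac < 0.6:
            raise ValueError("planted terms must be >= 60% interactor genes")
        if min(self.n_proteins, self.n_genes, self.n_replicates,
               self.n_rna_replicates, self.n_terms) < 1:
            raise ValueError("sizes must be positive")


@dataclass
class GroundTruth:
    """Labels behind the synthetic data, filled in by the generators."""

    protein_labels: dict[str, str]            # gene symbol -> LABELS entry
    gene_de_class: dict[str, str] = field(default_factory=dict)
    planted_terms: set[str] = field(default_factory=set)

    def genes_with_label(self, label: str) -> set[str]:
        return {g for g, l in self.protein_labels.items() if l == label}


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.seed, stream]))


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def protein_id_of(gene: str) -> str:
    return f"P:{gene}"


def _assign_labels(params: SimulationParams) -> GroundTruth:
    genes = _gene_names(params.n_genes)[: params.n_proteins]
    rng = _rng(params, 0)
    order = rng.permutation(params.n_proteins)
    n_true = round(params.frac_true_interactors * params.n_proteins)
    n_cont = round(params.frac_contaminants * params.n_proteins)
    n_nl = round(params.frac_non_lineage * params.n_proteins)
    labels: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_true:
            lab = "true_interactor"
        elif rank < n_true + n_cont:
            lab = "contaminant"
        elif rank < n_true + n_cont + n_nl:
            lab = "non_lineage"
        else:
            lab = "background"
        labels[genes[idx]] = lab
    return GroundTruth(protein_labels=labels)


def simulate_quant(params: SimulationParams
                   ) -> tuple[dict[str, list[QuantTable]], GroundTruth]:
    """Replicate bait/control quantification tables per stage, plus truth.

    Background proteins have equal expected LFQ in both channels; true
    interactors carry a bait-specific boost of ``2**x`` with
    ``x ~ Normal(bait_enrichment_log2_mean, sd)``, and a protein-level
    fraction of them is undetected in the control channel.  Contaminants
    (carry-over proteins such as keratins) are highly abundant with equal
    expected intensity in both channels; a protein-level fraction of them is
    stochastically undetected in the IgG run, which makes them look
    bait-specific -- exactly the failure mode the repository filter exists
    to catch.  Spectral counts are Poisson with mean increasing in the
    within-experiment LFQ rank.  Non-lineage proteins behave like background
    here; the transcriptome generator zeroes their genes.
    """
    truth = _assign_labels(params)
    rng = _rng(params, 1)
    genes = sorted(truth.protein_labels)
    labels = np.array([truth.protein_labels[g] for g in genes])
    n = len(genes)

    base_log10 = rng.normal(params.background_lfq_log10_mean,
                            params.background_lfq_log10_sd, size=n)
    cont = labels == "contaminant"
    base_log10[cont] = rng.normal(params.contaminant_lfq_log10_mean,
                                  params.contaminant_lfq_log10_sd,
                                  size=int(cont.sum()))
    base = 10.0 ** base_log10

    true_mask = labels == "true_interactor"
    boost = np.ones(n)
    boost[true_mask] = 2.0 ** rng.normal(params.bait_enrichment_log2_mean,
                                         params.bait_enrichment_log2_sd,
                                         size=int(true_mask.sum()))
    control_undetected = np.zeros(n, dtype=bool)
    control_undetected[true_mask] = (
        rng.random(int(true_mask.sum())) < params.frac_control_undetected)
    control_undetected[cont] = (
        rng.random(int(cont.sum()))
        < params.frac_contaminant_control_undetected)

    tables: dict[str, list[QuantTable]] = {}
    for stage in STAGES:
        reps = []
        for rep in range(params.n_replicates):
            noise_b = 2.0 ** rng.normal(0.0, params.channel_noise_log2_sd, size=n)
            noise_c = 2.0 ** rng.normal(0.0, params.channel_noise_log2_sd, size=n)
            bait = base * boost * noise_b
            control = base * noise_c
            control[control_undetected] = 0.0
            exp_id = f"{stage}_rep{rep + 1}"
            rows = []
            for channel, lfq in (("bait", bait), ("control", control)):
                rank_frac = pd.Series(lfq).rank(method="average").to_numpy() / n
                sc = rng.poisson(1.0 + 60.0 * rank_frac)
                sc[lfq <= 0] = 0
                for g, v, s in zip(genes, lfq, sc):
                    rows.append((protein_id_of(g), g, exp_id, channel,
                                 float(v), int(s)))
            reps.append(QuantTable(pd.DataFrame(
                rows, columns=["protein_id", "gene_symbol", "experiment_id",
                               "channel", "lfq_intensity", "spectral_count"])))
        tables[stage] = reps
    return tables, truth


def simulate_crapome(truth: GroundTruth, params: SimulationParams) -> CrapomeTable:
    """Repository table covering every simulated protein.

    Truth-contaminants get either a max spectral count over 200 (probability
    0.7) or one that trips the product rule at two IP experiments; all other
    proteins stay at max counts <= 40, below both rules.
    """
    rng = _rng(params, 2)
    rows = []
    for gene in sorted(truth.protein_labels):
        label = truth.protein_labels[gene]
        if label == "contaminant":
            if rng.random() < 0.7:
                max_sc = int(rng.integers(201, 601))
            else:
                max_sc = int(rng.integers(51, 201))
            n_exp = int(rng.integers(100, 351))
        else:
            max_sc = int(rng.integers(0, 41))
            n_exp = int(rng.integers(1, 51))
        avg = float(max_sc) * float(rng.uniform(0.3, 1.0))
        rows.append((protein_id_of(gene), n_exp, max_sc, avg))
    return CrapomeTable(pd.DataFrame(
        rows, columns=["protein_id", "n_experiments", "max_spectral_count",
                       "avg_spectral_count"]))


def simulate_transcriptome(truth: GroundTruth,
                           params: SimulationParams) -> ExpressionMatrix:
    """Negative-binomial two-stage transcriptome in triplicate.

    A fraction ``frac_de`` of lineage genes is shifted by ``de_log2fc``,
    split evenly between OPC-up and OL-up; genes of non-lineage proteins get
    zero counts in all samples.  Gene lengths are log-uniform in
    [500, 10000] bp.  Updates ``truth.gene_de_class`` in place.
    """
    rng = _rng(params, 3)
    genes = _gene_names(params.n_genes)
    non_lineage = truth.genes_with_label("non_lineage")
    base_mu = 10.0 ** rng.normal(params.baseline_log10_mean,
                                 params.baseline_log10_sd, size=params.n_genes)

    lineage_idx = [i for i, g in enumerate(genes) if g not in non_lineage]
    n_de = round(params.frac_de * len(lineage_idx))
    de_idx = rng.choice(lineage_idx, size=n_de, replace=False)
    half = n_de // 2
    opc_up = set(de_idx[:half].tolist())
    ol_up = set(de_idx[half:].tolist())

    truth.gene_de_class = {}
    for i, g in enumerate(genes):
        if g in non_lineage:
            truth.gene_de_class[g] = "NS"
        elif i in opc_up:
            truth.gene_de_class[g] = "OPC_up"
        elif i in ol_up:
            truth.gene_de_class[g] = "OL_up"
        else:
            truth.gene_de_class[g] = "NS"

    fc = 2.0 ** params.de_log2fc
    mu = {stage: base_mu.copy() for stage in STAGES}
    for i in opc_up:
        mu["OPC"][i] *= fc
    for i in ol_up:
        mu["OL"][i] *= fc
    for i, g in enumerate(genes):
        if g in non_lineage:
            mu["OPC"][i] = 0.0
            mu["OL"][i] = 0.0

    alpha = params.nb_dispersion
    counts = {}
    for stage in STAGES:
        for rep in range(params.n_rna_replicates):
            m = mu[stage]
            col = np.zeros(params.n_genes, dtype=int)
            pos = m > 0
            # NB(mean m, var m + alpha m^2) via shape 1/alpha
            p = 1.0 / (1.0 + alpha * m[pos])
            col[pos] = rng.negative_binomial(1.0 / alpha, p)
            counts[f"{stage}_{rep + 1}"] = col
    lengths = np.exp(rng.uniform(np.log(500), np.log(10000),
                                 size=params.n_genes)).astype(int)
    counts_df = pd.DataFrame(counts, index=genes)
    stages = {s: s.split("_")[0] for s in counts_df.columns}
    return ExpressionMatrix(counts_df, pd.Series(lengths, index=genes), stages)


def simulate_annotations(truth: GroundTruth,
                         params: SimulationParams) -> GeneSetCollection:
    """Gene-set collection with planted interactor-enriched terms.

    Planted terms draw ``planted_interactor_frac`` of their members from a
    shared pool of ``planted_term_pool`` true-interactor genes (related
    annotation terms overlap in membership, which is what gives the term
    network its kappa edges) and the rest from other lineage genes; the
    remaining terms are uniform draws from lineage genes with sizes in
    [10, 80].  Updates ``truth.planted_terms`` in place.
    """
    rng = _rng(params, 4)
    genes = np.array(_gene_names(params.n_genes))
    non_lineage = truth.genes_with_label("non_lineage")
    lineage = np.array([g for g in genes if g not in non_lineage])
    interactors = np.array(sorted(truth.genes_with_label("true_interactor")))
    other = np.array([g for g in lineage if g not in set(interactors)])

    pool = (rng.choice(interactors,
                       size=min(params.planted_term_pool, len(interactors)),
                       replace=False)
            if len(interactors) else interactors)
    terms = []
    truth.planted_terms = set()
    for t in range(params.n_planted_terms):
        n_int = int(np.ceil(params.planted_interactor_frac
                            * params.planted_term_size))
        n_int = min(n_int, len(pool))  # null scenario: nothing to plant
        n_other = params.planted_term_size - n_int
        members = set(rng.choice(pool, size=n_int, replace=False)) if n_int else set()
        members |= set(rng.choice(other, size=n_other, replace=False))
        term_id = f"T{t:03d}"
        terms.append(GeneSet(term_id, f"planted term {t}",
                             frozenset(members), category="GO"))
        truth.planted_terms.add(term_id)
    for t in range(params.n_planted_terms, params.n_terms):
        size = int(rng.integers(10, 81))
        members = frozenset(rng.choice(lineage, size=size, replace=False))
        terms.append(GeneSet(f"T{t:03d}", f"random term {t}", members,
                             category="GO"))
    return GeneSetCollection(terms)


def simulate_tf_list(truth: GroundTruth, params: SimulationParams) -> set[str]:
    """A transcription-factor list mixing interactor and other lineage genes."""
    rng = _rng(params, 5)
    interactors = sorted(truth.genes_with_label("true_interactor"))
    others = sorted(set(truth.protein_labels) - set(interactors))
    n_from_int = min(params.n_tfs // 3, len(interactors))
    tfs = set(rng.choice(interactors, size=n_from_int, replace=False))
    tfs |= set(rng.choice(others, size=params.n_tfs - n_from_int, replace=False))
    return tfs


def simulate_all(params: SimulationParams) -> dict:
    """Run every generator; returns a dict of all inputs plus the truth."""
    quant, truth = simulate_quant(params)
    crapome = simulate_crapome(truth, params)
    transcriptome = simulate_transcriptome(truth, params)
    annotations = simulate_annotations(truth, params)
    tf_list = simulate_tf_list(truth, params)
    return {"quant": quant, "crapome": crapome, "transcriptome": transcriptome,
            "annotations": annotations, "tf_list": tf_list, "truth": truth}
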