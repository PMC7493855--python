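"""Three-stage interactor filter cascade with full accounting.

A candidate prey protein from a bait pulldown becomes an interactor call by
surviving, in order:

1. **specificity** — its gene is expressed in the stage-matched transcriptome
   (non-lineage identifications are removed);
2. **reliability** — it is detected in the bait channel but not the IgG
   control, or its log2 LFQ ratio (bait over control, after equal-total
   channel normalization) strictly exceeds a threshold (default 2);
3. **contamination** — it is not flagged by the contaminant repository:
   flagged when max spectral count > 200, or the product of the number of IP
   experiments and the max spectral count > 100 (strict inequalities).

Every run yields a :class:`FilterLedger` whose counts satisfy the
conservation identity
``n_identified = n_lineage_removed + (n_after_lineage - n_enrichment_pass)
+ n_contaminants + n_final``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tables_io import CHANNELS, CrapomeTable, QuantTable

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "InteractorCall",
    "FilterLedger",
    "normalize_against_control",
    "enrichment_call",
    "lineage_filter",
    "crapome_flag",
    "combine_replicates",
    "run_cascade",
    "calls_to_frame",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and switches of the filter cascade.

    ``pseudo_intensity`` is used only as a floor on the bait intensity when
    forming a ratio against a nonzero control (it keeps the log-ratio finite
    for bait-undetected proteins); detected intensities are never shifted.
    ``n_ip_experiments`` is the study's IP replicate count used by the
    contaminant product rule; set ``crapome_n_source='repository'`` to use the
    repository's own detection count instead.
    """

    log2_ratio_threshold: float = 2.0
    crapome_max_count_threshold: int = 200
    crapome_product_threshold: int = 100
    pseudo_intensity: float = 1.0
    replicate_combination: str = "union"  # or "intersection"
    n_ip_experiments: int = 2
    crapome_n_source: str = "study"  # or "repository"

    def __post_init__(self):
        if self.log2_ratio_threshold <= 0:
            raise ValueError("log2_ratio_threshold must be > 0")
        if self.crapome_max_count_threshold <= 0 or self.crapome_product_threshold <= 0:
            raise ValueError("contaminant thresholds must be > 0")
        if self.pseudo_intensity <= 0:
            raise ValueError("pseudo_intensity must be > 0")
        if self.replicate_combination not in ("union", "intersection"):
            raise ValueError("replicate_combination must be 'union' or 'intersection'")
        if self.crapome_n_source not in ("study", "repository"):
            raise ValueError("crapome_n_source must be 'study' or 'repository'")
        if self.n_ip_experiments < 1:
            raise ValueError("n_ip_experiments must be >= 1")


@dataclass
class InteractorCall:
    """Per-protein, per-stage outcome of the cascade."""

    protein_id: str
    gene_symbol: str
    stage: str
    detected_in_control: bool
    log2_enrichment: float | None
    transcriptome_pass: bool
    enrichment_pass: bool
    contaminant: bool

    @property
    def final_pass(self) -> bool:
        return self.transcriptome_pass and self.enrichment_pass and not self.contaminant


@dataclass(frozen=True)
class FilterLedger:
    """Stage-by-stage accounting of the cascade; validated on construction."""

    n_identified: int
    n_lineage_removed: int
    n_after_lineage: int
    n_enrichment_pass: int
    n_contaminants: int
    n_final: int

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.n_after_lineage != self.n_identified - self.n_lineage_removed:
            raise ValueError("n_after_lineage must equal n_identified - n_lineage_removed")
        if self.n_final != self.n_enrichment_pass - self.n_contaminants:
            raise ValueError("n_final must equal n_enrichment_pass - n_contaminants")
        if self.n_enrichment_pass > self.n_after_lineage:
            raise ValueError("n_enrichment_pass cannot exceed n_after_lineage")

    @classmethod
    def from_stage_counts(cls, n_identified: int, n_lineage_removed: int,
                          n_enrichment_pass: int, n_contaminants: int) -> "FilterLedger":
        """Derive the dependent counts from the four independent ones."""
        return cls(n_identified=n_identified,
                   n_lineage_removed=n_lineage_removed,
                   n_after_lineage=n_identified - n_lineage_removed,
                   n_enrichment_pass=n_enrichment_pass,
                   n_contaminants=n_contaminants,
                   n_final=n_enrichment_pass - n_contaminants)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


# ---------------------------------------------------------------------------
# Individual filter predicates
# ---------------------------------------------------------------------------


def normalize_against_control(table: QuantTable) -> QuantTable:
    """Scale the bait channel so its total intensity matches the control's.

    Scaling is per experiment.  This makes the downstream bait/control ratio a
    relative-enrichment measure that is invariant to overall pulldown yield.
    """
    df = table.df.copy()
    for exp in table.experiments():
        sub = df["experiment_id"] == exp
        totals = df.loc[sub].groupby("channel")["lfq_intensity"].sum()
        control_total = float(totals.get("control", 0.0))
        bait_total = float(totals.get("bait", 0.0))
        if control_total <= 0:
            raise ValueError(f"experiment {exp!r}: control channel absent or all-zero; "
                             "cannot normalize against control")
        if bait_total <= 0:
            raise ValueError(f"experiment {exp!r}: bait channel absent or all-zero")
        scale = control_total / bait_total
        mask = sub & (df["channel"] == "bait")
        df.loc[mask, "lfq_intensity"] = df.loc[mask, "lfq_intensity"] * scale
    return QuantTable(df)


def enrichment_call(bait_lfq: float, control_lfq: float,
                    config: FilterConfig = FilterConfig()) -> tuple[bool, float | None]:
    """Reliability call for one protein.

    Returns ``(passed, log2_enrichment)``.  The log2 enrichment is undefined
    (``None``) when the control intensity is zero: bait-only detection passes
    outright, and a protein absent from both channels fails.
    """
    if bait_lfq < 0 or control_lfq < 0:
        raise ValueError("intensities must be non-negative")
    if control_lfq == 0:
        return (bait_lfq > 0), None
    numerator = bait_lfq if bait_lfq > 0 else config.pseudo_intensity
    log2_enrichment = math.log2(numerator / control_lfq)
    return log2_enrichment > config.log2_ratio_threshold, log2_enrichment


def lineage_filter(proteins: set[str], expressed: set[str]) -> tuple[set[str], set[str]]:
    """Partition ``proteins`` into transcriptome-supported and removed sets."""
    if not expressed:
        raise ValueError("expressed gene set is empty; transcriptome missing")
    kept = set(proteins) & set(expressed)
    removed = set(proteins) - set(expressed)
    return kept, removed


def crapome_flag(record, n_ip_experiments: int,
                 config: FilterConfig = FilterConfig()) -> bool:
    """True when repository evidence marks the protein as a likely contaminant.

    ``record`` is a row from :class:`~ipmsflow.tables_io.CrapomeTable` (or
    None when the protein has no repository evidence, which is never a flag).
    """
    if record is None:
        return False
    if n_ip_experiments < 1:
        raise ValueError("n_ip_experiments must be >= 1")
    max_sc = int(record["max_spectral_count"])
    if config.crapome_n_source == "repository":
        n = int(record["n_experiments"])
    else:
        n = n_ip_experiments
    return (max_sc > config.crapome_max_count_threshold
            or n * max_sc > config.crapome_product_threshold)


def combine_replicates(tables: Sequence[QuantTable],
                       config: FilterConfig = FilterConfig()) -> QuantTable:
    """Merge replicate pulldowns into one table.

    ``union`` keeps a protein detected in any replicate; ``intersection``
    requires detection in all.  Per protein and channel the maximum LFQ
    intensity and maximum spectral count across replicates are retained, under
    a synthetic ``combined`` experiment id.
    """
    if not tables:
        raise ValueError("combine_replicates requires at least one table")
    df = pd.concat([t.df for t in tables], ignore_index=True)
    if config.replicate_combination == "intersection":
        per_rep = [t.proteins() for t in tables]
        keep = set.intersection(*per_rep)
        df = df[df["protein_id"].isin(keep)]
    agg = (df.groupby(["protein_id", "gene_symbol", "channel"], as_index=False)
             .agg(lfq_intensity=("lfq_intensity", "max"),
                  spectral_count=("spectral_count", "max")))
    agg["experiment_id"] = "combined"
    return QuantTable(agg[["protein_id", "gene_symbol", "experiment_id", "channel",
                           "lfq_intensity", "spectral_count"]])


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------


def run_cascade(quant: Mapping[str, Sequence[QuantTable]],
                crapome: CrapomeTable,
                expressed: Mapping[str, set[str]],
                config: FilterConfig = FilterConfig(),
                ) -> tuple[list[InteractorCall], FilterLedger]:
    """Run the full cascade, stage by stage.

    Parameters
    ----------
    quant
        Stage -> list of replicate quantification tables (bait + control
        channels).  Each replicate is normalized against its control before
        replicates are combined.
    expressed
        Stage -> set of gene symbols with nonzero expression in that stage.

    Returns
    -------
    calls
        One :class:`InteractorCall` per (stage, protein) detected in the bait
        channel of that stage.
    ledger
        Pooled accounting across stages, keyed by protein: a protein counts
        as lineage-removed only if removed in every stage where it was
        detected, and as enrichment-passing / final if it passes in at least
        one stage.  This pooled view matches the union arithmetic of the
        per-stage interactomes.
    """
    calls: list[InteractorCall] = []
    n_control_only = 0
    # pooled per-protein status across stages
    detected: set[str] = set()
    kept_any: set[str] = set()
    pass_any: set[str] = set()
    final_any: set[str] = set()
    contaminant_ids: set[str] = set()

    for stage, tables in quant.items():
        normalized = [normalize_against_control(t) for t in tables]
        combined = combine_replicates(normalized, config)
        wide = combined.to_wide()
        stage_expressed = set(expressed[stage])
        for row in wide.itertuples(index=False):
            bait, control = float(row.bait_lfq), float(row.control_lfq)
            if bait <= 0 and control > 0:
                n_control_only += 1
                continue
            if bait <= 0 and control <= 0:
                continue
            detected.add(row.protein_id)
            kept, _removed = lineage_filter({row.gene_symbol}, stage_expressed)
            transcriptome_pass = bool(kept)
            passed, log2_enr = enrichment_call(bait, control, config)
            record = crapome.get(row.protein_id)
            contaminant = crapome_flag(record, config.n_ip_experiments, config)
            call = InteractorCall(
                protein_id=row.protein_id,
                gene_symbol=row.gene_symbol,
                stage=stage,
                detected_in_control=control > 0,
                log2_enrichment=log2_enr,
                transcriptome_pass=transcriptome_pass,
                enrichment_pass=passed,
                contaminant=contaminant,
            )
            calls.append(call)
            if transcriptome_pass:
                kept_any.add(row.protein_id)
                if passed:
                    pass_any.add(row.protein_id)
                    if contaminant:
                        contaminant_ids.add(row.protein_id)
                    else:
                        final_any.add(row.protein_id)

    # a protein flagged as contaminant in one stage may still be final via
    # another stage only if crapome evidence differed -- it cannot, the flag
    # is per protein; enforce the partition
    contaminant_ids -= final_any

    ledger = FilterLedger.from_stage_counts(
        n_identified=len(detected),
        n_lineage_removed=len(detected - kept_any),
        n_enrichment_pass=len(pass_any),
        n_contaminants=len(contaminant_ids),
    )
    if n_control_only:
        logger.info("dropped %d protein/stage entries detected only in the "
                    "control channel", n_control_only)
    if ledger.n_final == 0:
        logger.warning("cascade produced an empty final interactor set")
    return calls, ledger


def calls_to_frame(calls: Iterable[InteractorCall]) -> pd.DataFrame:
    """Flatten calls to a DataFrame (TSV-ready), including final_pass."""
    rows = []
    for c in calls:
        d = asdict(c)
        d["final_pass"] = c.final_pass
        rows.append(d)
    cols = ["protein_id", "gene_symbol", "stage", "detected_in_control",
            "log2_enrichment", "transcriptome_pass", "enrichment_pass",
            "contaminant", "final_pass"]
    return pd.DataFrame(rows, columns=cols)
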