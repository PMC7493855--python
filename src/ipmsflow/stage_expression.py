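"""Stage-resolved expression analysis and interactome partitioning.

Covers: RPKM computation from a gene x sample count matrix; a two-group
differential-expression test between the precursor (OPC) and mature (OL)
stages; Venn partitioning of the two stage interactomes; cross-tabulation of
stage-specific interactors against their expression class; the clustered
log2 heatmap matrix; and intersection with a transcription-factor list.

The DE statistic
----------------
Per gene, counts are pooled within each stage and compared as two
proportions of the stage library totals with a z statistic.  Raw pooled
proportions have binomial variance only; biological replicates are
overdispersed, so the variance is widened by a global negative-binomial
dispersion estimated by method of moments from within-stage replicate
variability.  P-values are two-sided normal, corrected across genes with
Benjamini-Hochberg.  The fold change is computed from stage-mean RPKM with a
pseudo-RPKM of 1 added to both means; positive log2 fold change means higher
in OL.  A gene is called OL-up when FDR < 0.05 and log2FC > 1, OPC-up when
FDR < 0.05 and log2FC < -1, otherwise NS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .tables_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DEConfig",
    "VennPartition",
    "StageCrosstab",
    "compute_rpkm",
    "de_test",
    "venn_partition",
    "stage_crosstab",
    "heatmap_matrix",
    "intersect_tf",
]

DE_CLASSES = ("OPC_up", "OL_up", "NS")


@dataclass(frozen=True)
class DEConfig:
    fdr_threshold: float = 0.05
    log2fc_threshold: float = 1.0
    pseudo_rpkm: float = 1.0

    def __post_init__(self):
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.log2fc_threshold <= 0:
            raise ValueError("log2fc_threshold must be > 0")


def compute_rpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, per gene and sample.

    ``rpkm = count * 1e9 / (library_size * gene_length_bp)``.
    """
    lib = matrix.library_sizes().astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for sample(s) {bad}")
    lengths = matrix.gene_lengths.astype(float)
    return matrix.counts.div(lib, axis=1).div(lengths, axis=0) * 1e9


def _estimate_dispersion(counts: pd.DataFrame, matrix: ExpressionMatrix) -> float:
    """Global NB dispersion (alpha in var = mu + alpha*mu^2) by method of moments.

    Counts are scaled to a common library size within each stage and the
    excess of replicate variance over the mean is regressed against the
    squared mean.  A plain ratio estimator is dominated by the handful of
    most abundant genes, so it is refined by iteratively reweighted least
    squares with weights ``1/(mu + alpha*mu^2)^2`` (the approximate variance
    of the per-gene moment residual), which spreads the information over all
    well-expressed genes.  Clipped at zero (Poisson).
    """
    ms = []
    vs = []
    lib = matrix.library_sizes().astype(float)
    mean_lib = float(lib.mean())
    for stage in sorted(set(matrix.sample_stages[list(counts.columns)])):
        cols = matrix.samples_of(stage)
        if len(cols) < 2:
            continue
        scaled = counts[cols].to_numpy(dtype=float) * (mean_lib / lib[cols].to_numpy())
        ms.append(scaled.mean(axis=1))
        vs.append(scaled.var(axis=1, ddof=1))
    if not ms:
        return 0.0
    m = np.concatenate(ms)
    v = np.concatenate(vs)
    keep = m >= 1.0
    if not keep.any() or np.sum(m[keep] ** 2) <= 0:
        return 0.0
    m, v = m[keep], v[keep]
    alpha = max(0.0, float(np.sum(v - m) / np.sum(m ** 2)))
    for _ in range(3):
        w = 1.0 / (m + alpha * m ** 2) ** 2
        alpha = max(0.0, float(np.sum(w * (v - m) * m ** 2) / np.sum(w * m ** 4)))
    return alpha


def de_test(matrix: ExpressionMatrix, config: DEConfig = DEConfig()) -> pd.DataFrame:
    """Differential expression OL vs OPC; one row per gene.

    Columns: ``gene_id, mean_rpkm_opc, mean_rpkm_ol, log2_fold_change,
    p_value, fdr, de_class, all_zero``.
    """
    for stage in ("OPC", "OL"):
        if not matrix.samples_of(stage):
            raise ValueError(f"no samples for stage {stage}")
    counts = matrix.counts
    rpkm = compute_rpkm(matrix)
    opc_cols = matrix.samples_of("OPC")
    ol_cols = matrix.samples_of("OL")
    lib = matrix.library_sizes().astype(float)

    x1 = counts[opc_cols].sum(axis=1).to_numpy(dtype=float)
    x2 = counts[ol_cols].sum(axis=1).to_numpy(dtype=float)
    n1 = float(lib[opc_cols].sum())
    n2 = float(lib[ol_cols].sum())
    alpha = _estimate_dispersion(counts, matrix)

    pooled = (x1 + x2) / (n1 + n2)
    lib1 = lib[opc_cols].to_numpy()
    lib2 = lib[ol_cols].to_numpy()
    # NB variance of each stage sum under the pooled null proportion
    mu1 = pooled[:, None] * lib1[None, :]
    mu2 = pooled[:, None] * lib2[None, :]
    var1 = (mu1 + alpha * mu1 ** 2).sum(axis=1) / n1 ** 2
    var2 = (mu2 + alpha * mu2 ** 2).sum(axis=1) / n2 ** 2
    se = np.sqrt(var1 + var2)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x2 / n2 - x1 / n1) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    all_zero = (x1 + x2) == 0
    p = np.where(all_zero | ~np.isfinite(p), 1.0, p)
    if all_zero.any():
        logger.info("%d gene(s) with zero counts in all samples flagged NS",
                    int(all_zero.sum()))

    fdr = multipletests(p, method="fdr_bh")[1]

    mean_opc = rpkm[opc_cols].mean(axis=1).to_numpy()
    mean_ol = rpkm[ol_cols].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_ol + config.pseudo_rpkm) / (mean_opc + config.pseudo_rpkm))

    de_class = np.full(len(counts), "NS", dtype=object)
    sig = fdr < config.fdr_threshold
    de_class[sig & (log2fc > config.log2fc_threshold)] = "OL_up"
    de_class[sig & (log2fc < -config.log2fc_threshold)] = "OPC_up"
    de_class[all_zero] = "NS"

    return pd.DataFrame({
        "gene_id": counts.index,
        "mean_rpkm_opc": mean_opc,
        "mean_rpkm_ol": mean_ol,
        "log2_fold_change": log2fc,
        "p_value": p,
        "fdr": fdr,
        "de_class": de_class,
        "all_zero": all_zero,
    }).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Set partitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VennPartition:
    shared: frozenset
    a_specific: frozenset
    b_specific: frozenset

    @property
    def size_a(self) -> int:
        return len(self.shared) + len(self.a_specific)

    @property
    def size_b(self) -> int:
        return len(self.shared) + len(self.b_specific)

    def to_dict(self) -> dict:
        return {"shared": sorted(self.shared),
                "a_specific": sorted(self.a_specific),
                "b_specific": sorted(self.b_specific),
                "n_shared": len(self.shared),
                "n_a_specific": len(self.a_specific),
                "n_b_specific": len(self.b_specific),
                "n_a": self.size_a,
                "n_b": self.size_b}


def venn_partition(set_a: Iterable, set_b: Iterable) -> VennPartition:
    """Two-set Venn decomposition: shared, A-specific, B-specific."""
    a, b = set(set_a), set(set_b)
    return VennPartition(frozenset(a & b), frozenset(a - b), frozenset(b - a))


@dataclass(frozen=True)
class StageCrosstab:
    """Expression-class tally of one stage-specific interactor set."""

    stage: str
    n_up_in_own_stage: int
    n_up_in_other_stage: int
    n_ns: int

    @property
    def total(self) -> int:
        return self.n_up_in_own_stage + self.n_up_in_other_stage + self.n_ns

    def percent_ns(self) -> float:
        """Share of the set without significant expression priority, 2 decimals."""
        if self.total == 0:
            return 0.0
        return round(100.0 * self.n_ns / self.total, 2)

    def to_dict(self) -> dict:
        return {"stage": self.stage,
                "n_up_in_own_stage": self.n_up_in_own_stage,
                "n_up_in_other_stage": self.n_up_in_other_stage,
                "n_ns": self.n_ns,
                "total": self.total,
                "percent_ns": self.percent_ns()}


def stage_crosstab(specific: Mapping[str, set[str]],
                   de: pd.DataFrame) -> dict[str, StageCrosstab]:
    """Tally each stage-specific set by DE class of its members.

    ``specific`` maps stage ("OPC"/"OL") to its stage-specific gene set.
    Genes without a DE result are counted NS and logged.
    """
    de_class = dict(zip(de["gene_id"], de["de_class"]))
    own_up = {"OPC": "OPC_up", "OL": "OL_up"}
    other_up = {"OPC": "OL_up", "OL": "OPC_up"}
    out: dict[str, StageCrosstab] = {}
    for stage, genes in specific.items():
        missing = [g for g in genes if g not in de_class]
        if missing:
            logger.info("stage %s: %d gene(s) without DE result counted NS",
                        stage, len(missing))
        classes = [de_class.get(g, "NS") for g in genes]
        out[stage] = StageCrosstab(
            stage=stage,
            n_up_in_own_stage=sum(c == own_up[stage] for c in classes),
            n_up_in_other_stage=sum(c == other_up[stage] for c in classes),
            n_ns=sum(c not in (own_up[stage], other_up[stage]) for c in classes),
        )
    return out


# ---------------------------------------------------------------------------
# Heatmap matrix
# ---------------------------------------------------------------------------


def heatmap_matrix(rpkm: pd.DataFrame, genes: Sequence[str],
                   clip_range: tuple[float, float] = (0.0, 8.0),
                   linkage_method: str = "average",
                   metric: str = "euclidean",
                   ) -> tuple[pd.DataFrame, list[int], list[int], pd.DataFrame]:
    """Clustered log2 expression matrix for a gene subset.

    Values are ``log2(rpkm + 1)``; rows (genes) and columns (samples) are
    ordered by agglomerative hierarchical clustering (average linkage,
    Euclidean distance by default) with scipy's deterministic tie-breaking,
    which follows input order.

    Returns ``(matrix, row_order, col_order, display)`` where ``matrix`` is
    the unclipped log2 matrix in clustered order and ``display`` the same
    matrix clipped to ``clip_range`` for rendering.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in rpkm.index]
    if missing:
        raise KeyError(f"genes absent from the RPKM table: {missing}")
    mat = np.log2(rpkm.loc[genes].to_numpy(dtype=float) + 1.0)
    log2 = pd.DataFrame(mat, index=genes, columns=rpkm.columns)

    def _leaf_order(data: np.ndarray) -> list[int]:
        if data.shape[0] < 2:
            return list(range(data.shape[0]))
        link = hierarchy.linkage(pdist(data, metric=metric), method=linkage_method)
        return list(hierarchy.leaves_list(link))

    row_order = _leaf_order(log2.to_numpy())
    col_order = _leaf_order(log2.to_numpy().T)
    ordered = log2.iloc[row_order, col_order]
    display = ordered.clip(lower=clip_range[0], upper=clip_range[1])
    return ordered, row_order, col_order, display


def intersect_tf(interactors: Mapping[str, set[str]],
                 tf_list: set[str]) -> dict:
    """Per-stage transcription-factor interactors plus their Venn partition."""
    if not tf_list:
        raise ValueError("transcription-factor list is empty")
    per_stage = {stage: set(genes) & set(tf_list)
                 for stage, genes in interactors.items()}
    stages = sorted(per_stage)
    result: dict = {"per_stage": per_stage}
    if len(stages) == 2:
        result["venn"] = venn_partition(per_stage[stages[0]], per_stage[stages[1]])
        result["stage_order"] = stages
    return result
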