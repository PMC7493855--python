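"""Readers, writers and validated containers for every external table the
pipeline touches.

All tabular input and output is UTF-8 TSV with a required header row
(decimal point ``.``, no thousands separators).  A column-name mapping
("dialect") lets MaxQuant-style headers such as ``LFQ intensity <sample>``
be adapted to the canonical long form without editing files.  Gene-set
collections use the standard GMT exchange format; term networks are
serialized as GraphML or a TSV edge list via :mod:`networkx`.

Readers are strict: a malformed row raises instead of being silently
dropped, so the number of rows in equals the number of records out.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TableFormatError",
    "TableValidationError",
    "QuantTable",
    "CrapomeTable",
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "read_quant_table",
    "write_quant_table",
    "read_crapome",
    "write_crapome",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_tf_list",
    "write_tf_list",
    "read_symbol_map",
    "write_network",
    "read_network",
    "STAGES",
    "CHANNELS",
]

STAGES = ("OPC", "OL")
CHANNELS = ("bait", "control")


class TableFormatError(ValueError):
    """A file does not conform to the expected dialect (missing columns, bad GMT line...)."""


class TableValidationError(ValueError):
    """A parsed row violates a domain invariant (negative intensity, avg > max...)."""


# ---------------------------------------------------------------------------
# QuantTable
# ---------------------------------------------------------------------------

QUANT_COLUMNS = ("protein_id", "gene_symbol", "experiment_id", "channel",
                 "lfq_intensity", "spectral_count")


class QuantTable:
    """Long-form label-free quantification table.

    One row per (protein, experiment, channel) with the LFQ intensity and
    spectral count measured in that channel.  ``channel`` is ``bait`` for the
    target pulldown and ``control`` for the matched IgG pulldown.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)[list(QUANT_COLUMNS)].copy()
        self.df["lfq_intensity"] = self.df["lfq_intensity"].astype(float)
        self.df["spectral_count"] = self.df["spectral_count"].astype(int)
        if validate:
            self.validate()

    def validate(self) -> None:
        df = self.df
        bad_channel = ~df["channel"].isin(CHANNELS)
        if bad_channel.any():
            row = int(np.flatnonzero(bad_channel.to_numpy())[0])
            raise TableValidationError(
                f"row {row}: channel must be one of {CHANNELS}, "
                f"got {df['channel'].iloc[row]!r}")
        neg = df["lfq_intensity"].to_numpy() < 0
        if neg.any():
            row = int(np.flatnonzero(neg)[0])
            raise TableValidationError(f"row {row}: negative lfq_intensity")
        negc = df["spectral_count"].to_numpy() < 0
        if negc.any():
            row = int(np.flatnonzero(negc)[0])
            raise TableValidationError(f"row {row}: negative spectral_count")
        dup = df.duplicated(subset=["protein_id", "experiment_id", "channel"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise TableValidationError(
                f"row {row}: duplicate (protein_id, experiment_id, channel) key")

    def __len__(self) -> int:
        return len(self.df)

    def experiments(self) -> list[str]:
        return sorted(self.df["experiment_id"].unique())

    def proteins(self) -> set[str]:
        return set(self.df["protein_id"])

    def gene_of(self) -> dict[str, str]:
        """protein_id -> gene_symbol (first occurrence wins)."""
        sub = self.df.drop_duplicates("protein_id")
        return dict(zip(sub["protein_id"], sub["gene_symbol"]))

    def to_wide(self) -> pd.DataFrame:
        """Per-protein wide view: bait/control LFQ and spectral counts.

        Missing channels are filled with zero (undetected).  Intensities of a
        protein seen in several experiments are summed; use
        :func:`ipmsflow.interactor_filter.combine_replicates` for the
        max-across-replicates semantics of the cascade.
        """
        piv = self.df.pivot_table(index=["protein_id", "gene_symbol"],
                                  columns="channel",
                                  values=["lfq_intensity", "spectral_count"],
                                  aggfunc="sum", fill_value=0)
        out = pd.DataFrame(index=piv.index)
        for ch in CHANNELS:
            out[f"{ch}_lfq"] = piv.get(("lfq_intensity", ch), 0.0)
            out[f"{ch}_sc"] = piv.get(("spectral_count", ch), 0)
        return out.reset_index()


def read_quant_table(path: str | Path,
                     dialect: Mapping[str, str] | None = None,
                     symbol_map: Mapping[str, str] | None = None) -> QuantTable:
    """Read a long-form quantification TSV.

    Parameters
    ----------
    dialect
        Optional mapping from the file's column names to the canonical ones,
        e.g. ``{"Majority protein IDs": "protein_id"}``.  Unknown columns are
        ignored.
    symbol_map
        Optional accession -> gene symbol mapping used to fill or override
        ``gene_symbol`` (cross-dataset joins are on gene symbol).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    df = df[list(QUANT_COLUMNS)]
    try:
        df = df.assign(lfq_intensity=df["lfq_intensity"].astype(float),
                       spectral_count=df["spectral_count"].astype(float).astype(int))
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-numeric quantification value ({exc})") from exc
    if symbol_map:
        df["gene_symbol"] = [symbol_map.get(p, g)
                             for p, g in zip(df["protein_id"], df["gene_symbol"])]
    return QuantTable(df)


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CrapomeTable
# ---------------------------------------------------------------------------

CRAPOME_COLUMNS = ("protein_id", "n_experiments", "max_spectral_count",
                   "avg_spectral_count")


class CrapomeTable:
    """Contaminant-repository evidence per protein.

    ``n_experiments`` is the number of repository control runs detecting the
    protein; ``max_spectral_count`` / ``avg_spectral_count`` summarize its
    abundance in those runs.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)[list(CRAPOME_COLUMNS)].copy()
        self.df["n_experiments"] = self.df["n_experiments"].astype(int)
        self.df["max_spectral_count"] = self.df["max_spectral_count"].astype(int)
        self.df["avg_spectral_count"] = self.df["avg_spectral_count"].astype(float)
        if validate:
            self.validate()
        self._by_protein = self.df.set_index("protein_id")

    def validate(self) -> None:
        df = self.df
        bad = df["avg_spectral_count"].to_numpy() > df["max_spectral_count"].to_numpy()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise TableValidationError(
                f"row {row}: avg_spectral_count exceeds max_spectral_count")
        if (df["n_experiments"].to_numpy() < 1).any():
            row = int(np.flatnonzero(df["n_experiments"].to_numpy() < 1)[0])
            raise TableValidationError(f"row {row}: n_experiments must be >= 1")
        if (df["max_spectral_count"].to_numpy() < 0).any():
            raise TableValidationError("negative max_spectral_count")
        if df["protein_id"].duplicated().any():
            raise TableValidationError("duplicate protein_id in contaminant table")

    def __len__(self) -> int:
        return len(self.df)

    def get(self, protein_id: str):
        """Return the record row for ``protein_id`` or None if absent."""
        try:
            return self._by_protein.loc[protein_id]
        except KeyError:
            return None


def read_crapome(path: str | Path) -> CrapomeTable:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CRAPOME_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: contaminant table is empty", path)
    return CrapomeTable(df)


def write_crapome(table: CrapomeTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """Gene x sample read-count matrix with gene lengths and stage labels.

    ``counts`` is an integer DataFrame (genes x samples); ``gene_lengths`` a
    Series of transcript lengths in bp; ``sample_stages`` maps each sample
    (column) to one of the two differentiation stages.
    """

    def __init__(self, counts: pd.DataFrame, gene_lengths: pd.Series,
                 sample_stages: Mapping[str, str], validate: bool = True):
        self.counts = counts.astype(int)
        self.gene_lengths = gene_lengths.reindex(counts.index).astype(int)
        self.sample_stages = pd.Series(dict(sample_stages), dtype=object)
        if validate:
            self.validate()

    def validate(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise TableValidationError("negative read count")
        if (self.gene_lengths.to_numpy() <= 0).any():
            raise TableValidationError("gene_length_bp must be positive")
        if self.gene_lengths.isna().any():
            raise TableValidationError("gene length missing for some genes")
        missing = [s for s in self.counts.columns if s not in self.sample_stages.index]
        if missing:
            raise TableValidationError(f"samples without stage label: {missing}")
        stages = set(self.sample_stages[list(self.counts.columns)])
        for st in stages:
            if not any(self.sample_stages[s] == st for s in self.counts.columns):
                raise TableValidationError(f"stage {st} has no samples")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def samples_of(self, stage: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_stages[s] == stage]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def expressed_genes(self, stage: str | None = None) -> set[str]:
        """Genes with a nonzero count in any sample (of ``stage`` if given)."""
        cols = self.samples_of(stage) if stage else list(self.counts.columns)
        mask = (self.counts[cols] > 0).any(axis=1)
        return set(self.counts.index[mask])


def read_expression_matrix(path: str | Path,
                           sample_stages: Mapping[str, str] | None = None) -> ExpressionMatrix:
    """Read a counts TSV: ``gene_id``, ``gene_length_bp``, one column per sample.

    If ``sample_stages`` is omitted, stages are inferred from sample-name
    prefixes ``OPC``/``OL`` (case-insensitive, up to the first underscore).
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "gene_length_bp"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    df = df.set_index("gene_id")
    lengths = df.pop("gene_length_bp")
    if sample_stages is None:
        sample_stages = {}
        for s in df.columns:
            prefix = s.split("_")[0].upper()
            if prefix not in STAGES:
                raise TableFormatError(
                    f"{path}: cannot infer stage for sample {s!r}; "
                    "pass sample_stages explicitly")
            sample_stages[s] = prefix
    return ExpressionMatrix(df, lengths, sample_stages)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "gene_length_bp", matrix.gene_lengths)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    members: frozenset[str]
    category: str = "GO"

    def __post_init__(self):
        if not self.members:
            raise TableValidationError(f"term {self.term_id}: empty member set")


class GeneSetCollection:
    """An ordered collection of named gene sets keyed by unique term id."""

    def __init__(self, terms: Iterable[GeneSet]):
        self.terms: dict[str, GeneSet] = {}
        for t in terms:
            if t.term_id in self.terms:
                raise TableValidationError(f"duplicate term_id {t.term_id!r}")
            self.terms[t.term_id] = t

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.terms[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms


def read_gmt(path: str | Path, category: str = "GO") -> GeneSetCollection:
    """Parse a GMT file: ``term_id<TAB>description<TAB>gene...`` per line.

    Duplicate member symbols within a term are collapsed; a duplicate term id
    across lines is an error.
    """
    terms: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableFormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            term_id, desc, *genes = fields
            members = frozenset(g for g in genes if g)
            terms.append(GeneSet(term_id, desc, members, category=category))
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in collection:
            fh.write("\t".join([t.term_id, t.name, *sorted(t.members)]) + "\n")


# ---------------------------------------------------------------------------
# Plain-text symbol lists and maps
# ---------------------------------------------------------------------------


def read_tf_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.add(sym)
    return out


def write_tf_list(symbols: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sym in sorted(symbols):
            fh.write(sym + "\n")


def read_symbol_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (accession, gene_symbol) -> dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: symbol map needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# Term networks
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("graphml", "tsv")


def write_network(network: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Serialize a term network with its node and edge attributes.

    ``graphml`` preserves all attributes through :mod:`networkx`; ``tsv``
    writes an edge list (``source, target, kind, kappa``) plus a sibling
    ``<path>.nodes.tsv`` with node attributes so that the round trip is exact.
    """
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unsupported network format {format!r}; "
                         f"choose one of {NETWORK_FORMATS}")
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network, path)
        return
    rows = [{"source": u, "target": v,
             "kind": d.get("kind", "kappa"),
             "kappa": d.get("kappa", "")}
            for u, v, d in network.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "kind", "kappa"]).to_csv(
        path, sep="\t", index=False)
    node_rows = []
    for n, d in network.nodes(data=True):
        node_rows.append({"node": n, **d})
    pd.DataFrame(node_rows).to_csv(str(path) + ".nodes.tsv", sep="\t", index=False)


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unsupported network format {format!r}")
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    g = nx.Graph()
    nodes_path = Path(str(path) + ".nodes.tsv")
    if nodes_path.exists():
        ndf = pd.read_csv(nodes_path, sep="\t")
        if len(ndf):
            for _, row in ndf.iterrows():
                attrs = {k: v for k, v in row.items()
                         if k != "node" and pd.notna(v)}
                g.add_node(row["node"], **attrs)
    edf = pd.read_csv(path, sep="\t")
    for _, row in edf.iterrows():
        attrs = {"kind": row["kind"]}
        if pd.notna(row["kappa"]) and row["kappa"] != "":
            attrs["kappa"] = float(row["kappa"])
        g.add_edge(row["source"], row["target"], **attrs)
    return g
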