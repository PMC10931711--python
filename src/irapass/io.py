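"""Readers, writers and canonical containers for the APA pipeline.

Every table travels as TSV.  Event identifiers use the canonical
``GENE|chrom|site`` form, where *site* is the genomic coordinate of the
predicted proximal polyadenylation site.  DaPars2 output, which keys rows
by transcript (``transcript|GENE|chrom|strand``) and carries the proximal
site in its own column, is mapped onto that form on ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EventId",
    "PduiTable",
    "ExpressionTable",
    "ClinicalTable",
    "GeneSetCollection",
    "InteractionTable",
    "ParseError",
    "ValidationError",
    "read_pdui_table",
    "write_pdui_table",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "read_interactions",
    "write_interactions",
    "read_gene_list",
    "write_gene_list",
    "write_result_table",
    "read_result_table",
    "align_samples",
]

logger = logging.getLogger("irapass")

#: Response labels accepted in clinical tables: partial/complete response
#: (responders) vs progressive/stable disease (non-responders).
RESPONSE_LABELS = ("PRCR", "PDSD", "NA")

_TOOL_TAG = "irapass"


class ParseError(ValueError):
    """A file did not match its expected on-disk layout."""


class ValidationError(ValueError):
    """Parsed content violated a container invariant."""


# ---------------------------------------------------------------------------
# Event identifiers
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class EventId:
    """One APA event: a gene's predicted proximal polyA site.

    Serializes as ``GENE|chrom|site`` and round-trips losslessly.
    """

    gene_symbol: str
    chrom: str
    proximal_site: int

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValidationError("EventId gene_symbol must be non-empty")
        if not self.chrom:
            raise ValidationError("EventId chrom must be non-empty")
        if self.proximal_site < 0:
            raise ValidationError(
                f"EventId proximal_site must be >= 0, got {self.proximal_site}"
            )

    def __str__(self) -> str:
        return f"{self.gene_symbol}|{self.chrom}|{self.proximal_site}"

    @classmethod
    def parse(cls, text: str) -> "EventId":
        parts = text.split("|")
        if len(parts) != 3:
            raise ParseError(
                f"event id {text!r} must have exactly two '|' separators"
            )
        gene, chrom, site = parts
        try:
            site_int = int(site)
        except ValueError as exc:
            raise ParseError(f"event id {text!r}: site {site!r} is not an integer") from exc
        return cls(gene_symbol=gene, chrom=chrom, proximal_site=site_int)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


def _check_unique(values, what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dupes}")


@dataclass
class PduiTable:
    """Events x samples matrix of Percentage of Distal polyA site Usage.

    ``data`` is indexed by canonical event-id strings; values are floats in
    [0, 1] with NaN marking missing (DaPars2 output is sparse and missingness
    is preserved, never imputed, at this layer).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "event ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy()
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            rows = self.data.index[np.where(bad & ~np.isnan(vals))[0]].unique().tolist()[:5]
            raise ValidationError(f"PDUI values outside [0,1] at events {rows}")
        # parse eagerly so malformed ids fail at construction
        self._events = [EventId.parse(str(e)) for e in self.data.index]

    @property
    def event_ids(self) -> list[EventId]:
        return list(self._events)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ExpressionTable:
    """Genes x samples non-negative expression matrix (TPM scale)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy()
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValidationError("expression values must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation.

    Columns: ``response`` in {PRCR, PDSD, NA}; ``os_time`` (days, > 0 when
    present); ``os_event`` (1 = death observed); any further numeric columns
    (e.g. StromalScore, ImmuneScore) ride along as covariates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        if "response" in self.data.columns:
            labels = self.data["response"].fillna("NA").astype(str)
            bad = sorted(set(labels) - set(RESPONSE_LABELS))
            if bad:
                raise ValidationError(
                    f"unknown response label(s) {bad}; allowed: {list(RESPONSE_LABELS)}"
                )
            self.data = self.data.assign(response=labels)
        if "os_time" in self.data.columns:
            t = pd.to_numeric(self.data["os_time"], errors="coerce")
            if np.any(t.dropna() <= 0):
                raise ValidationError("os_time must be > 0 whenever present")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def response_mask(self) -> pd.Series:
        """Boolean per sample: True = responder (PRCR), False = PDSD.

        Samples with response NA are dropped.
        """
        resp = self.data["response"]
        keep = resp.isin(["PRCR", "PDSD"])
        return (resp[keep] == "PRCR").astype(bool)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways), e.g. MSigDB hallmark / KEGG / Reactome."""

    sets: dict[str, frozenset[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, genes in self.sets.items():
            fs = frozenset(str(g) for g in genes)
            if not fs:
                raise ValidationError(f"gene set {name!r} is empty")
            if name in clean:
                raise ValidationError(f"duplicate pathway name {name!r}")
            clean[name] = fs
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class InteractionTable:
    """Undirected PPI edge list with STRING-style combined scores (0-1000).

    Self-loops are dropped; duplicate undirected pairs collapse keeping the
    maximum score.
    """

    edges: pd.DataFrame  # columns gene_a, gene_b, combined_score

    def __post_init__(self) -> None:
        df = self.edges.copy()
        if df.empty:
            self.edges = pd.DataFrame(columns=["gene_a", "gene_b", "combined_score"])
            return
        df["gene_a"] = df["gene_a"].astype(str)
        df["gene_b"] = df["gene_b"].astype(str)
        score = df["combined_score"]
        as_float = pd.to_numeric(score, errors="raise").astype(float)
        if np.any(as_float != np.round(as_float)):
            raise ValidationError("combined_score must be integer-valued")
        df["combined_score"] = as_float.astype(int)
        df = df[df["gene_a"] != df["gene_b"]]
        lo = np.minimum(df["gene_a"], df["gene_b"])
        hi = np.maximum(df["gene_a"], df["gene_b"])
        df = df.assign(gene_a=lo, gene_b=hi)
        df = (
            df.groupby(["gene_a", "gene_b"], as_index=False)["combined_score"]
            .max()
            .sort_values(["gene_a", "gene_b"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.edges = df

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def nodes(self) -> list[str]:
        return sorted(set(self.edges["gene_a"]) | set(self.edges["gene_b"]))

    def to_graph(self):
        import networkx as nx

        g = nx.Graph()
        for a, b, s in self.edges.itertuples(index=False):
            g.add_edge(a, b, combined_score=int(s))
        return g


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------


def _header_comment(params: dict | None = None) -> str:
    from irapass import __version__

    kv = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    return f"# {_TOOL_TAG} v{__version__}" + (f" {kv}" if kv else "")


def _read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def _write_tsv(df: pd.DataFrame, path, params: dict | None, index_label: str) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(params) + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label, lineterminator="\n")


def read_pdui_table(path, dialect: str = "canonical") -> PduiTable:
    """Read a PDUI matrix.

    ``canonical``: first column holds ``GENE|chrom|site`` ids, remaining
    columns are per-sample PDUI.  ``dapars2``: first column holds DaPars2's
    four-field ``transcript|GENE|chrom|strand`` ids, a
    ``Predicted_Proximal_APA`` column holds the proximal site, any
    ``fit_value``/``Loci`` columns are ignored, and multiple transcripts of
    one gene collapse to the transcript with the fewest missing PDUI values.
    """
    if dialect not in ("canonical", "dapars2"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = _read_tsv(path)
    if dialect == "canonical":
        for i, ev in enumerate(raw.index):
            try:
                EventId.parse(str(ev))
            except ParseError as exc:
                raise ParseError(f"row {i + 1}: {exc}") from exc
        return PduiTable(raw)

    if "Predicted_Proximal_APA" not in raw.columns:
        raise ParseError("dapars2 dialect requires a Predicted_Proximal_APA column")
    sites = pd.to_numeric(raw["Predicted_Proximal_APA"], errors="raise").astype(int)
    drop = [c for c in ("Predicted_Proximal_APA", "fit_value", "Loci") if c in raw.columns]
    values = raw.drop(columns=drop)
    records = []
    for i, (tx_id, site) in enumerate(sites.items()):
        parts = str(tx_id).split("|")
        if len(parts) != 4:
            raise ParseError(
                f"row {i + 1}: dapars2 id {tx_id!r} must be transcript|GENE|chrom|strand"
            )
        _tx, gene, chrom, _strand = parts
        ev = EventId(gene_symbol=gene, chrom=chrom, proximal_site=int(site))
        row = values.iloc[i]
        records.append((gene, int(row.isna().sum()), str(ev), row))
    # one row per gene: keep the transcript with the fewest missing values,
    # first occurrence on ties (DaPars2 reports transcripts in a stable order)
    best: dict[str, tuple[int, str, pd.Series]] = {}
    for gene, n_missing, ev_str, row in records:
        if gene not in best or n_missing < best[gene][0]:
            best[gene] = (n_missing, ev_str, row)
    out = pd.DataFrame({ev: row for _m, ev, row in best.values()}).T
    out.columns = values.columns
    logger.info(
        "dapars2 ingest: %d transcript rows collapsed to %d gene-level events",
        len(records), len(out),
    )
    return PduiTable(out)


def write_pdui_table(table: PduiTable, path, params: dict | None = None) -> None:
    _write_tsv(table.data, path, params, index_label="event_id")


def read_expression(path) -> ExpressionTable:
    return ExpressionTable(_read_tsv(path))


def write_expression(table: ExpressionTable, path, params: dict | None = None) -> None:
    _write_tsv(table.data, path, params, index_label="gene_id")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, keep_default_na=False,
                     na_values=[""])
    if "response" in df.columns:
        df["response"] = df["response"].replace("", "NA").fillna("NA")
    for col in df.columns:
        if col != "response":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path, params: dict | None = None) -> None:
    _write_tsv(table.data, path, params, index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, genes, tab-separated."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"line {lineno}: GMT lines need >= 3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"line {lineno}: duplicate pathway name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets=sets, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.provenance or 'na'}\t{genes}\n")


def read_interactions(path, min_score: int = 700) -> InteractionTable:
    """Read a STRING-style edge TSV, keeping edges with score > ``min_score``.

    The filter is strictly greater-than, and undirected duplicates keep the
    maximum score (applied before filtering).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        return InteractionTable(pd.DataFrame(columns=["gene_a", "gene_b", "combined_score"]))
    if df.shape[1] < 3:
        raise ParseError("interaction TSV needs two node columns and a score column")
    df = df.iloc[:, :3]
    df.columns = ["gene_a", "gene_b", "combined_score"]
    table = InteractionTable(df)
    kept = table.edges[table.edges["combined_score"] > min_score].reset_index(drop=True)
    return InteractionTable(kept)


def write_interactions(table: InteractionTable, path, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(params) + "\n")
        table.edges.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_gene_list(path) -> list[str]:
    """Plain text, one gene symbol per line (e.g. the APA-factor list)."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    _check_unique(genes, "genes in list")
    return genes


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_result_table(df: pd.DataFrame, path, params: dict | None = None,
                       index_label: str = "event_id") -> None:
    """Generic writer for result frames, with a parameter-recording header."""
    _write_tsv(df, path, params, index_label=index_label)


def read_result_table(path) -> pd.DataFrame:
    return _read_tsv(path)


def align_samples(*tables) -> list[str]:
    """Intersect sample ids across tables, preserving the first table's order."""
    ids = [list(t.sample_ids) for t in tables]
    common = set(ids[0])
    for other in ids[1:]:
        common &= set(other)
    ordered = [s for s in ids[0] if s in common]
    if not ordered:
        raise ValidationError("tables share no samples")
    dropped = sum(len(i) for i in ids) - len(ordered) * len(ids)
    if dropped:
        logger.info("sample alignment: %d shared samples, %d table entries dropped",
                    len(ordered), dropped)
    return ordered
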