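"""Read/write sample x taxon count tables, metadata and network exports.

The canonical in-memory orientation is samples as rows, taxa as columns.
TSV tables may come either way round; a header heuristic (overridable)
decides whether to transpose on read.  A minimal dense BIOM-JSON
reader/writer is provided for interoperability with QIIME-style exports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .errors import EmptyNetworkError, ParseError, ValidationError

# header cells that mark a taxa-as-rows table (BIOM/QIIME exports)
_TAXA_ROW_HINTS = {
    "#otu id", "otu id", "otu_id", "otu", "asv", "asv_id", "#asv id",
    "taxon", "taxon_id", "feature id", "feature_id", "#feature id",
}
_SAMPLE_ROW_HINTS = {"sample", "sample_id", "#sampleid", "sample id"}

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


@dataclass
class AsvTable:
    """A validated sample x taxon count matrix with optional annotations.

    Attributes
    ----------
    counts : (n_samples, n_taxa) integer array, all entries >= 0.
    sample_ids, taxon_ids : ordered unique labels for rows / columns.
    taxonomy : per-taxon semicolon-delimited rank string (may be empty).
    metadata : per-sample table indexed by sample id (optional).
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    taxonomy: dict[str, str] = field(default_factory=dict)
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon ids")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValidationError("counts must be integral")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        self.counts = counts.astype(np.int64)
        if self.metadata is not None:
            self.metadata = self.metadata.loc[self.sample_ids]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids,
                            columns=self.taxon_ids)

    def subset_samples(self, sample_ids: list[str]) -> "AsvTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AsvTable(self.counts[idx], list(sample_ids), list(self.taxon_ids),
                        dict(self.taxonomy),
                        None if self.metadata is None else self.metadata.loc[list(sample_ids)])

    def subset_taxa(self, taxon_ids: list[str]) -> "AsvTable":
        pos = {t: i for i, t in enumerate(self.taxon_ids)}
        idx = [pos[t] for t in taxon_ids]
        taxo = {t: self.taxonomy[t] for t in taxon_ids if t in self.taxonomy}
        return AsvTable(self.counts[:, idx], list(self.sample_ids),
                        list(taxon_ids), taxo, self.metadata)


@dataclass
class EnvMatrix:
    """Samples x environmental-variables real matrix (stage, plant richness,
    SOC, TN, NO3, NH4, TP, EC, pH, SM, C:N, C:P, N:P ...)."""

    values: np.ndarray
    sample_ids: list[str]
    variables: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.variables)):
            raise ValidationError("env matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("env matrix contains missing/non-finite values")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.variables)


def parse_taxonomy_string(tax: str) -> dict[str, str]:
    """Split a semicolon-delimited rank string into named ranks.

    Unknown/absent ranks come back as empty strings; 'k__'-style prefixes
    are stripped.
    """
    parts = [p.strip() for p in tax.split(";")] if tax else []
    out = {}
    for rank, part in zip(TAXONOMY_RANKS, parts):
        if len(part) > 2 and part[1:3] == "__":
            part = part[3:]
        out[rank] = part
    for rank in TAXONOMY_RANKS[len(parts):]:
        out[rank] = ""
    return out


def _validate_count_frame(df: pd.DataFrame, path: str) -> pd.DataFrame:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        row, col = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell at row {df.index[row]!r}, "
            f"column {df.columns[col]!r}"
        )
    return numeric


def read_asv_table(path, fmt: str = "tsv", orientation: str = "auto") -> AsvTable:
    """Read an ASV table from ``tsv`` or ``biom-json``.

    orientation: 'auto' (header heuristic), 'samples' (rows are samples)
    or 'taxa' (rows are taxa; table is transposed on read).
    """
    if fmt == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise ParseError(f"{path}: {exc}") from exc
        df = _validate_count_frame(df, str(path))
        header = (df.index.name or "").strip().lower()
        if orientation == "auto":
            if header in _TAXA_ROW_HINTS:
                orientation = "taxa"
            elif header in _SAMPLE_ROW_HINTS:
                orientation = "samples"
            else:
                orientation = "samples"
        if orientation == "taxa":
            df = df.T
        elif orientation != "samples":
            raise ValidationError(f"unknown orientation {orientation!r}")
        return AsvTable(df.to_numpy(), list(df.index.astype(str)),
                        list(df.columns.astype(str)))
    if fmt == "biom-json":
        return _read_biom_json(path)
    raise ValidationError(f"unknown table format {fmt!r}")


def _read_biom_json(path) -> AsvTable:
    """Minimal dense parse of the BIOM 1.0 JSON format.

    BIOM stores observations (taxa) as rows and samples as columns; the
    matrix is transposed into the canonical orientation.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    try:
        n_obs, n_samp = doc["shape"]
        taxon_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        mat = np.zeros((n_obs, n_samp))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
        else:
            mat[:] = np.asarray(doc["data"])
        taxonomy = {}
        for r in doc["rows"]:
            md = r.get("metadata") or {}
            tax = md.get("taxonomy", "")
            if isinstance(tax, (list, tuple)):
                tax = ";".join(tax)
            if tax:
                taxonomy[r["id"]] = tax
    except (KeyError, TypeError, IndexError) as exc:
        raise ParseError(f"{path}: malformed BIOM document ({exc})") from exc
    return AsvTable(mat.T, sample_ids, taxon_ids, taxonomy)


def write_asv_table(table: AsvTable, path, fmt: str = "tsv") -> None:
    if fmt == "tsv":
        df = table.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
    elif fmt == "biom-json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "type": "OTU table",
            "matrix_type": "dense",
            "shape": [table.n_taxa, table.n_samples],
            "rows": [
                {"id": t, "metadata":
                    ({"taxonomy": table.taxonomy[t]} if t in table.taxonomy else None)}
                for t in table.taxon_ids
            ],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.T.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValidationError(f"unknown table format {fmt!r}")


def read_metadata(path) -> pd.DataFrame:
    """Per-sample metadata TSV keyed by sample id (first column)."""
    try:
        return pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_env(path) -> EnvMatrix:
    df = read_metadata(path)
    vals = df.apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        raise ValidationError(f"{path}: environmental table has missing values")
    return EnvMatrix(vals.to_numpy(), list(df.index.astype(str)),
                     list(df.columns.astype(str)))


def rarefy(table: AsvTable, depth: int, seed: int) -> AsvTable:
    """Randomly subsample every sample to ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning.
    Reproducible given ``seed`` (multivariate hypergeometric draws).
    """
    if depth is None or int(depth) <= 0:
        raise ValidationError("rarefaction depth must be a positive integer")
    depth = int(depth)
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    if not np.all(keep):
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}",
            stacklevel=2)
    rows = []
    kept_ids = []
    for i, sid in enumerate(table.sample_ids):
        if not keep[i]:
            continue
        row = table.counts[i]
        if totals[i] == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
        kept_ids.append(sid)
    if not rows:
        raise ValidationError(f"no sample reaches depth {depth}")
    meta = None if table.metadata is None else table.metadata.loc[kept_ids]
    return AsvTable(np.asarray(rows), kept_ids, list(table.taxon_ids),
                    dict(table.taxonomy), meta)


def write_network(net, path, fmt: str = "tsv") -> None:
    """Export a co-occurrence network as an edge-list TSV or GraphML.

    The edge list carries source, target, correlation and sign columns;
    GraphML keeps the same attributes plus node annotations, and is
    loadable by Cytoscape/Gephi.
    """
    graph = getattr(net, "graph", None)
    if not isinstance(graph, nx.Graph):
        graph = net
    if graph.number_of_edges() == 0:
        raise EmptyNetworkError("refusing to export a network with no edges")
    if fmt == "tsv":
        rows = [
            {"source": u, "target": v,
             "correlation": d.get("correlation", np.nan),
             "sign": d.get("sign", "+")}
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "correlation", "sign"]
                     ).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValidationError(f"unknown network format {fmt!r}")


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
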