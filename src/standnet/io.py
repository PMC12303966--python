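"""Readers and writers for the pipeline's delimited-text artifacts.

Soil tables are TSV with a header row (sample_id, stand, plot, indicators).
Abundance tables are TSV with ASVs as rows: asv_id, one column per sample,
then taxonomy (semicolon-delimited ranks) and domain columns; sample
metadata (stand, plot) travels in a sidecar ``<name>.samples.tsv``.
All writers round-trip exactly with the readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from standnet.tables import AbundanceTable, validate_soil_table


def write_soil_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_soil_table(path) -> pd.DataFrame:
    """Read and validate a soil-property table."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    sep = "\t" if path.suffix != ".csv" else ","
    table = pd.read_csv(path, sep=sep, index_col="sample_id")
    return validate_soil_table(table)


def write_abundance_table(table: AbundanceTable, path) -> None:
    path = Path(path)
    out = table.counts.T.copy()
    out["taxonomy"] = table.taxonomy.reindex(out.index)
    out["domain"] = table.domain
    out.to_csv(path, sep="\t", index_label="asv_id")
    if len(table.metadata):
        table.metadata.to_csv(
            path.with_suffix(".samples.tsv"), sep="\t", index_label="sample_id"
        )


def read_abundance_table(path) -> AbundanceTable:
    """Read an ASV table (ASVs as rows) plus its sample-metadata sidecar."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    raw = pd.read_csv(path, sep="\t", index_col="asv_id")
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate ASV ids: {dups}")
    if "taxonomy" not in raw.columns or "domain" not in raw.columns:
        raise ValueError("abundance table needs taxonomy and domain columns")
    taxonomy = raw["taxonomy"].astype(str).rename(None)
    domains = raw["domain"].unique()
    if len(domains) != 1:
        raise ValueError(f"mixed domain tags in one file: {sorted(domains)}")
    counts = raw.drop(columns=["taxonomy", "domain"])
    bad = counts.columns[
        ~counts.apply(lambda c: pd.api.types.is_integer_dtype(c)).to_numpy()
    ]
    for col in bad:
        try:
            counts[col] = counts[col].astype("int64")
        except (ValueError, TypeError) as err:
            raise ValueError(f"non-integer counts in sample {col!r}") from err

    sidecar = path.with_suffix(".samples.tsv")
    metadata = (
        pd.read_csv(sidecar, sep="\t", index_col="sample_id")
        if sidecar.exists()
        else pd.DataFrame()
    )
    samples = counts.T
    samples.index.name = "sample_id"
    samples.columns.name = None
    taxonomy.index.name = None
    return AbundanceTable(
        counts=samples,
        taxonomy=taxonomy,
        domain=str(domains[0]),
        metadata=metadata,
    )


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [
        {
            "node1": u,
            "node2": v,
            "r": d.get("r"),
            "p": d.get("p"),
            "q": d.get("q"),
            "sign": d.get("sign"),
        }
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node1", "node2", "r", "p", "q", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
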