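"""File formats: expression TSV, partition TSV, edge lists, JSON reports.

Canonical formats (all plain text):

- expression TSV: header row of sample ids, first column gene ids,
  tab-separated numeric cells; duplicate gene ids and missing values are
  errors (with coordinates) rather than silent repairs.
- partition TSV: two columns, ``gene_id<TAB>module``.
- edge list TSV: ``source<TAB>target<TAB>weight``, one row per unordered
  pair at or above the export threshold (importable by Cytoscape).
- JSON reports embed the config hash and seeds that produced them, so a
  run can be reproduced exactly from its own output.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import RunConfig
from .network import WeightedNetwork
from .partition import GRAY_LABEL, ModulePartition

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_partition_tsv",
    "write_partition_tsv",
    "write_edge_list",
    "write_graphml",
    "write_json_report",
]


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV.

    Errors name the offending gene/line: duplicate gene ids, missing
    values (with row/column coordinates), and non-numeric cells all
    raise rather than being coerced.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        line = int(np.flatnonzero(df.index == dup)[-1]) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: duplicate gene id {dup!r} (line {line})")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        gene = bad.index[0] if len(bad) else "?"
        raise ValueError(f"{path}: non-numeric cell in column {col!r} (gene {gene!r})")
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().values)
        gene, sample = df.index[rows[0]], df.columns[cols[0]]
        raise ValueError(f"{path}: missing value at gene {gene!r}, sample {sample!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return df.astype(float)


def write_expression_tsv(data: pd.DataFrame, path) -> None:
    data.to_csv(path, sep="\t", index_label="gene_id")


def read_partition_tsv(path, gray_label: str = GRAY_LABEL, min_size: int = 3) -> ModulePartition:
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: partition TSV needs two columns (gene_id, module)")
    if frame.iloc[:, 0].duplicated().any():
        dup = frame.iloc[:, 0][frame.iloc[:, 0].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene id {dup!r} in partition")
    return ModulePartition.from_frame(frame, gray_label=gray_label, min_size=min_size)


def write_partition_tsv(partition: ModulePartition, path) -> None:
    partition.to_frame().to_csv(path, sep="\t", index=False)


def write_edge_list(network: WeightedNetwork, path, threshold: float = 0.0) -> int:
    """Write source/target/weight rows for pairs with adjacency >= threshold.

    Returns the number of edges written.
    """
    a = network.adjacency
    ii, jj = np.triu_indices_from(a, k=1)
    keep = a[ii, jj] >= threshold
    n = 0
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for i, j in zip(ii[keep], jj[keep]):
            fh.write(f"{network.gene_ids[i]}\t{network.gene_ids[j]}\t{a[i, j]:.6g}\n")
            n += 1
    return n


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict("records"))
    return obj


def write_json_report(report: dict, path, cfg: RunConfig | None = None) -> None:
    """Serialise a report with its provenance (config hash + seeds).

    NaN markers become JSON nulls so the files stay strictly valid JSON.
    """
    payload = dict(report)
    if cfg is not None:
        payload["_provenance"] = {
            "config_hash": cfg.hash(),
            "config": cfg.to_dict(),
        }
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")
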