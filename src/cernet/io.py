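"""Plain-text readers and writers for the pipeline's standard formats.

Everything tabular is TSV; networks are written as SIF and GraphML; gene
sets as GMT (handled by :mod:`cernet.enrichment`). Floating-point columns
are written with a fixed ``%.6g`` format so that re-running a stage on
identical inputs yields byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .diffexpr import DERecord
from .expression import ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_interactions",
    "write_interactions",
    "write_table",
    "read_de_records",
    "write_de_records",
    "write_sif",
    "write_graphml",
]

FLOAT_FORMAT = "%.6g"


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_expression(
    matrix: ExpressionMatrix, expr_path: str | Path, samples_path: str | Path
) -> None:
    values = matrix.values.copy()
    values.index.name = values.index.name or "feature"
    values.to_csv(expr_path, sep="\t", float_format=FLOAT_FORMAT)
    samples = matrix.samples.copy()
    samples.index.name = samples.index.name or "sample"
    samples.to_csv(samples_path, sep="\t")


def read_expression(
    expr_path: str | Path, samples_path: str | Path
) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, samples)


def write_interactions(records: pd.DataFrame, path: str | Path) -> None:
    records[["mirna", "target", "database"]].to_csv(path, sep="\t", index=False)


def read_interactions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"mirna", "target", "database"}
    if set(df.columns) != expected:
        raise ValueError(
            f"interaction table needs columns {sorted(expected)}, "
            f"got {list(df.columns)}"
        )
    return df


def write_de_records(records: Iterable[DERecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "feature": r.feature,
                "class": r.feature_class,
                "log2fc": r.log2fc,
                "t": r.t,
                "p": r.p,
                "direction": r.direction,
            }
            for r in records
        ],
        columns=["feature", "class", "log2fc", "t", "p", "direction"],
    )
    write_table(df, path)


def read_de_records(path: str | Path) -> list[DERecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        DERecord(
            feature=str(r["feature"]),
            feature_class=str(r["class"]),
            log2fc=float(r["log2fc"]),
            p=float(r["p"]),
            direction=str(r["direction"]),
            t=float(r.get("t", float("nan"))),
        )
        for _, r in df.iterrows()
    ]


def write_sif(network: nx.Graph, path: str | Path) -> None:
    """Simple interaction format: source, edge kind, target (sorted)."""
    lines = []
    for a, b, data in network.edges(data=True):
        a, b = sorted((a, b))
        lines.append(f"{a}\t{data.get('kind', 'pp')}\t{b}")
    Path(path).write_text("\n".join(sorted(lines)) + ("\n" if lines else ""))


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    # rebuild with sorted nodes/edges so output order is deterministic
    g = nx.Graph()
    for n in sorted(network.nodes):
        g.add_node(n, **network.nodes[n])
    for a, b in sorted(tuple(sorted(e)) for e in network.edges):
        g.add_edge(a, b, **network.edges[a, b])
    nx.write_graphml(g, str(path))
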