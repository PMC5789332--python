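"""Gene-gene functional association network with regulation overlay.

Edges come from a STRING-format tab-separated export (``node1``,
``node2``, ``combined_score`` plus optional evidence-channel columns).
Scores are confidences in [0, 1]; the integer 0-999 export dialect is
auto-detected and rescaled.  Nodes are gene symbols after resolving
database aliases (the rat STRING export labels pyruvate kinase as
``LOC689343`` and triosephosphate isomerase by its Ensembl id).  After
annotation, every node carries a ``regulation`` attribute (up / down /
nc) and the conventional display colour (red / blue / grey).
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "DEFAULT_ALIASES",
    "REGULATION_COLORS",
    "load_interactions",
    "annotate_regulation",
    "export_graph",
    "read_graph",
]

DEFAULT_ALIASES = {
    "LOC689343": "Pk",
    "ENSRNOG00000015290": "Tpi",
}

REGULATION_COLORS = {"up": "red", "down": "blue", "nc": "grey"}


def _coerce_score(raw: str) -> float:
    value = float(raw)
    if value < 0:
        raise ValueError(f"negative score {value}")
    return value


def load_interactions(
    edge_tsv: str | Path,
    score_threshold: float = 0.4,
    aliases: dict[str, str] | None = None,
) -> nx.Graph:
    """Load a STRING-style edge list into an undirected graph.

    Edges below ``score_threshold`` (combined score, 0-1 scale) are
    dropped; duplicate edges collapse to the maximum score; self-loops
    are discarded.  Malformed rows warn individually and the file is
    rejected outright if more than 10% of its rows are malformed.
    """
    if aliases is None:
        aliases = DEFAULT_ALIASES
    path = Path(edge_tsv)
    rows: list[tuple[str, str, float, dict[str, float]]] = []
    malformed = 0
    total = 0
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"node1", "node2", "combined_score"} <= set(
            reader.fieldnames
        ):
            raise ValueError(
                f"{path}: expected columns node1, node2, combined_score; "
                f"got {reader.fieldnames}"
            )
        extra_cols = [
            c for c in reader.fieldnames if c not in ("node1", "node2", "combined_score")
        ]
        for lineno, record in enumerate(reader, start=2):
            total += 1
            try:
                n1 = aliases.get(record["node1"], record["node1"]).strip()
                n2 = aliases.get(record["node2"], record["node2"]).strip()
                if not n1 or not n2:
                    raise ValueError("empty node id")
                score = _coerce_score(record["combined_score"])
                channels = {c: float(record[c]) for c in extra_cols if record.get(c)}
            except (ValueError, TypeError, KeyError) as exc:
                malformed += 1
                warnings.warn(f"{path}:{lineno}: malformed row ({exc})", stacklevel=2)
                continue
            rows.append((n1, n2, score, channels))
    if total and malformed / total > 0.10:
        raise ValueError(
            f"{path}: {malformed}/{total} rows malformed (>10%); refusing to load"
        )

    # dialect detection: STRING text exports use integer scores 0-999
    integer_dialect = any(score > 1.0 for _, _, score, _ in rows)
    scale = 1000.0 if integer_dialect else 1.0

    graph = nx.Graph()
    for n1, n2, score, channels in rows:
        score /= scale
        channels = {k: v / scale for k, v in channels.items()}
        if not 0.0 <= score <= 1.0:
            warnings.warn(f"score {score} outside [0, 1] for ({n1}, {n2}); skipped",
                          stacklevel=2)
            continue
        if n1 == n2:
            continue
        if score < score_threshold:
            continue
        if graph.has_edge(n1, n2):
            if score > graph[n1][n2]["combined_score"]:
                graph[n1][n2].update(combined_score=score, **channels)
        else:
            graph.add_edge(n1, n2, combined_score=score, **channels)
    return graph


def annotate_regulation(
    graph: nx.Graph, detable: pd.DataFrame, group: str
) -> nx.Graph:
    """Set each node's ``regulation`` (and display colour) from DE calls.

    Genes absent from the DE table for the group are marked ``nc`` with a
    warning.  Topology is never modified.
    """
    sub = detable[detable["group"] == group].set_index("gene")
    missing = [n for n in graph.nodes if n not in sub.index]
    if missing:
        warnings.warn(
            f"{len(missing)} nodes absent from DE table for {group!r} "
            f"(e.g. {missing[:4]}); marked nc",
            stacklevel=2,
        )
    for node in graph.nodes:
        call = str(sub.loc[node, "call"]) if node in sub.index else "nc"
        graph.nodes[node]["regulation"] = call
        graph.nodes[node]["color"] = REGULATION_COLORS[call]
    return graph


def export_graph(graph: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write the annotated graph (GraphML is the lossless round-trip form;
    TSV is a flat edge table with endpoint regulation columns)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "tsv":
        rows = []
        for n1, n2, attrs in graph.edges(data=True):
            row = {"node1": n1, "node2": n2, "combined_score": attrs["combined_score"]}
            row["node1_regulation"] = graph.nodes[n1].get("regulation", "")
            row["node2_regulation"] = graph.nodes[n2].get("regulation", "")
            rows.append(row)
        pd.DataFrame(
            rows, columns=["node1", "node2", "combined_score",
                           "node1_regulation", "node2_regulation"]
        ).to_csv(path, sep="\t", index=False, lineterminator="\n")
    else:
        raise ValueError(f"unknown format {format!r}; use 'graphml' or 'tsv'")


def read_graph(path: str | Path) -> nx.Graph:
    """Read back a GraphML export (inverse of :func:`export_graph`)."""
    return nx.read_graphml(Path(path), node_type=str)
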