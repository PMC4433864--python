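"""Readers and writers for the plain-text formats the pipeline exchanges.

All files are UTF-8, tab-separated, LF line endings:

* **edge list** — two columns ``u<TAB>v``, one interaction per line; extra
  columns are ignored.  Self-loops and duplicate pairs (either orientation)
  are dropped on read and counted in an :class:`EdgeListReport`.
* **expression** — header ``gene<TAB><label>:<rep>...``; a bare ``<label>``
  is treated as replicate 1.  Replicate columns of one time point must be
  contiguous; they are collapsed on read (mean or first).
* **annotations** — two columns ``protein<TAB>term``, many-to-many.
* **complexes** — one complex per line, members tab-separated.
* **protein list** — one identifier per line (core/attachment rosters).

Writers emit deterministically sorted output so that ``write(read(f))`` is
content-identical on valid input and regeneration is byte-stable.
Identifiers are opaque strings; case is preserved and no gene/protein
namespace mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "EdgeListReport",
    "read_edge_list",
    "write_edge_list",
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_annotations",
    "read_complexes",
    "write_complexes",
    "read_protein_list",
    "write_protein_list",
    "read_combined",
    "write_combined",
]

ComplexSet = list  # ordered list of frozenset[str]


@dataclass(frozen=True)
class EdgeListReport:
    """Accounting of an edge-list load: ``lines = kept + self_loops + duplicates``."""

    lines: int
    kept: int
    self_loops: int
    duplicates: int

    def __post_init__(self) -> None:
        if self.lines != self.kept + self.self_loops + self.duplicates:
            raise ValueError("edge-list report does not conserve line counts")


def _fields(line: str, path, lineno: int, minimum: int) -> list[str]:
    parts = line.split("\t")
    if len(parts) < minimum or any(p == "" for p in parts[:minimum]):
        raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
    return parts


def read_edge_list(path) -> tuple[nx.Graph, EdgeListReport]:
    """Read a two-column interaction file into a simple undirected graph.

    Self-loops are dropped (a node seen *only* in self-loops does not enter
    the graph); duplicate pairs in either orientation are collapsed.
    Returns the graph together with an :class:`EdgeListReport`.
    """
    graph = nx.Graph()
    lines = kept = loops = dups = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\n").rstrip("\r")
            u, v = _fields(line, path, lineno, 2)[:2]
            lines += 1
            if u == v:
                loops += 1
                continue
            if graph.has_edge(u, v):
                dups += 1
                continue
            graph.add_edge(u, v)
            kept += 1
    if lines == 0:
        raise ValueError(f"{path}: empty edge list")
    return graph, EdgeListReport(lines=lines, kept=kept, self_loops=loops, duplicates=dups)


def write_edge_list(graph: nx.Graph, path) -> None:
    pairs = sorted(tuple(sorted(edge)) for edge in graph.edges())
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for u, v in pairs:
            handle.write(f"{u}\t{v}\n")


def _parse_sample_label(column: str) -> tuple[str, str]:
    label, _, rep = column.partition(":")
    return label, rep or "1"


def read_expression(path, replicate_policy: str = "mean") -> pd.DataFrame:
    """Read a gene × sample expression table, collapsing replicates.

    The header row names the samples as ``label:rep`` (bare labels mean
    replicate 1); the first column holds gene identifiers.  Returns a
    gene × time-point DataFrame of floats, replicates collapsed per
    ``replicate_policy`` (``mean`` or ``first``).

    Raises ``ValueError`` on duplicate genes, non-numeric or empty cells,
    negative values, or non-contiguous replicate groups.
    """
    if replicate_policy not in ("mean", "first"):
        raise ValueError(f"unknown replicate policy {replicate_policy!r}")
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").rstrip("\r")
        if not header:
            raise ValueError(f"{path}: empty expression file")
        columns = header.split("\t")
        if len(columns) < 2:
            raise ValueError(f"{path}: header must name a gene column and >=1 sample")
        sample_labels = [_parse_sample_label(c)[0] for c in columns[1:]]
        # replicate columns of a time point must sit next to each other
        label_order: list[str] = []
        for label in sample_labels:
            if label not in label_order:
                label_order.append(label)
        seen_closed: set[str] = set()
        previous = None
        for label in sample_labels:
            if label != previous:
                if label in seen_closed:
                    raise ValueError(f"{path}: replicate columns for {label!r} are not contiguous")
                if previous is not None:
                    seen_closed.add(previous)
                previous = label
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(handle, 2):
            line = raw.rstrip("\n").rstrip("\r")
            parts = _fields(line, path, lineno, len(columns))
            if len(parts) != len(columns):
                raise ValueError(f"{path}: line {lineno} has {len(parts)} fields, expected {len(columns)}")
            gene = parts[0]
            if gene in genes:
                raise ValueError(f"{path}: duplicate gene {gene!r} at line {lineno}")
            values = []
            for column, cell in zip(columns[1:], parts[1:]):
                try:
                    value = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} for gene {gene!r}, sample {column!r}"
                    ) from None
                if not value >= 0:
                    raise ValueError(f"{path}: negative/NaN value for gene {gene!r}, sample {column!r}")
                values.append(value)
            genes.append(gene)
            rows.append(values)
    if not genes:
        raise ValueError(f"{path}: expression file has no gene rows")
    wide = pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=sample_labels)
    if replicate_policy == "mean":
        collapsed = wide.T.groupby(level=0, sort=False).mean().T
    else:
        collapsed = wide.T.groupby(level=0, sort=False).first().T
    return collapsed[label_order]


def write_expression(series: pd.DataFrame, path) -> None:
    """Write a collapsed gene × time-point table (bare labels, replicate 1)."""
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("gene\t" + "\t".join(str(c) for c in series.columns) + "\n")
        for gene, row in series.iterrows():
            handle.write(str(gene) + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def read_annotations(path) -> dict[str, set[str]]:
    """Read a two-column ``protein<TAB>term`` file into protein → term sets."""
    annotations: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\n").rstrip("\r")
            protein, term = _fields(line, path, lineno, 2)[:2]
            annotations.setdefault(protein, set()).add(term)
    return annotations


def write_annotations(annotations: dict[str, set[str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for protein in sorted(annotations):
            for term in sorted(annotations[protein]):
                handle.write(f"{protein}\t{term}\n")


def read_complexes(path) -> ComplexSet:
    """Read one complex per line (tab-separated members, size >= 2)."""
    complexes: ComplexSet = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\n").rstrip("\r")
            members = _fields(line, path, lineno, 1)
            if any(m == "" for m in members):
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            if len(set(members)) != len(members):
                raise ValueError(f"{path}: duplicate member in complex at line {lineno}")
            if len(members) < 2:
                raise ValueError(f"{path}: complex at line {lineno} has fewer than 2 members")
            complexes.append(frozenset(members))
    return complexes


def write_complexes(complexes: ComplexSet, path) -> None:
    """Write one complex per line, members sorted lexicographically."""
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for cluster in complexes:
            handle.write("\t".join(sorted(cluster)) + "\n")


def read_protein_list(path) -> list[str]:
    proteins: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, 1):
            name = raw.rstrip("\n").rstrip("\r")
            if not name:
                raise ValueError(f"{path}: blank line {lineno}")
            proteins.append(name)
    return proteins


def write_protein_list(proteins, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for name in proteins:
            handle.write(f"{name}\n")


def read_combined(path) -> nx.Graph:
    """Read a 4-column ``u v weight origin`` weighted-network file."""
    graph = nx.Graph()
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\n").rstrip("\r")
            u, v, weight, origin = _fields(line, path, lineno, 4)[:4]
            if origin not in ("ppi", "go_added", "both"):
                raise ValueError(f"{path}: unknown edge origin {origin!r} at line {lineno}")
            graph.add_edge(u, v, weight=int(weight), origin=origin)
    graph.graph["added_edge_count"] = sum(
        1 for _, _, d in graph.edges(data=True) if d["origin"] == "go_added"
    )
    return graph


def write_combined(graph: nx.Graph, path) -> None:
    rows = sorted((min(u, v), max(u, v), d["weight"], d["origin"]) for u, v, d in graph.edges(data=True))
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for u, v, weight, origin in rows:
            handle.write(f"{u}\t{v}\t{weight}\t{origin}\n")
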