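"""Synthetic fixture generator: planted complexes with coherent expression and GO.

Emulates the three inputs the pipeline needs — a static PPI network, a
time-course expression matrix and a protein→GO-slim annotation map —
together with the planted ground-truth complexes and core/attachment
rosters, so every stage of the pipeline is testable without any external
download.

The model is a planted-partition graph with condition structure:

* each of ``n_complexes`` complexes is a ``p_in``-dense subgraph over its
  members; all remaining pairs (cross-complex and background) get an edge
  with probability ``p_out`` (``0 <= p_out < p_in <= 1``);
* members share one private GO-slim term, carried by each member with
  probability ``fidelity``; background proteins carry one of
  ``n_decoy_terms`` decoy terms;
* expression is a two-level step function: a member's gene takes the value
  ``high`` during its complex's active stages and ``low`` otherwise, so the
  value >= own-mean activity rule holds exactly during active stages (a
  complex active at every stage is flat at ``high`` and active everywhere);
  optional Gaussian replicate noise of width ``noise_sigma`` can be
  overlaid (it weakens that exact guarantee);
* a ``background_offstage_frac`` fraction of background genes is expressed
  only at the last stage, i.e. inactive at every earlier stage, which is
  what makes a dynamic network built at an early stage genuinely cleaner
  than the static one;
* the remaining background genes get incoherent uniform expression.

One integer seed fixes every random draw; regenerating with the same spec
writes byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io

__all__ = ["SyntheticSpec", "SyntheticData", "generate", "write_fixtures"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted benchmark; defaults are the study conditions."""

    n_complexes: int = 20
    size_range: tuple = (3, 10)
    n_background: int = 200
    p_in: float = 0.9
    p_out: float = 0.01
    n_stages: int = 3
    n_replicates: int = 1
    fidelity: float = 0.9
    n_decoy_terms: int = 20
    background_offstage_frac: float = 0.0
    noise_sigma: float = 0.0
    high: float = 10.0
    low: float = 2.0
    active_stages: tuple | None = None  # per-complex tuples of 0-based stage indices
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.size_range
        if not (3 <= lo <= hi):
            raise ValueError("size_range must satisfy 3 <= lo <= hi")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if not 0.0 <= self.fidelity <= 1.0:
            raise ValueError("fidelity must lie in [0, 1]")
        if not 0.0 <= self.background_offstage_frac <= 1.0:
            raise ValueError("background_offstage_frac must lie in [0, 1]")
        if self.n_complexes < 1 or self.n_background < 0:
            raise ValueError("need >=1 complex and >=0 background proteins")
        if self.n_stages < 1 or self.n_replicates < 1:
            raise ValueError("need >=1 stage and >=1 replicate")
        if not 0.0 <= self.low < self.high:
            raise ValueError("need 0 <= low < high")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.active_stages is not None:
            if len(self.active_stages) != self.n_complexes:
                raise ValueError("active_stages must list one schedule per complex")
            for schedule in self.active_stages:
                if not schedule:
                    raise ValueError("every complex needs >=1 active stage")
                if any(not 0 <= s < self.n_stages for s in schedule):
                    raise ValueError("active stage index out of range")


@dataclass
class SyntheticData:
    """Everything :func:`generate` plants, in the pipeline's native containers."""

    spec: SyntheticSpec
    static: nx.Graph
    expression: pd.DataFrame            # replicate-collapsed genes x stages
    replicate_expression: pd.DataFrame  # genes x (stage, replicate) as written
    annotations: dict
    complexes: list                     # ground truth, list of frozenset
    schedules: list                     # per-complex tuple of active stage indices
    core: list
    attachment: list
    stage_labels: list = field(default_factory=list)

    def ground_truth_at(self, stage: str) -> list:
        """Planted complexes scheduled active at a stage label."""
        index = self.stage_labels.index(stage)
        return [
            cluster
            for cluster, schedule in zip(self.complexes, self.schedules)
            if index in schedule
        ]


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Draw one synthetic benchmark from a spec (deterministic in ``spec.seed``)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.size_range
    sizes = [int(s) for s in rng.integers(lo, hi + 1, size=spec.n_complexes)]

    complexes = []
    for c, size in enumerate(sizes):
        complexes.append(frozenset(f"C{c + 1:02d}P{m + 1:02d}" for m in range(size)))
    members = sorted(set().union(*complexes))
    background = [f"B{k + 1:03d}" for k in range(spec.n_background)]
    nodes = members + background
    member_of = {p: c for c, cluster in enumerate(complexes) for p in cluster}

    static = nx.Graph()
    static.add_nodes_from(nodes)
    for u, v in combinations(nodes, 2):
        same = member_of.get(u) is not None and member_of.get(u) == member_of.get(v)
        p = spec.p_in if same else spec.p_out
        if rng.random() < p:
            static.add_edge(u, v)

    schedules = (
        [tuple(sorted(s)) for s in spec.active_stages]
        if spec.active_stages is not None
        else [tuple(range(spec.n_stages))] * spec.n_complexes
    )
    stage_labels = [f"t{s + 1}" for s in range(spec.n_stages)]

    n_offstage = round(spec.background_offstage_frac * spec.n_background)
    base = np.empty((len(nodes), spec.n_stages))
    for row, node in enumerate(nodes):
        c = member_of.get(node)
        if c is not None:
            schedule = set(schedules[c])
            base[row] = [spec.high if s in schedule else spec.low for s in range(spec.n_stages)]
        elif node in set(background[:n_offstage]):
            profile = [spec.low] * spec.n_stages
            profile[-1] = spec.high
            base[row] = profile
        else:
            base[row] = rng.uniform(spec.low, spec.high, size=spec.n_stages)

    replicate_columns = [
        (label, rep + 1) for label in stage_labels for rep in range(spec.n_replicates)
    ]
    values = np.repeat(base, spec.n_replicates, axis=1)
    if spec.noise_sigma > 0:
        values = np.clip(values + rng.normal(0.0, spec.noise_sigma, values.shape), 0.0, None)
    replicate_expression = pd.DataFrame(
        values,
        index=pd.Index(nodes, name="gene"),
        columns=pd.MultiIndex.from_tuples(replicate_columns, names=["stage", "replicate"]),
    )
    expression = replicate_expression.T.groupby(level="stage", sort=False).mean().T

    annotations: dict[str, set] = {}
    for c, cluster in enumerate(complexes):
        term = f"GO:CPLX{c + 1:03d}"
        for protein in sorted(cluster):
            if rng.random() < spec.fidelity:
                annotations.setdefault(protein, set()).add(term)
    if spec.n_decoy_terms > 0:
        for protein in background:
            decoy = int(rng.integers(spec.n_decoy_terms))
            annotations.setdefault(protein, set()).add(f"GO:DECOY{decoy + 1:02d}")

    core: list = []
    attachment: list = []
    for cluster in complexes:
        ordered = sorted(cluster)
        split = (len(ordered) + 1) // 2
        core.extend(ordered[:split])
        attachment.extend(ordered[split:])

    return SyntheticData(
        spec=spec,
        static=static,
        expression=expression,
        replicate_expression=replicate_expression,
        annotations=annotations,
        complexes=complexes,
        schedules=schedules,
        core=core,
        attachment=attachment,
        stage_labels=stage_labels,
    )


def write_fixtures(data: SyntheticData, out_dir) -> dict:
    """Write all five artifacts through the package writers; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "edges.tsv",
        "expression": out / "expression.tsv",
        "annotations": out / "annotations.tsv",
        "complexes": out / "complexes.tsv",
        "core": out / "core.txt",
        "attachment": out / "attachment.txt",
    }
    io.write_edge_list(data.static, paths["edges"])
    with open(paths["expression"], "w", encoding="utf-8", newline="\n") as handle:
        header = [f"{label}:{rep}" for label, rep in data.replicate_expression.columns]
        handle.write("gene\t" + "\t".join(header) + "\n")
        for gene, row in data.replicate_expression.iterrows():
            handle.write(str(gene) + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")
    io.write_annotations(data.annotations, paths["annotations"])
    io.write_complexes(data.complexes, paths["complexes"])
    io.write_protein_list(data.core, paths["core"])
    io.write_protein_list(data.attachment, paths["attachment"])
    return paths
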