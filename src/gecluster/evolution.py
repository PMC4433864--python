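"""Cross-condition complex-evolution analysis.

Given complex sets predicted on a series of condition-specific networks
(e.g. successive ethanol stages of a fermentation), two questions are
asked: which complexes persist between conditions, and how the core /
attachment composition of the complement changes.

Complex persistence reuses the evaluation matcher: complexes A (stage s)
and B (stage t) are related when M_Score(A, B) >= M_thres, the same 0.2
default as complex-level evaluation.  Core and attachment status is
caller-supplied (an external classification of complex subunits into
always-present functional cores vs. isoform-specific modifiers); the
"complex number" of a protein is the number of predicted complexes that
contain it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

from .evaluation import m_score

__all__ = ["EvolutionMap", "relate", "CompositionReport", "composition"]


@dataclass(frozen=True)
class EvolutionMap:
    """Pairwise complex-relationship map across a list of labelled networks.

    ``matches[(a, b)]`` lists (index in a's set, index in b's set, score)
    for every related complex pair; ``counts`` gives the total per network
    pair and is symmetric for unordered pairs.
    """

    labels: list
    m_thres: float
    matches: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "m_thres": self.m_thres,
            "counts": {f"{a}|{b}": n for (a, b), n in sorted(self.counts.items())},
            "matches": {
                f"{a}|{b}": [[i, j, s] for i, j, s in pairs]
                for (a, b), pairs in sorted(self.matches.items())
            },
        }


def relate(complex_sets, labels, m_thres: float = 0.2) -> EvolutionMap:
    """Relate complexes across >=2 conditions by overlap matching.

    Every unordered pair of conditions is compared complex-by-complex with
    the same M_Score >= m_thres criterion the evaluator uses; the reverse
    direction is stored with indices swapped so counts are symmetric.
    """
    complex_sets = list(complex_sets)
    labels = list(labels)
    if len(complex_sets) < 2:
        raise ValueError("relate requires at least two complex sets")
    if len(labels) != len(complex_sets):
        raise ValueError("labels and complex sets must align")
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")
    emap = EvolutionMap(labels=labels, m_thres=m_thres)
    for a, b in combinations(range(len(complex_sets)), 2):
        pairs = []
        for i, first in enumerate(complex_sets[a]):
            for j, second in enumerate(complex_sets[b]):
                score = m_score(first, second)
                if score >= m_thres:
                    pairs.append((i, j, score))
        emap.matches[(labels[a], labels[b])] = pairs
        emap.matches[(labels[b], labels[a])] = [(j, i, s) for i, j, s in pairs]
        emap.counts[(labels[a], labels[b])] = len(pairs)
        emap.counts[(labels[b], labels[a])] = len(pairs)
    return emap


@dataclass(frozen=True)
class CompositionReport:
    """Core/attachment census of one condition's predicted complexes."""

    n_core: int
    n_attachment: int
    n_unclassified: int
    complex_number: dict  # protein -> number of complexes containing it


def composition(complexes, core, attachment) -> CompositionReport:
    """Count distinct core/attachment proteins appearing in >=1 complex.

    ``core`` and ``attachment`` are disjoint protein rosters; proteins in
    neither are tallied as unclassified.  The per-protein complex number is
    reported for every protein in a complex or on either roster (0 for
    roster proteins absent from every complex).
    """
    core = set(core)
    attachment = set(attachment)
    if core & attachment:
        raise ValueError("core and attachment rosters must be disjoint")
    membership: Counter = Counter()
    for cluster in complexes:
        for protein in cluster:
            membership[protein] += 1
    present = set(membership)
    universe = present | core | attachment
    return CompositionReport(
        n_core=len(present & core),
        n_attachment=len(present & attachment),
        n_unclassified=len(present - core - attachment),
        complex_number={p: membership.get(p, 0) for p in sorted(universe)},
    )
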