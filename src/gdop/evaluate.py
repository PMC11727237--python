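"""Pathway rankings and top-N accuracy.

A trained model scores every pathway for a compound; the prediction is the
full descending-score ordering. Top-N accuracy is the proportion of evaluated
compounds for which at least one true (positive) pathway appears among the N
highest-ranked predictions; N in {100, 30, 10} is the conventional report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = ["PathwayRanking", "TopNReport", "rank_pathways", "topn_accuracy"]

DEFAULT_N_VALUES = (100, 30, 10)


@dataclass(frozen=True)
class PathwayRanking:
    """Descending-score ordering of every pathway for one compound.

    Ties are broken by pathway index ascending, so rankings are deterministic.
    """

    compound_id: str
    pathway_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.float64)
        if scores.shape != (len(self.pathway_ids),):
            raise ValueError("scores and pathway_ids must have equal length")
        if np.any(np.diff(scores) > 0):
            raise ValueError("scores must be non-increasing")
        object.__setattr__(self, "scores", scores)

    def top(self, n: int) -> tuple[str, ...]:
        return self.pathway_ids[:n]

    def rank_of(self, pathway_id: str) -> int:
        """1-based rank of a pathway in this ordering."""
        return self.pathway_ids.index(pathway_id) + 1


@dataclass(frozen=True)
class TopNReport:
    """Top-N accuracy at several N over one evaluated compound set."""

    n_values: tuple[int, ...]
    accuracy: tuple[float, ...]
    n_compounds_evaluated: int

    def as_rows(self) -> list[tuple[int, float, int]]:
        return [
            (n, a, self.n_compounds_evaluated)
            for n, a in zip(self.n_values, self.accuracy)
        ]


def rank_pathways(
    compound_id: str,
    scores: np.ndarray,
    pathway_ids: Sequence[str],
) -> PathwayRanking:
    """Order pathways by descending score, ties broken by index ascending."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (len(pathway_ids),):
        raise ValueError("scores and pathway_ids must have equal length")
    order = np.argsort(-scores, kind="stable")
    return PathwayRanking(
        compound_id=compound_id,
        pathway_ids=tuple(pathway_ids[i] for i in order),
        scores=scores[order],
    )


def topn_accuracy(
    rankings: Sequence[PathwayRanking],
    positives: Mapping[str, set[str]],
    n: int,
) -> float:
    """Fraction of compounds with >= 1 positive pathway in their top n.

    Every compound in ``positives`` is evaluated and must have a ranking and a
    non-empty positive set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not positives:
        raise ValueError("no compounds to evaluate")
    by_compound = {r.compound_id: r for r in rankings}
    hits = 0
    for cid, pos in positives.items():
        if not pos:
            raise ValueError(f"compound {cid} has no positive pathways")
        if cid not in by_compound:
            raise KeyError(f"no ranking for compound {cid}")
        if pos & set(by_compound[cid].top(n)):
            hits += 1
    return hits / len(positives)


def topn_report(
    rankings: Sequence[PathwayRanking],
    positives: Mapping[str, set[str]],
    n_values: Sequence[int] = DEFAULT_N_VALUES,
) -> TopNReport:
    accs = tuple(topn_accuracy(rankings, positives, n) for n in n_values)
    return TopNReport(
        n_values=tuple(n_values),
        accuracy=accs,
        n_compounds_evaluated=len(positives),
    )
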