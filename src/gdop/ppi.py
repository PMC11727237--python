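"""Landmark-gene PPI graph and its spectral propagation operator.

The protein–protein-interaction graph is restricted to the landmark gene
space, thresholded on the STRING-style combined score (0–1000; edges with
score >= 800 are kept by default), deduplicated to undirected edges, and
augmented with a self-connection on every node. Graph convolution then uses
the symmetrically normalised adjacency S = D^(-1/2) A D^(-1/2), whose
spectrum lies in [-1, 1], applied as a polynomial filter sum_k S^k x W_k.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSpace",
    "PPINetwork",
    "PropagationOperator",
    "EdgeLoadReport",
    "load_edges",
    "propagation_operator",
]

DEFAULT_SCORE_THRESHOLD = 800


class GeneSpace:
    """Fixed ordered vocabulary of landmark genes.

    Defines both the node order of the PPI graph and the dimension of every
    expression profile. The order is frozen for the lifetime of a model.
    """

    def __init__(self, genes: Iterable[str]):
        self.genes: tuple[str, ...] = tuple(genes)
        if not self.genes:
            raise ValueError("gene space must be non-empty")
        self.index: dict[str, int] = {g: i for i, g in enumerate(self.genes)}
        if len(self.index) != len(self.genes):
            raise ValueError("gene space contains duplicate symbols")

    @property
    def size(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSpace):
            return NotImplemented
        return self.genes == other.genes


@dataclass
class EdgeLoadReport:
    """Counts from one edge-list load; unknown-gene edges are dropped silently
    but tallied here."""

    n_input_edges: int = 0
    n_unknown_gene: int = 0
    n_below_threshold: int = 0
    n_duplicate: int = 0
    n_kept: int = 0


@dataclass
class PPINetwork:
    """Curated undirected graph over a :class:`GeneSpace`.

    ``edges`` holds (i, j, score) with node indices into the gene space;
    self-connections, when included, appear as (i, i, score) for every node
    and count toward the edge total.
    """

    gene_space: GeneSpace
    edges: list[tuple[int, int, int]]
    self_loops_included: bool
    load_report: EdgeLoadReport | None = None

    @property
    def n_nodes(self) -> int:
        return self.gene_space.size

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Dense binary adjacency (scores are threshold-only, not weights)."""
        n = self.n_nodes
        a = np.zeros((n, n), dtype=np.float64)
        for i, j, _score in self.edges:
            a[i, j] = 1.0
            a[j, i] = 1.0
        return a


@dataclass
class PropagationOperator:
    """Symmetric-normalised spectral operator S = D^(-1/2) A D^(-1/2)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("operator must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("operator must be symmetric")
        self.matrix = m

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    def powers(self, x: np.ndarray, order: int) -> np.ndarray:
        """Stack [x, Sx, S^2 x, ..., S^order x], shape (n, order + 1).

        This is the polynomial-filter basis the graph-convolution layer mixes;
        precomputing it makes the layer a plain linear map of fixed features.
        """
        x = np.asarray(x, dtype=np.float64)
        if x.shape != (self.size,):
            raise ValueError(
                f"profile length {x.shape} does not match operator size {self.size}"
            )
        cols = [x]
        for _ in range(order):
            cols.append(self.matrix @ cols[-1])
        return np.stack(cols, axis=1)


def load_edges(
    path: str | Path,
    gene_space: GeneSpace,
    score_threshold: int = DEFAULT_SCORE_THRESHOLD,
    add_self_loops: bool = True,
) -> PPINetwork:
    """Load a symbol-mapped edge TSV and curate it against a gene space.

    The TSV must have columns ``gene_a``, ``gene_b``, ``combined_score``
    (integers on the 0–1000 scale). Edges are kept when both endpoints are in
    ``gene_space`` and the score is >= ``score_threshold``; symmetric
    duplicates collapse to a single undirected edge (first score wins); a
    self-connection is added for every node when ``add_self_loops``.

    Raises
    ------
    ValueError
        On missing columns or non-integer scores.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_a", "gene_b", "combined_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"edge file missing columns: {missing}")

    report = EdgeLoadReport(n_input_edges=len(df))
    seen: dict[tuple[int, int], int] = {}
    for row_num, (ga, gb, raw_score) in enumerate(
        df[required].itertuples(index=False, name=None), start=2
    ):
        try:
            score = int(raw_score)
        except (TypeError, ValueError):
            raise ValueError(
                f"non-integer combined_score {raw_score!r} at line {row_num}"
            ) from None
        if ga not in gene_space or gb not in gene_space:
            report.n_unknown_gene += 1
            continue
        if score < score_threshold:
            report.n_below_threshold += 1
            continue
        i, j = gene_space.index[ga], gene_space.index[gb]
        key = (min(i, j), max(i, j))
        if key in seen:
            report.n_duplicate += 1
            continue
        seen[key] = score

    edges = [(i, j, s) for (i, j), s in seen.items()]
    if add_self_loops:
        present = {(i, j) for i, j, _ in edges}
        for i in range(gene_space.size):
            if (i, i) not in present:
                edges.append((i, i, 1000))
    report.n_kept = len(edges)
    return PPINetwork(
        gene_space=gene_space,
        edges=edges,
        self_loops_included=add_self_loops,
        load_report=report,
    )


def propagation_operator(net: PPINetwork) -> PropagationOperator:
    """Build S = D^(-1/2) A D^(-1/2) from the binarised adjacency.

    Requires self-connections so every degree is positive; a node touched only
    by its self-loop maps to the unit row/column.
    """
    if not net.self_loops_included:
        raise ValueError("propagation operator requires self-connections")
    a = net.adjacency()
    deg = a.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("zero-degree node despite self-connections")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    s = a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return PropagationOperator(matrix=s)
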