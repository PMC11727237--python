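"""End-to-end assembly: raw files -> curated dataset -> GDOP model.

The directory layout matches what the synthetic generator writes (and what a
real export of pathway/graph/signature/compound tables would look like):
pathways.gmt, edges.tsv, signatures.tsv, compounds.csv.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .compounds import (
    CompoundRecord,
    CurationReport,
    DatasetSplit,
    LabeledPair,
    assign_positive_labels,
    curate_compounds,
    read_compound_metadata,
    read_signatures,
    sample_negatives,
    split_dataset,
)
from .model import GDOP, ModelConfig
from .pathways import PathwayCollection, PathwayFilterConfig, filter_pathways, read_gmt
from .ppi import (
    GeneSpace,
    PPINetwork,
    PropagationOperator,
    load_edges,
    propagation_operator,
)

__all__ = ["CuratedDataset", "gene_space_from_signatures", "curate_directory",
           "build_model"]

_NON_GENE_COLUMNS = {"signature_id", "compound_id", "plate", "dose", "time",
                     "cell_line"}


def gene_space_from_signatures(path: str | Path) -> GeneSpace:
    """Derive the landmark gene space from a signature TSV header: every
    column that is not an id or metadata column, in file order."""
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    genes = [c for c in header if c not in _NON_GENE_COLUMNS]
    if not genes:
        raise ValueError(f"no gene columns found in {path}")
    return GeneSpace(genes)


@dataclass
class CuratedDataset:
    """Everything curation produces, ready for model construction."""

    gene_space: GeneSpace
    pathways: PathwayCollection
    network: PPINetwork
    operator: PropagationOperator
    compounds: list[CompoundRecord]
    curation_report: CurationReport
    positives: list[LabeledPair]
    unlabeled_compounds: list[str]


def curate_directory(
    data_dir: str | Path,
    pathway_filter: PathwayFilterConfig | None = None,
    score_threshold: int = 800,
    min_signatures: int = 5,
) -> CuratedDataset:
    """Run the full curation chain over a data directory."""
    data_dir = Path(data_dir)
    gene_space = gene_space_from_signatures(data_dir / "signatures.tsv")
    pathways = filter_pathways(read_gmt(data_dir / "pathways.gmt"), pathway_filter)
    network = load_edges(
        data_dir / "edges.tsv", gene_space, score_threshold=score_threshold
    )
    operator = propagation_operator(network)
    signatures = read_signatures(data_dir / "signatures.tsv", gene_space)
    metadata = read_compound_metadata(data_dir / "compounds.csv")
    compounds, report = curate_compounds(
        signatures, metadata, min_signatures=min_signatures
    )
    positives, unlabeled = assign_positive_labels(compounds, pathways)
    return CuratedDataset(
        gene_space=gene_space,
        pathways=pathways,
        network=network,
        operator=operator,
        compounds=compounds,
        curation_report=report,
        positives=positives,
        unlabeled_compounds=unlabeled,
    )


def build_model(
    dataset: CuratedDataset,
    config: ModelConfig | None = None,
    negative_ratio: int = 3,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> GDOP:
    """Sample negatives, split compounds, and assemble a GDOP model.

    ``seed`` drives negative sampling and the split (training has its own
    seed, passed to ``fit``).
    """
    negatives = sample_negatives(
        dataset.positives, dataset.pathways, ratio=negative_ratio, seed=seed
    )
    split = split_dataset(
        [c.compound_id for c in dataset.compounds], fractions=fractions, seed=seed
    )
    return GDOP(
        compounds=dataset.compounds,
        pairs=[*dataset.positives, *negatives],
        pathways=dataset.pathways,
        operator=dataset.operator,
        split=split,
        config=config,
    )
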