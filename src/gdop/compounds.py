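"""Compound curation, pathway labeling, negative sampling and data splits.

Mirrors the LINCS-style processing chain: replicate signatures are averaged
into one profile per compound with plate/dose/time/cell-line metadata ignored;
compounds lacking target annotations, with fewer than five signatures, or with
unparseable SMILES are excluded; positive (compound, pathway) pairs come from
target-gene membership in curated pathways; negatives are drawn at random from
each compound's non-positive pathways at a fixed ratio (default 3 per
positive); compounds are split at random into train/validation/test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import smiles_is_valid
from .pathways import PathwayCollection
from .ppi import GeneSpace

__all__ = [
    "Signature",
    "CompoundRecord",
    "LabeledPair",
    "DatasetSplit",
    "CurationReport",
    "read_signatures",
    "read_compound_metadata",
    "curate_compounds",
    "assign_positive_labels",
    "sample_negatives",
    "split_dataset",
]

MIN_SIGNATURES = 5
DEFAULT_NEGATIVE_RATIO = 3

SIGNATURE_META_COLUMNS = ("plate", "dose", "time", "cell_line")


@dataclass
class Signature:
    """One replicate differential-expression profile for a compound."""

    compound_id: str
    profile: np.ndarray
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=np.float64)
        if self.profile.ndim != 1:
            raise ValueError("profile must be a 1-D vector")
        if not np.isfinite(self.profile).all():
            raise ValueError(f"non-finite profile for {self.compound_id}")


@dataclass
class CompoundRecord:
    """A curated molecule: averaged profile, structure, target annotations."""

    compound_id: str
    smiles: str
    targets: frozenset[str]
    profile: np.ndarray
    n_signatures: int

    def __post_init__(self) -> None:
        self.targets = frozenset(self.targets)
        self.profile = np.asarray(self.profile, dtype=np.float64)


@dataclass(frozen=True)
class LabeledPair:
    """A (compound, pathway) training instance."""

    compound_id: str
    pathway_id: str
    is_positive: bool


@dataclass
class CurationReport:
    """Exclusion tallies from one curation pass."""

    n_input_compounds: int = 0
    n_missing_metadata: int = 0
    n_no_targets: int = 0
    n_too_few_signatures: int = 0
    n_bad_smiles: int = 0
    n_retained: int = 0
    excluded_ids: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/validation/test compound-id sets covering all compounds."""

    train: frozenset[str]
    validation: frozenset[str]
    test: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if (
            self.train & self.validation
            or self.train & self.test
            or self.validation & self.test
        ):
            raise ValueError("split sets must be pairwise disjoint")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.validation), len(self.test)


def read_signatures(path: str | Path, gene_space: GeneSpace) -> list[Signature]:
    """Read a signature matrix TSV.

    Layout: ``signature_id``, ``compound_id``, the four metadata columns
    (plate, dose, time, cell_line), then one column per gene in ``gene_space``
    order. Metadata is carried along but never used numerically.
    """
    df = pd.read_csv(path, sep="\t", dtype={"signature_id": str, "compound_id": str})
    expected_meta = [c for c in SIGNATURE_META_COLUMNS if c in df.columns]
    gene_cols = [c for c in df.columns if c in gene_space.index]
    if len(gene_cols) != gene_space.size:
        raise ValueError(
            f"signature file has {len(gene_cols)} gene columns for a "
            f"gene space of size {gene_space.size}"
        )
    gene_cols = sorted(gene_cols, key=gene_space.index.__getitem__)
    profiles = df[gene_cols].to_numpy(dtype=np.float64)
    signatures = []
    for row, profile in zip(df.itertuples(index=False), profiles):
        meta = {c: str(getattr(row, c)) for c in expected_meta}
        signatures.append(
            Signature(compound_id=str(row.compound_id), profile=profile, meta=meta)
        )
    return signatures


def read_compound_metadata(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read the compound CSV (compound_id, smiles, pipe-separated targets).

    Returns a mapping compound_id -> (smiles, targets). An empty or missing
    targets field maps to an empty set (the compound is later excluded).
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = ["compound_id", "smiles", "targets"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"compound file missing columns: {missing}")
    out: dict[str, tuple[str, frozenset[str]]] = {}
    for row in df.itertuples(index=False):
        targets = frozenset(t for t in str(row.targets).split("|") if t)
        out[str(row.compound_id)] = (str(row.smiles), targets)
    return out


def curate_compounds(
    signatures: Sequence[Signature],
    metadata: dict[str, tuple[str, frozenset[str]]],
    min_signatures: int = MIN_SIGNATURES,
) -> tuple[list[CompoundRecord], CurationReport]:
    """Apply the three molecule filters and average replicate profiles.

    A compound is retained iff it has target annotations, at least
    ``min_signatures`` signatures, and a parseable SMILES. Its profile is the
    unweighted arithmetic mean of all its signature profiles, metadata
    ignored. Compounds present in the signature matrix but absent from the
    metadata table are excluded and tallied in the report.
    """
    by_compound: dict[str, list[Signature]] = {}
    for sig in signatures:
        by_compound.setdefault(sig.compound_id, []).append(sig)

    report = CurationReport(n_input_compounds=len(by_compound))
    records: list[CompoundRecord] = []
    for cid, sigs in by_compound.items():
        if cid not in metadata:
            report.n_missing_metadata += 1
            report.excluded_ids[cid] = "missing_metadata"
            continue
        smiles, targets = metadata[cid]
        if not targets:
            report.n_no_targets += 1
            report.excluded_ids[cid] = "no_targets"
            continue
        if len(sigs) < min_signatures:
            report.n_too_few_signatures += 1
            report.excluded_ids[cid] = "too_few_signatures"
            continue
        if not smiles_is_valid(smiles):
            report.n_bad_smiles += 1
            report.excluded_ids[cid] = "bad_smiles"
            continue
        profile = np.mean([s.profile for s in sigs], axis=0)
        records.append(
            CompoundRecord(
                compound_id=cid,
                smiles=smiles,
                targets=targets,
                profile=profile,
                n_signatures=len(sigs),
            )
        )
    report.n_retained = len(records)
    return records, report


def assign_positive_labels(
    compounds: Sequence[CompoundRecord],
    pathways: PathwayCollection,
) -> tuple[list[LabeledPair], list[str]]:
    """Label (compound, pathway) positive iff a target gene is a pathway member.

    Returns the positive pairs plus the ids of compounds with zero positives;
    those compounds stay in the dataset (they can still be scored) but carry
    no supervised signal.
    """
    pairs: list[LabeledPair] = []
    unlabeled: list[str] = []
    for c in compounds:
        hits = [p.id for p in pathways if c.targets & p.genes]
        if not hits:
            unlabeled.append(c.compound_id)
            continue
        pairs.extend(
            LabeledPair(compound_id=c.compound_id, pathway_id=pid, is_positive=True)
            for pid in hits
        )
    return pairs, unlabeled


def sample_negatives(
    positives: Sequence[LabeledPair],
    pathways: PathwayCollection,
    ratio: int = DEFAULT_NEGATIVE_RATIO,
    seed: int = 0,
) -> list[LabeledPair]:
    """Draw negative pathways per compound at ``ratio`` per positive.

    For each compound with k positives, ``ratio * k`` distinct pathways are
    drawn uniformly without replacement from the pathways not positive for
    that compound. If too few exist, all of them are taken and a warning is
    emitted. Deterministic for a given seed.
    """
    if ratio < 1:
        raise ValueError("negative ratio must be >= 1")
    rng = np.random.default_rng(seed)
    pos_by_compound: dict[str, set[str]] = {}
    for p in positives:
        if not p.is_positive:
            raise ValueError("sample_negatives expects positive pairs only")
        pos_by_compound.setdefault(p.compound_id, set()).add(p.pathway_id)

    all_ids = pathways.ids
    negatives: list[LabeledPair] = []
    capped: list[str] = []
    for cid in sorted(pos_by_compound):
        pos = pos_by_compound[cid]
        candidates = [pid for pid in all_ids if pid not in pos]
        want = ratio * len(pos)
        if want > len(candidates):
            capped.append(cid)
            chosen = candidates
        else:
            chosen = [
                candidates[i]
                for i in rng.choice(len(candidates), size=want, replace=False)
            ]
        negatives.extend(
            LabeledPair(compound_id=cid, pathway_id=pid, is_positive=False)
            for pid in chosen
        )
    if capped:
        preview = ", ".join(capped[:5]) + ("…" if len(capped) > 5 else "")
        warnings.warn(
            f"{len(capped)} compound(s) had fewer non-positive pathways than "
            f"requested negatives; all available were taken ({preview})",
            stacklevel=2,
        )
    return negatives


def split_dataset(
    compound_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    rounding: str = "round",
) -> DatasetSplit:
    """Randomly split compounds into train/validation/test.

    The id list is permuted under the seed and sliced contiguously. With
    ``rounding="round"`` (default) the train and validation sizes are the
    fractions rounded half-up and test takes the remainder — e.g. 2338
    compounds at (0.8, 0.1, 0.1) give 1870/234/234; ``rounding="floor"``
    floors train and validation instead.
    """
    ids = list(compound_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("compound ids must be unique")
    if len(ids) < 3:
        raise ValueError("need at least 3 compounds to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")

    def _size(x: float) -> int:
        if rounding == "round":
            return int(np.floor(x + 0.5))
        if rounding == "floor":
            return int(np.floor(x))
        raise ValueError(f"unknown rounding rule: {rounding!r}")

    n = len(ids)
    n_train = _size(n * fractions[0])
    n_val = _size(n * fractions[1])
    if n_train + n_val >= n:  # degenerate tiny inputs: keep test non-empty
        n_train = max(1, n - 2)
        n_val = 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [ids[i] for i in perm]
    return DatasetSplit(
        train=frozenset(shuffled[:n_train]),
        validation=frozenset(shuffled[n_train : n_train + n_val]),
        test=frozenset(shuffled[n_train + n_val :]),
        seed=seed,
    )
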