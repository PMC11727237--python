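"""Synthetic fixture generator with planted pathway signal.

Emulates the statistical structure the pipeline assumes, without any
downloads: a sparse gene–gene interaction graph whose pathway members are
preferentially connected, bounded-size pathway gene sets, and compounds whose
replicate signatures are Gaussian noise plus a mean shift on the member genes
of the compound's (single) true pathway. Target annotations are drawn from
the true pathway, so positive labels point at the planted mechanism; fractions
of compounds get missing targets, corrupted SMILES, or too few replicates, so
every curation filter is exercised.

Default settings define the standard synthetic study regime used throughout
the test-bench: 60 genes, 15 pathways of 5–15 genes, 300 compounds with 3–8
replicate signatures (straddling the >=5 curation cutoff), mean shift 3 on a
noise standard deviation of 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pathways import Pathway, PathwayCollection
from .ppi import GeneSpace
from .smiles_catalog import SMILES_CATALOG

__all__ = [
    "SyntheticConfig",
    "FixtureBundle",
    "make_fixture",
    "expected_curation_counts",
    "centroid_scores",
]

_DOSES = ("0.1uM", "1uM", "10uM")
_TIMES = ("6h", "24h")
_CELL_LINES = ("A375", "MCF7", "PC3")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults are the standard synthetic study regime.

    effect_size is the mean shift (in noise-SD units when noise_sd = 1) added
    to every true-pathway member gene of every signature; 0 yields pure noise.
    pathway_edge_prob is the elevated edge probability among the members of a
    pathway, making graph propagation informative.
    """

    n_genes: int = 60
    graph_edge_prob: float = 0.05
    pathway_edge_prob: float = 0.3
    n_pathways: int = 15
    pathway_size_range: tuple[int, int] = (4, 8)
    n_compounds: int = 300
    signatures_per_compound_range: tuple[int, int] = (3, 8)
    effect_size: float = 3.0
    noise_sd: float = 1.0
    targets_per_compound: int = 2
    fraction_missing_targets: float = 0.05
    fraction_bad_smiles: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if lo < 1 or hi < lo:
            raise ValueError("pathway_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_genes:
            raise ValueError(
                f"pathway_size_range upper bound {hi} exceeds n_genes {self.n_genes}"
            )
        if self.n_pathways > self.n_genes:
            raise ValueError("need at least one gene per pathway core")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in ("graph_edge_prob", "pathway_edge_prob",
                     "fraction_missing_targets", "fraction_bad_smiles"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        slo, shi = self.signatures_per_compound_range
        if slo < 1 or shi < slo:
            raise ValueError("signatures_per_compound_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class FixtureBundle:
    """Paths of one generated fixture; files are mutually consistent."""

    pathways: Path
    edges: Path
    signatures: Path
    compounds: Path
    truth: Path

    def load_truth(self) -> dict[str, str]:
        out = {}
        for line in self.truth.read_text().splitlines()[1:]:
            cid, pid = line.split("\t")
            out[cid] = pid
        return out


def make_fixture(config: SyntheticConfig, out_dir: str | Path) -> FixtureBundle:
    """Generate a consistent fixture bundle under ``out_dir``.

    Writes pathways.gmt, edges.tsv, signatures.tsv, compounds.csv and
    truth.tsv (compound -> planted pathway). Regeneration under an equal seed
    is byte-identical; all randomness flows from one generator.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:03d}" for i in range(1, config.n_genes + 1)]

    # --- pathways: a distinctive core per pathway plus shared periphery ---
    # cores partition the gene space, so target annotations (drawn from the
    # core) point at few pathways, as in real pathway label spaces where a
    # drug's targets are characteristic members of its mechanism pathway
    lo, hi = config.pathway_size_range
    core_size = max(1, config.n_genes // config.n_pathways)
    gene_perm = rng.permutation(config.n_genes)
    pathway_members: dict[str, list[int]] = {}
    pathway_cores: dict[str, list[int]] = {}
    for p in range(1, config.n_pathways + 1):
        pid = f"PW{p:03d}"
        core = gene_perm[(p - 1) * core_size : p * core_size].tolist()
        size = int(rng.integers(lo, hi + 1))
        if size <= len(core):
            members = core[:size]
            core = members
        else:
            non_core = np.array(sorted(set(range(config.n_genes)) - set(core)))
            extras = rng.choice(non_core, size=size - len(core), replace=False)
            members = core + extras.tolist()
        pathway_cores[pid] = sorted(core)
        pathway_members[pid] = sorted(members)

    pathways_path = out_dir / "pathways.gmt"
    with pathways_path.open("w") as fh:
        for pid, members in pathway_members.items():
            fh.write("\t".join([pid, "synthetic pathway",
                                *[genes[i] for i in members]]) + "\n")

    # --- graph: sparse background + densified pathway interiors ----------
    # decoy sub-threshold edges are emitted too, so score filtering is real
    scores: dict[tuple[int, int], int] = {}
    for i in range(config.n_genes):
        for j in range(i + 1, config.n_genes):
            r = rng.random()
            if r < config.graph_edge_prob:
                scores[(i, j)] = int(rng.integers(800, 1001))
            elif r < 2 * config.graph_edge_prob:
                scores[(i, j)] = int(rng.integers(150, 800))
    for members in pathway_members.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                key = (members[a], members[b])
                if rng.random() < config.pathway_edge_prob:
                    scores[key] = int(rng.integers(800, 1001))

    edges_path = out_dir / "edges.tsv"
    with edges_path.open("w") as fh:
        fh.write("gene_a\tgene_b\tcombined_score\n")
        for (i, j), s in sorted(scores.items()):
            fh.write(f"{genes[i]}\t{genes[j]}\t{s}\n")

    # --- compounds, signatures, truth -------------------------------------
    pathway_ids = list(pathway_members)
    slo, shi = config.signatures_per_compound_range
    signatures_path = out_dir / "signatures.tsv"
    compounds_path = out_dir / "compounds.csv"
    truth_path = out_dir / "truth.tsv"
    with signatures_path.open("w") as sig_fh, \
            compounds_path.open("w") as cmp_fh, \
            truth_path.open("w") as tr_fh:
        sig_fh.write("signature_id\tcompound_id\tplate\tdose\ttime\tcell_line\t"
                     + "\t".join(genes) + "\n")
        cmp_fh.write("compound_id,smiles,targets\n")
        tr_fh.write("compound_id\tpathway_id\n")
        sig_counter = 0
        for c in range(1, config.n_compounds + 1):
            cid = f"C{c:04d}"
            true_pid = pathway_ids[int(rng.integers(config.n_pathways))]
            members = pathway_members[true_pid]

            core = pathway_cores[true_pid]
            if rng.random() < config.fraction_missing_targets:
                targets: list[str] = []
            else:
                k = min(config.targets_per_compound, len(core))
                targets = sorted(
                    genes[i] for i in rng.choice(core, size=k, replace=False)
                )

            smiles = SMILES_CATALOG[(c - 1) % len(SMILES_CATALOG)]
            if rng.random() < config.fraction_bad_smiles:
                smiles = smiles + "(("  # unclosed branch: never parseable

            n_sigs = int(rng.integers(slo, shi + 1))
            for _ in range(n_sigs):
                sig_counter += 1
                profile = rng.normal(0.0, config.noise_sd, size=config.n_genes)
                profile[members] += config.effect_size
                meta = (
                    f"PL{int(rng.integers(1, 6)):02d}",
                    _DOSES[int(rng.integers(len(_DOSES)))],
                    _TIMES[int(rng.integers(len(_TIMES)))],
                    _CELL_LINES[int(rng.integers(len(_CELL_LINES)))],
                )
                sig_fh.write(
                    f"S{sig_counter:05d}\t{cid}\t" + "\t".join(meta) + "\t"
                    + "\t".join(f"{v:.6f}" for v in profile) + "\n"
                )
            cmp_fh.write(f"{cid},{smiles},{'|'.join(targets)}\n")
            tr_fh.write(f"{cid}\t{true_pid}\n")

    return FixtureBundle(
        pathways=pathways_path,
        edges=edges_path,
        signatures=signatures_path,
        compounds=compounds_path,
        truth=truth_path,
    )


def expected_curation_counts(config: SyntheticConfig) -> float:
    """Analytic expectation of compounds surviving all three curation filters.

    Missing-target, bad-SMILES and replicate-count draws are independent per
    compound; the replicate count is uniform on the configured integer range,
    so P(kept) = (1 - f_missing) (1 - f_bad) P(n_sigs >= 5).
    """
    slo, shi = config.signatures_per_compound_range
    n_vals = shi - slo + 1
    n_ok = max(0, shi - max(slo, 5) + 1)
    p_sigs = n_ok / n_vals
    return (
        config.n_compounds
        * (1.0 - config.fraction_missing_targets)
        * (1.0 - config.fraction_bad_smiles)
        * p_sigs
    )


def centroid_scores(
    profile: np.ndarray,
    gene_space: GeneSpace,
    pathways: PathwayCollection,
) -> np.ndarray:
    """Nearest-centroid baseline: score each pathway by the mean profile value
    over its member genes. A model-free oracle for planted-signal recovery."""
    profile = np.asarray(profile, dtype=np.float64)
    out = np.empty(len(pathways))
    for k, p in enumerate(pathways):
        idx = [gene_space.index[g] for g in p.genes if g in gene_space.index]
        out[k] = profile[idx].mean() if idx else -np.inf
    return out
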