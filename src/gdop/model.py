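"""The GDOP network: spectral graph convolution + dense pathway classifier.

A compound's averaged expression profile x (one value per landmark gene) is
propagated over the PPI graph by a polynomial spectral filter,

    H = ReLU( sum_{k=0..K} S^k x W_k ),    S = D^(-1/2) A D^(-1/2),

giving C latent channels per gene; the flattened gene-by-channel latent vector
is concatenated with the compound's Morgan fingerprint and passed through a
four-layer dense network (default widths 4096/3016/2048/1024, ReLU on every
layer but the last) with per-layer dropout (0.2 on the graph-convolution
layer, 0.5/0.5/0.5/0.2 on the dense layers). A final linear head with a
per-pathway sigmoid scores every pathway; training minimises binary
cross-entropy restricted to the labeled (positive + sampled-negative) pairs,
with Adam and early stopping on validation loss.

Implemented directly in numpy (forward, backward, Adam); everything is
float64 and seeded, so runs are exactly reproducible.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import morgan_fingerprint
from .compounds import CompoundRecord, DatasetSplit, LabeledPair
from .evaluate import (
    DEFAULT_N_VALUES,
    PathwayRanking,
    TopNReport,
    rank_pathways,
    topn_report,
)
from .pathways import PathwayCollection
from .ppi import GeneSpace, PropagationOperator

__all__ = [
    "ModelConfig",
    "GDOP",
    "GDOPResults",
    "EarlyStopping",
    "init_model",
    "sgcn_encode",
    "forward",
    "masked_cross_entropy",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    dropout_rates maps in order [graph-conv layer, dense1..dense4]; its length
    must be len(dense_widths) + 1. The output head (linear + sigmoid) carries
    neither activation nor dropout.
    """

    sgcn_channels: int = 4
    sgcn_order: int = 1
    dense_widths: tuple[int, ...] = (4096, 3016, 2048, 1024)
    dropout_rates: tuple[float, ...] = (0.2, 0.5, 0.5, 0.5, 0.2)
    activation: str = "relu"
    learning_rate: float = 1e-4
    patience: int = 10
    max_epochs: int = 200
    batch_size: int = 32
    fingerprint_radius: int = 2
    fingerprint_bits: int = 2048

    def __post_init__(self) -> None:
        object.__setattr__(self, "dense_widths", tuple(self.dense_widths))
        object.__setattr__(self, "dropout_rates", tuple(self.dropout_rates))
        if self.sgcn_channels < 1 or self.sgcn_order < 0:
            raise ValueError("sgcn_channels >= 1 and sgcn_order >= 0 required")
        if len(self.dropout_rates) != len(self.dense_widths) + 1:
            raise ValueError(
                "dropout_rates must have one entry per dense layer plus one "
                f"for the graph-convolution layer ({len(self.dense_widths) + 1} "
                f"expected, got {len(self.dropout_rates)})"
            )
        if any(not (0.0 <= r < 1.0) for r in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")
        if any(w < 1 for w in self.dense_widths):
            raise ValueError("dense widths must be positive")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation: {self.activation!r}")

    @classmethod
    def small(cls) -> "ModelConfig":
        """Scaled-down configuration for synthetic benchmarks on one CPU:
        2 graph-convolution channels, dense widths 64/48/32/16, the same
        dropout pattern, and a learning rate suited to the small network."""
        return cls(
            sgcn_channels=2,
            dense_widths=(64, 48, 32, 16),
            dropout_rates=(0.2, 0.5, 0.5, 0.5, 0.2),
            learning_rate=3e-3,
            max_epochs=300,
            patience=30,
            batch_size=16,
        )


# ---------------------------------------------------------------------------
# parameters and primitive passes
# ---------------------------------------------------------------------------


def init_model(
    config: ModelConfig,
    gene_space: GeneSpace | int,
    n_pathways: int,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Randomly initialise all weights (He scaling for the ReLU layers).

    ``gene_space`` may be the GeneSpace itself or just its size. Returns a
    flat name->array dict: ``sgcn_W``/``sgcn_b`` for the graph-convolution
    channel mixing, ``W{i}``/``b{i}`` per dense layer and ``Wout``/``bout``
    for the pathway head. Deterministic under ``seed``.

    The spectral-mixing weights start at the identity polynomial basis
    (channel c reads S^(c mod (K+1)) x), so the first latent channels are the
    raw and propagated profiles and training only has to learn the mixing;
    random mixing inits can zero out the profile direction under ReLU and
    leave optimisation stuck at a marginal-rate plateau. Downstream dense
    weights are random (He scaling), which breaks any channel symmetry.
    """
    if n_pathways < 2:
        raise ValueError("need at least 2 pathways")
    n_genes = gene_space if isinstance(gene_space, int) else gene_space.size
    rng = np.random.default_rng(seed)
    k1 = config.sgcn_order + 1
    sgcn_w = np.zeros((k1, config.sgcn_channels))
    for c in range(config.sgcn_channels):
        sgcn_w[c % k1, c] = 1.0
    params: dict[str, np.ndarray] = {
        "sgcn_W": sgcn_w,
        "sgcn_b": np.zeros(config.sgcn_channels),
    }
    d_in = n_genes * config.sgcn_channels + config.fingerprint_bits
    widths = [d_in, *config.dense_widths]
    for i, (fan_in, fan_out) in enumerate(zip(widths[:-1], widths[1:])):
        params[f"W{i}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        params[f"b{i}"] = np.zeros(fan_out)
    params["Wout"] = rng.normal(
        0.0, np.sqrt(1.0 / widths[-1]), size=(widths[-1], n_pathways)
    )
    params["bout"] = np.zeros(n_pathways)
    return params


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _dropout_mask(rng: np.random.Generator, shape, rate: float) -> np.ndarray:
    """Inverted-dropout mask: zeros at ``rate``, survivors scaled by 1/(1-rate)."""
    if rate == 0.0:
        return np.ones(shape)
    keep = 1.0 - rate
    return (rng.random(shape) < keep) / keep


def sgcn_encode(
    params: Mapping[str, np.ndarray],
    profile: np.ndarray,
    operator: PropagationOperator,
    config: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Graph-convolution encoding of one profile into a latent vector.

    latent = flatten( ReLU( sum_k (S^k x) W_k + b ) ), length n_genes *
    sgcn_channels. Dropout at dropout_rates[0] applies in training mode only.
    """
    phi = operator.powers(np.asarray(profile, dtype=np.float64), config.sgcn_order)
    h = _relu(phi @ params["sgcn_W"] + params["sgcn_b"])
    latent = h.reshape(-1)
    if training:
        if rng is None:
            raise ValueError("training-mode encoding requires an rng")
        latent = latent * _dropout_mask(rng, latent.shape, config.dropout_rates[0])
    return latent


def forward(
    params: Mapping[str, np.ndarray],
    latent: np.ndarray,
    fingerprint_bits: np.ndarray,
    config: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Dense stack over [latent | fingerprint]; per-pathway sigmoid scores.

    ReLU on every dense layer except none on the output head; dropout per
    layer in training mode only. Inference is deterministic.
    """
    z = np.concatenate(
        [np.asarray(latent, dtype=np.float64),
         np.asarray(fingerprint_bits, dtype=np.float64)]
    )
    n_dense = len(config.dense_widths)
    for i in range(n_dense):
        z = _relu(z @ params[f"W{i}"] + params[f"b{i}"])
        if training:
            if rng is None:
                raise ValueError("training-mode forward requires an rng")
            z = z * _dropout_mask(rng, z.shape, config.dropout_rates[i + 1])
    logits = z @ params["Wout"] + params["bout"]
    return _sigmoid(logits)


def masked_cross_entropy(
    scores: Mapping[str, np.ndarray],
    pairs: Sequence[LabeledPair],
    pathway_index: Mapping[str, int],
) -> float:
    """Mean binary cross-entropy over the labeled pairs only.

    ``scores`` maps compound id to its per-pathway sigmoid score vector.
    Pathways without a label for a compound contribute nothing, so
    perturbing an unlabeled score leaves the loss unchanged.
    """
    if not pairs:
        raise ValueError("cannot compute loss over an empty pair list")
    total = 0.0
    for pair in pairs:
        s = float(scores[pair.compound_id][pathway_index[pair.pathway_id]])
        s = min(max(s, 1e-15), 1.0 - 1e-15)
        total += -np.log(s) if pair.is_positive else -np.log1p(-s)
    return total / len(pairs)


# ---------------------------------------------------------------------------
# batched training internals
# ---------------------------------------------------------------------------


def _forward_batch(params, phi, fp, config, training, rng):
    """Batched forward pass returning logits plus the cache for backprop."""
    cache: dict[str, object] = {}
    pre = np.einsum("bgk,kc->bgc", phi, params["sgcn_W"]) + params["sgcn_b"]
    h = _relu(pre)
    latent = h.reshape(h.shape[0], -1)
    if training:
        m0 = _dropout_mask(rng, latent.shape, config.dropout_rates[0])
        latent = latent * m0
        cache["m0"] = m0
    z = np.concatenate([latent, fp], axis=1)
    cache.update(pre=pre, z0=z)
    acts = [z]
    for i in range(len(config.dense_widths)):
        a = acts[-1] @ params[f"W{i}"] + params[f"b{i}"]
        zi = _relu(a)
        if training:
            mi = _dropout_mask(rng, zi.shape, config.dropout_rates[i + 1])
            zi = zi * mi
            cache[f"m{i + 1}"] = mi
        cache[f"a{i}"] = a
        acts.append(zi)
    cache["acts"] = acts
    logits = acts[-1] @ params["Wout"] + params["bout"]
    return logits, cache


def _masked_bce_from_logits(logits, y, mask):
    """Numerically stable masked BCE: mean over labeled entries."""
    n_labeled = mask.sum()
    per_entry = np.logaddexp(0.0, logits) - y * logits
    return float((per_entry * mask).sum() / n_labeled)


def _backward_batch(params, phi, config, logits, y, mask, cache):
    """Gradients of the masked BCE w.r.t. every parameter."""
    grads: dict[str, np.ndarray] = {}
    n_labeled = mask.sum()
    dlogits = (_sigmoid(logits) - y) * mask / n_labeled
    acts = cache["acts"]
    grads["Wout"] = acts[-1].T @ dlogits
    grads["bout"] = dlogits.sum(axis=0)
    dz = dlogits @ params["Wout"].T
    for i in reversed(range(len(config.dense_widths))):
        if f"m{i + 1}" in cache:
            dz = dz * cache[f"m{i + 1}"]
        da = dz * (cache[f"a{i}"] > 0)
        grads[f"W{i}"] = acts[i].T @ da
        grads[f"b{i}"] = da.sum(axis=0)
        dz = da @ params[f"W{i}"].T
    n_latent = phi.shape[1] * config.sgcn_channels
    dlatent = dz[:, :n_latent]
    if "m0" in cache:
        dlatent = dlatent * cache["m0"]
    dh = dlatent.reshape(cache["pre"].shape) * (cache["pre"] > 0)
    grads["sgcn_W"] = np.einsum("bgk,bgc->kc", phi, dh)
    grads["sgcn_b"] = dh.sum(axis=(0, 1))
    return grads


class _Adam:
    """Adam with the standard moment defaults (beta1 0.9, beta2 0.999)."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class EarlyStopping:
    """Stop when the monitored value fails to improve for ``patience``
    successive epochs; remembers the best value and its epoch."""

    def __init__(self, patience: int, min_delta: float = 0.0):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.min_delta = min_delta
        self.best_value = np.inf
        self.best_epoch: int | None = None
        self.bad_epochs = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record one epoch's monitor value; returns True on improvement."""
        if value < self.best_value - self.min_delta:
            self.best_value = value
            self.best_epoch = epoch
            self.bad_epochs = 0
            return True
        self.bad_epochs += 1
        return False

    @property
    def should_stop(self) -> bool:
        return self.bad_epochs >= self.patience


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class GDOP:
    """Drug on-target pathway prediction model, built from curated data.

    Parameters
    ----------
    compounds : curated compound records (averaged profile + SMILES + targets).
    pairs : positive and sampled-negative labeled pairs.
    pathways : the curated label space; its order fixes the output layer.
    operator : spectral propagation operator over the gene space.
    split : train/validation/test compound-id split.
    config : architecture/training settings (paper-scale defaults).

    Construction precomputes the polynomial-filter features S^k x per compound
    and each compound's Morgan fingerprint; :meth:`fit` trains the network and
    returns a :class:`GDOPResults`.
    """

    def __init__(
        self,
        compounds: Sequence[CompoundRecord],
        pairs: Sequence[LabeledPair],
        pathways: PathwayCollection,
        operator: PropagationOperator,
        split: DatasetSplit,
        config: ModelConfig | None = None,
    ):
        self.config = config or ModelConfig()
        self.compounds = list(compounds)
        self.pairs = list(pairs)
        self.pathways = pathways
        self.operator = operator
        self.split = split
        if operator.size != len(self.compounds[0].profile):
            raise ValueError("operator size does not match profile length")

        self.compound_ids = [c.compound_id for c in self.compounds]
        self._row = {cid: i for i, cid in enumerate(self.compound_ids)}
        n, p = len(self.compounds), len(pathways)

        self.phi = np.stack(
            [operator.powers(c.profile, self.config.sgcn_order) for c in self.compounds]
        )
        self.fingerprints = np.stack(
            [
                morgan_fingerprint(
                    c.smiles,
                    radius=self.config.fingerprint_radius,
                    n_bits=self.config.fingerprint_bits,
                ).bits.astype(np.float64)
                for c in self.compounds
            ]
        )
        self.label_mask = np.zeros((n, p))
        self.labels = np.zeros((n, p))
        for pair in self.pairs:
            i = self._row[pair.compound_id]
            j = pathways.index[pair.pathway_id]
            self.label_mask[i, j] = 1.0
            self.labels[i, j] = 1.0 if pair.is_positive else 0.0

        def rows(ids: frozenset[str], labeled_only: bool) -> np.ndarray:
            idx = [self._row[cid] for cid in self.compound_ids if cid in ids]
            if labeled_only:
                idx = [i for i in idx if self.label_mask[i].any()]
            return np.array(sorted(idx), dtype=int)

        # compounds without any labeled pair carry no loss signal
        self.train_rows = rows(split.train, labeled_only=True)
        self.val_rows = rows(split.validation, labeled_only=True)
        self.test_rows = rows(split.test, labeled_only=False)

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)

    def _loss_on(self, params, row_idx) -> float:
        logits, _ = _forward_batch(
            params, self.phi[row_idx], self.fingerprints[row_idx],
            self.config, training=False, rng=None,
        )
        return _masked_bce_from_logits(
            logits, self.labels[row_idx], self.label_mask[row_idx]
        )

    def fit(self, seed: int = 0) -> "GDOPResults":
        """Train with Adam and early stopping on validation loss.

        Returns the best-validation checkpoint. Fully reproducible: the seed
        drives initialisation, batch shuffling and dropout.
        """
        cfg = self.config
        if len(self.train_rows) == 0 or len(self.val_rows) == 0:
            raise ValueError("training requires non-empty train and validation sets")
        rng = np.random.default_rng(seed)
        params = init_model(cfg, self.operator.size, self.n_pathways,
                            seed=int(rng.integers(2**31)))
        opt = _Adam(params, cfg.learning_rate)
        stopper = EarlyStopping(cfg.patience)
        best_params = copy.deepcopy(params)
        records = []

        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(len(self.train_rows))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(order), cfg.batch_size):
                rows = self.train_rows[order[start : start + cfg.batch_size]]
                mask = self.label_mask[rows]
                if not mask.any():
                    continue
                logits, cache = _forward_batch(
                    params, self.phi[rows], self.fingerprints[rows],
                    cfg, training=True, rng=rng,
                )
                loss = _masked_bce_from_logits(logits, self.labels[rows], mask)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}"
                    )
                grads = _backward_batch(
                    params, self.phi[rows], cfg, logits,
                    self.labels[rows], mask, cache,
                )
                opt.step(params, grads)
                epoch_loss += loss
                n_batches += 1

            val_loss = self._loss_on(params, self.val_rows)
            if not np.isfinite(val_loss):
                raise RuntimeError(
                    f"training diverged: non-finite validation loss at epoch {epoch}"
                )
            improved = stopper.update(val_loss, epoch)
            if improved:
                best_params = copy.deepcopy(params)
            records.append(
                {
                    "epoch": epoch,
                    "train_loss": epoch_loss / max(n_batches, 1),
                    "val_loss": val_loss,
                    "improved": improved,
                }
            )
            if stopper.should_stop:
                break

        history = pd.DataFrame.from_records(records)
        return GDOPResults(
            model=self,
            params=best_params,
            config=cfg,
            pathway_ids=tuple(self.pathways.ids),
            operator=self.operator,
            history=history,
            best_epoch=stopper.best_epoch,
            best_val_loss=float(stopper.best_value),
            seed=seed,
        )


class GDOPResults:
    """Fitted GDOP model: weights, training history, prediction, evaluation.

    Obtained from :meth:`GDOP.fit` or reloaded from a checkpoint (in which
    case the training data are absent and only prediction is available).
    """

    def __init__(
        self,
        model: GDOP | None,
        params: dict[str, np.ndarray],
        config: ModelConfig,
        pathway_ids: tuple[str, ...],
        operator: PropagationOperator,
        history: pd.DataFrame | None,
        best_epoch: int | None,
        best_val_loss: float | None,
        seed: int | None,
    ):
        self.model = model
        self.params = params
        self.config = config
        self.pathway_ids = pathway_ids
        self.operator = operator
        self.history = history
        self.best_epoch = best_epoch
        self.best_val_loss = best_val_loss
        self.seed = seed

    # -- prediction ---------------------------------------------------------

    def predict_scores(self, profile: np.ndarray, fingerprint_bits: np.ndarray) -> np.ndarray:
        """Per-pathway sigmoid scores for one profile + fingerprint."""
        latent = sgcn_encode(self.params, profile, self.operator, self.config)
        return forward(self.params, latent, fingerprint_bits, self.config)

    def predict_rank(self, compound: CompoundRecord) -> PathwayRanking:
        """Full descending-score pathway ranking for one compound."""
        fp = morgan_fingerprint(
            compound.smiles,
            radius=self.config.fingerprint_radius,
            n_bits=self.config.fingerprint_bits,
        ).bits.astype(np.float64)
        scores = self.predict_scores(compound.profile, fp)
        return rank_pathways(compound.compound_id, scores, self.pathway_ids)

    # -- evaluation ---------------------------------------------------------

    def _subset_rows(self, subset: str) -> np.ndarray:
        if self.model is None:
            raise ValueError("evaluation requires the fitted model's data; "
                             "a reloaded checkpoint can only predict")
        return {
            "train": self.model.train_rows,
            "validation": self.model.val_rows,
            "test": self.model.test_rows,
        }[subset]

    def rankings(self, subset: str = "test") -> list[PathwayRanking]:
        rows = self._subset_rows(subset)
        logits, _ = _forward_batch(
            self.params, self.model.phi[rows], self.model.fingerprints[rows],
            self.config, training=False, rng=None,
        )
        scores = _sigmoid(logits)
        return [
            rank_pathways(self.model.compound_ids[r], scores[i], self.pathway_ids)
            for i, r in enumerate(rows)
        ]

    def positives(self, subset: str = "test") -> dict[str, set[str]]:
        """True (positive-labeled) pathways per compound in a subset."""
        rows = set(self._subset_rows(subset).tolist())
        out: dict[str, set[str]] = {}
        for pair in self.model.pairs:
            if pair.is_positive and self.model._row[pair.compound_id] in rows:
                out.setdefault(pair.compound_id, set()).add(pair.pathway_id)
        return out

    def top_n_report(
        self,
        subset: str = "test",
        n_values: Sequence[int] = DEFAULT_N_VALUES,
    ) -> TopNReport:
        """Top-N accuracy over the compounds of a subset that have >= 1
        positive pathway."""
        return topn_report(self.rankings(subset), self.positives(subset), n_values)

    def summary(self) -> str:
        """Plain-text results table in the spirit of statsmodels summaries."""
        lines = [
            "GDOP Pathway Ranking Model Results",
            "=" * 50,
            f"pathways (labels):        {len(self.pathway_ids)}",
            f"gene space size:          {self.operator.size}",
            f"graph-conv channels:      {self.config.sgcn_channels}"
            f" (filter order {self.config.sgcn_order})",
            f"dense widths:             {self.config.dense_widths}",
            f"dropout rates:            {self.config.dropout_rates}",
            f"optimizer:                Adam (lr={self.config.learning_rate})",
        ]
        if self.model is not None:
            lines += [
                f"compounds (train/val/test): "
                f"{len(self.model.train_rows)}/{len(self.model.val_rows)}/"
                f"{len(self.model.test_rows)}",
            ]
        if self.history is not None:
            lines += [
                f"epochs run:               {len(self.history)}",
                f"best epoch:               {self.best_epoch}",
                f"best validation loss:     {self.best_val_loss:.4f}",
            ]
        if self.model is not None and len(self.model.test_rows):
            n_values = [n for n in (10, 3, 1) if n <= len(self.pathway_ids)]
            rep = self.top_n_report("test", n_values=n_values)
            lines.append("test top-N accuracy:")
            for n, acc, m in rep.as_rows():
                lines.append(f"    top-{n:<4d} {acc:.3f}   (n={m})")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a single-file checkpoint (weights + config + label space +
        operator); reloading reproduces predictions bit-identically."""
        header = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": asdict(self.config),
            "pathway_ids": list(self.pathway_ids),
            "best_epoch": self.best_epoch,
            "best_val_loss": self.best_val_loss,
            "seed": self.seed,
        }
        arrays = {f"param__{k}": v for k, v in self.params.items()}
        arrays["operator"] = self.operator.matrix
        np.savez(path, __header__=np.frombuffer(
            json.dumps(header).encode("utf-8"), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GDOPResults":
        with np.load(path) as archive:
            header = json.loads(bytes(archive["__header__"]).decode("utf-8"))
            if header["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint version {header['format_version']}"
                )
            params = {
                k[len("param__"):]: archive[k]
                for k in archive.files
                if k.startswith("param__")
            }
            operator = PropagationOperator(matrix=archive["operator"])
        cfg_dict = header["config"]
        cfg_dict["dense_widths"] = tuple(cfg_dict["dense_widths"])
        cfg_dict["dropout_rates"] = tuple(cfg_dict["dropout_rates"])
        config = ModelConfig(**cfg_dict)
        return cls(
            model=None,
            params=params,
            config=config,
            pathway_ids=tuple(header["pathway_ids"]),
            operator=operator,
            history=None,
            best_epoch=header["best_epoch"],
            best_val_loss=header["best_val_loss"],
            seed=header["seed"],
        )
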