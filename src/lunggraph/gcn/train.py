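"""Training loop for the survival GCN: BCE loss, Adam, plateau LR schedule.

Matches the printed training recipe: up to 100 epochs, learning rate
starting at 0.01 and floored at 0.00001 (reduced x0.1 on a validation-loss
plateau), weight decay 0.00005.  The best-validation-AUC epoch's weights
are returned.  Fully reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from lunggraph.evaluation import auc_point
from lunggraph.gcn.model import ModelConfig, SurvivalGCN
from lunggraph.gcn.nn import Adam
from lunggraph.lung_graph import LungGraph


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    lr_init: float = 0.01
    lr_min: float = 0.00001
    weight_decay: float = 0.00005
    batch_size: int = 32
    seed: int = 0
    plateau_patience: int = 10
    plateau_factor: float = 0.1
    standardize_features: bool = True

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_min > self.lr_init:
            raise ValueError("lr_min must be <= lr_init")
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must be in (0, 1)")


@dataclass
class FeatureScaler:
    """Feature scaling fitted on training node features only.

    Centres each dimension but divides by one *global* standard deviation:
    node features are ridge-shrunk PCA scores whose per-dimension variances
    encode component importance, and per-dimension standardization would
    undo that shrinkage and amplify pure-noise components (verified to
    overfit badly at cohort scale).
    """

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, graphs: Sequence[LungGraph]) -> "FeatureScaler":
        rows = np.concatenate([g.features for g in graphs], axis=0)
        scale = float(rows.std())
        if scale < 1e-12:
            scale = 1.0
        return cls(mean=rows.mean(axis=0), std=np.full(rows.shape[1], scale))

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (features - self.mean) / self.std

    @classmethod
    def identity(cls, dim: int) -> "FeatureScaler":
        return cls(mean=np.zeros(dim), std=np.ones(dim))


@dataclass
class TrainedModel:
    model: SurvivalGCN
    model_config: ModelConfig
    train_config: TrainConfig
    history: list[dict] = field(default_factory=list)
    scaler: Optional[FeatureScaler] = None
    best_epoch: int = -1
    best_val_auc: float = float("nan")

    def predict(self, graphs: Sequence[LungGraph]) -> np.ndarray:
        blocks = None
        if self.scaler is not None:
            blocks = np.stack([self.scaler.transform(g.features) for g in graphs])
        return self.model.predict_many(list(graphs), blocks)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.model.save(path)
        meta = {
            "train_config": self.train_config.__dict__,
            "history": self.history,
            "best_epoch": self.best_epoch,
            "best_val_auc": self.best_val_auc,
            "scaler_mean": None if self.scaler is None else self.scaler.mean.tolist(),
            "scaler_std": None if self.scaler is None else self.scaler.std.tolist(),
        }
        path.with_suffix(".train.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        model = SurvivalGCN.load(path)
        meta = json.loads(path.with_suffix(".train.json").read_text())
        scaler = None
        if meta["scaler_mean"] is not None:
            scaler = FeatureScaler(
                mean=np.asarray(meta["scaler_mean"]), std=np.asarray(meta["scaler_std"])
            )
        return cls(
            model=model,
            model_config=model.config,
            train_config=TrainConfig(**meta["train_config"]),
            history=meta["history"],
            scaler=scaler,
            best_epoch=meta["best_epoch"],
            best_val_auc=meta["best_val_auc"],
        )


def _grouped(
    graphs: Sequence[LungGraph], blocks: np.ndarray, idxs: Sequence[int]
) -> list[tuple[np.ndarray, list[list[int]], np.ndarray]]:
    """Split a set of graph indices into topology groups of (H, adj, y)."""
    by_key: dict[tuple, list[int]] = {}
    for i in idxs:
        by_key.setdefault(graphs[i].topology_key(), []).append(i)
    out = []
    for key in sorted(by_key):
        members = by_key[key]
        H = blocks[members]
        y = np.array([graphs[i].label for i in members], dtype=float)
        out.append((H, graphs[members[0]].neighbor_indices(), y))
    return out


def _bce(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(probs, eps, 1 - eps)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def _eval_set(
    model: SurvivalGCN, groups: list[tuple[np.ndarray, list[list[int]], np.ndarray]]
) -> tuple[float, float]:
    probs_all, y_all = [], []
    for H, adj, y in groups:
        prob, _ = model.forward_group(H, adj)
        probs_all.append(prob)
        y_all.append(y)
    probs = np.concatenate(probs_all)
    y = np.concatenate(y_all)
    return _bce(probs, y), auc_point(probs, y.astype(int))


def train(
    train_graphs: Sequence[LungGraph],
    val_graphs: Sequence[LungGraph],
    mc: ModelConfig = ModelConfig(),
    tc: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Train the survival GCN with binary cross-entropy.

    Requires labelled graphs with both classes present in the training set.
    Per epoch, minibatches are drawn by a seeded shuffle and each batch is
    processed in topology groups; the learning rate is multiplied by
    ``plateau_factor`` when the validation loss has not improved for
    ``plateau_patience`` epochs, never dropping below ``lr_min``.  The
    weights of the best-validation-AUC epoch are returned.
    """
    mc.validate()
    tc.validate()
    if not train_graphs or not val_graphs:
        raise ValueError("train and validation sets must be nonempty")
    labels = [g.label for g in train_graphs]
    if any(l is None for l in labels) or any(g.label is None for g in val_graphs):
        raise ValueError("all graphs must carry a 5-year label for training")
    if len(set(labels)) < 2:
        raise ValueError("training labels are single-class; cannot train a classifier")

    scaler = (
        FeatureScaler.fit(train_graphs)
        if tc.standardize_features
        else FeatureScaler.identity(train_graphs[0].features.shape[1])
    )
    train_blocks = np.stack([scaler.transform(g.features) for g in train_graphs])
    val_blocks = np.stack([scaler.transform(g.features) for g in val_graphs])
    val_groups = _grouped(val_graphs, val_blocks, range(len(val_graphs)))

    model = SurvivalGCN(mc, seed=tc.seed)
    opt = Adam(model.params)
    rng = np.random.default_rng(tc.seed)
    lr = tc.lr_init
    history: list[dict] = []
    best_auc, best_epoch, best_params = -np.inf, -1, model.clone_params()
    best_val_loss, plateau = np.inf, 0
    n = len(train_graphs)

    for epoch in range(tc.epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, tc.batch_size):
            batch = perm[start : start + tc.batch_size]
            groups = _grouped(train_graphs, train_blocks, batch)
            grads_total = {k: np.zeros_like(v) for k, v in model.params.items()}
            batch_loss, n_batch = 0.0, len(batch)
            for H, adj, y in groups:
                prob, caches = model.forward_group(H, adj, training=True, rng=rng)
                batch_loss += _bce(prob, y) * len(y)
                dlogit = (prob - y) / n_batch
                for k, v in model.backward_group(dlogit, adj, caches).items():
                    grads_total[k] += v
            opt.step(model.params, grads_total, lr, tc.weight_decay)
            epoch_losses.append(batch_loss / n_batch)
        val_loss, val_auc = _eval_set(model, val_groups)
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "val_auc": val_auc,
            }
        )
        if val_auc > best_auc:
            best_auc, best_epoch = val_auc, epoch
            best_params = model.clone_params()
        if val_loss < best_val_loss - 1e-6:
            best_val_loss, plateau = val_loss, 0
        else:
            plateau += 1
            if plateau >= tc.plateau_patience and lr > tc.lr_min:
                lr = max(lr * tc.plateau_factor, tc.lr_min)
                plateau = 0
    model.set_params(best_params)
    return TrainedModel(
        model=model,
        model_config=mc,
        train_config=tc,
        history=history,
        scaler=scaler if tc.standardize_features else None,
        best_epoch=best_epoch,
        best_val_auc=float(best_auc),
    )


def predict(trained: TrainedModel, graphs: Sequence[LungGraph]) -> np.ndarray:
    return trained.predict(graphs)


@dataclass
class SweepResult:
    best_config: ModelConfig
    val_aucs: dict[int, float]
    models: dict[int, TrainedModel]


def sweep_blocks(
    train_graphs: Sequence[LungGraph],
    val_graphs: Sequence[LungGraph],
    tc: TrainConfig = TrainConfig(),
    base_config: ModelConfig = ModelConfig(),
) -> SweepResult:
    """Train 1-4 SageConv blocks; return the argmax-validation-AUC config.

    Ties break toward fewer blocks.
    """
    val_aucs: dict[int, float] = {}
    models: dict[int, TrainedModel] = {}
    best_n, best_auc = None, -np.inf
    for n_blocks in (1, 2, 3, 4):
        mc = replace(base_config, n_blocks=n_blocks)
        tm = train(train_graphs, val_graphs, mc, tc)
        auc = auc_point(
            tm.predict(val_graphs), np.array([g.label for g in val_graphs], dtype=int)
        )
        val_aucs[n_blocks] = float(auc)
        models[n_blocks] = tm
        if auc > best_auc + 1e-12:
            best_auc, best_n = auc, n_blocks
    return SweepResult(
        best_config=replace(base_config, n_blocks=best_n),
        val_aucs=val_aucs,
        models=models,
    )
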