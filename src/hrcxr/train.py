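"""Training loop, evaluation and checkpointing.

Optimization follows the published recipe: Adam (0.9, 0.999), initial
learning rate 1e-3, weighted focal loss with per-class weights refreshed each
epoch from the previous round's validation accuracies (uniform in the first
epoch, since no previous round exists).  "Stop when the validation loss is
stable" is operationalized as patience-based early stopping: no improvement
greater than ``min_delta`` for ``patience`` consecutive epochs, capped at
``max_epochs``.  The best-validation parameters are what the checkpoint
keeps.  Runs are bit-reproducible given (seed, config, data) on one platform.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import Network, build_network
from .config import ConfigError, NetworkConfig
from .data import SyntheticDataset, normalize_gray_batch, split_dataset
from .losses import (
    ClassWeights, update_weights, weighted_focal_loss,
    weighted_focal_loss_grad,
)
from .metrics import MetricsReport, evaluate_scores
from .nn import Adam

log = logging.getLogger(__name__)


@dataclass
class TrainState:
    epoch: int = 0
    max_epochs: int = 80
    best_val_loss: float = float("inf")
    bad_epochs: int = 0
    weights: ClassWeights | None = None
    seed: int = 0
    log_rows: list[dict] = field(default_factory=list)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.log_rows)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, net: Network):
    state = {f"param/{k}": v for k, v in net.state_dict().items()}
    state["config_json"] = np.frombuffer(
        json.dumps(net.config.to_dict()).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **state)


def load_checkpoint(path, expect_config: NetworkConfig | None = None) -> Network:
    with np.load(path) as z:
        cfg = NetworkConfig.from_dict(
            json.loads(bytes(z["config_json"].tobytes()).decode())
        )
        if expect_config is not None and cfg != expect_config:
            raise ConfigError(
                "config: checkpoint configuration differs from the expected one"
            )
        net = build_network(cfg)
        net.load_state_dict({
            k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")
        })
    return net


# ---------------------------------------------------------------------------
# batching helpers
# ---------------------------------------------------------------------------

def _predict(net: Network, X_u8: np.ndarray, batch_size: int = 64) -> np.ndarray:
    net.eval()
    out = []
    for i in range(0, len(X_u8), batch_size):
        out.append(net.forward(normalize_gray_batch(X_u8[i:i + batch_size])))
    return np.concatenate(out, axis=0)


def _splits_from_dataset(dataset, ratios, seed):
    if isinstance(dataset, SyntheticDataset):
        index = dataset.to_index()
        tr, te, va = split_dataset(index, ratios, seed=seed)
        pos = {r[0]: i for i, r in enumerate(index.records)}

        def arrays(part):
            ids = [pos[r[0]] for r in part.records]
            return dataset.images[ids], dataset.labels[ids]

        return arrays(tr), arrays(va), arrays(te)
    if isinstance(dataset, dict):
        return dataset["train"], dataset["val"], dataset.get("test")
    raise TypeError("dataset must be a SyntheticDataset or a split dict")


# ---------------------------------------------------------------------------
# train / evaluate
# ---------------------------------------------------------------------------

def train(config: NetworkConfig, dataset, *, max_epochs: int = 80,
          lr: float = 1e-3, batch_size: int = 128, loss: str = "wfl",
          alpha_balance: float = 0.25, gamma: float = 2.0,
          patience: int = 10, min_delta: float = 1e-4, seed: int = 0,
          ratios=(0.7, 0.2, 0.1), checkpoint_path=None, log_path=None,
          verbose: bool = False):
    """Train on (synthetic or pre-split) data; returns (network, TrainState)."""
    if loss not in ("fl", "wfl"):
        raise ConfigError(f"loss: expected 'fl' or 'wfl', got {loss!r}")
    (Xtr, Ytr), (Xva, Yva), _ = _splits_from_dataset(dataset, ratios, seed)
    if Ytr.shape[1] != config.num_classes:
        raise ConfigError(
            f"num_classes: config has {config.num_classes}, "
            f"dataset has {Ytr.shape[1]}"
        )
    n_classes = config.num_classes
    net = build_network(config, seed=seed)
    opt = Adam(net.parameters(), lr=lr)
    shuffle_rng = np.random.default_rng(seed + 1)
    aug_rng = np.random.default_rng(seed + 2)
    state = TrainState(max_epochs=max_epochs, seed=seed,
                       weights=ClassWeights.uniform(n_classes))
    best_params = None

    for epoch in range(1, max_epochs + 1):
        state.epoch = epoch
        net.train()
        order = shuffle_rng.permutation(len(Xtr))
        total, count = 0.0, 0
        for i in range(0, len(order), batch_size):
            ids = order[i:i + batch_size]
            xb = normalize_gray_batch(Xtr[ids])
            flips = aug_rng.random(len(ids)) < 0.5
            xb[flips] = xb[flips, :, :, ::-1]
            yb = Ytr[ids]
            probs = net.forward(xb)
            lval = weighted_focal_loss(probs, yb, state.weights,
                                       alpha_balance, gamma)
            g = weighted_focal_loss_grad(probs, yb, state.weights,
                                         alpha_balance, gamma)
            opt.zero_grad()
            net.backward(g)
            opt.step()
            total += lval * len(ids)
            count += len(ids)
        train_loss = total / count

        val_probs = _predict(net, Xva, batch_size)
        val_loss = weighted_focal_loss(val_probs, Yva, state.weights,
                                       alpha_balance, gamma)
        val_acc = ((val_probs >= 0.5) == (Yva == 1)).mean(axis=0)
        report = evaluate_scores(val_probs, Yva)
        state.log_rows.append(dict(
            epoch=epoch, train_loss=float(train_loss),
            val_loss=float(val_loss), val_mean_auc=float(report.mean_auc),
            val_acc_per_class=json.dumps([round(float(a), 4) for a in val_acc]),
            class_weights=json.dumps(
                [round(float(w), 5) for w in state.weights.w]),
        ))
        if verbose:
            log.info("epoch %d train %.4f val %.4f auc %.3f",
                     epoch, train_loss, val_loss, report.mean_auc)
        if loss == "wfl":
            state.weights = update_weights(val_acc, n_classes)
        if val_loss < state.best_val_loss - min_delta:
            state.best_val_loss = float(val_loss)
            state.bad_epochs = 0
            best_params = {k: v.copy() for k, v in net.state_dict().items()}
        else:
            state.bad_epochs += 1
            if state.bad_epochs >= patience:
                break

    if best_params is not None:
        net.load_state_dict(best_params)
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, net)
    if log_path is not None:
        state.log_frame().to_csv(log_path, index=False)
    return net, state


def evaluate(net: Network, X_u8: np.ndarray, Y: np.ndarray, class_names=None,
             batch_size: int = 64, threshold: float = 0.5) -> MetricsReport:
    """Deterministic evaluation-mode pass over a labelled image set."""
    if Y.shape[1] != net.config.num_classes:
        raise ConfigError(
            f"num_classes: network has {net.config.num_classes}, "
            f"labels have {Y.shape[1]}"
        )
    scores = _predict(net, X_u8, batch_size)
    return evaluate_scores(scores, Y, class_names, threshold)
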