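"""The g2(0) regression network.

Architecture (matching the published topology): an input layer of 215
histogram bins, three hidden convolutional layers of 260 filters each
with kernel size 4, one max-pooling layer followed by dropout, then
three fully connected layers and a single linear output node.  The
total event count N_events of the histogram enters as a side input
concatenated to the flattened feature vector — after the feature
learning stage, never as a histogram bin — where it acts as a
regularizing scale cue (sparse histograms are fed as raw counts, so
the bins alone do not separate a dim emitter from a short acquisition).

Hyperparameters the topology leaves open are fixed here: ReLU hidden
activations, pool size 2, dropout 0.25, fully connected widths
128/64/32, stride-1 same-padding convolutions, Glorot initialization.
Training uses Adamax on the mean-absolute-percentage-error loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .layers import (
    Adamax,
    Conv1DSame,
    Dense,
    Dropout,
    MaxPool1D,
    mape_loss,
    relu,
    relu_backward,
)

__all__ = ["ModelSpec", "TrainConfig", "G2Regressor", "TrainingHistory"]


@dataclass(frozen=True)
class ModelSpec:
    """Network topology.  Defaults are the published configuration."""

    input_bins: int = 215
    conv_layers: int = 3
    filters_per_layer: int = 260
    kernel_size: int = 4
    pool_size: int = 2
    dropout_rate: float = 0.25
    fc_sizes: tuple[int, int, int] = (128, 64, 32)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fc_sizes"] = list(self.fc_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["fc_sizes"] = tuple(d["fc_sizes"])
        return cls(**d)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol: Adamax on MAPE loss for 100 epochs.

    ``train_fraction`` is the scenario-level split; the remaining
    fraction is halved into validation and test by the corpus builder.
    """

    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 0.001  # Keras Adamax default
    beta1: float = 0.9
    beta2: float = 0.999
    train_fraction: float = 0.8
    seed: int = 0
    label_floor: float = 0.01  # MAPE needs positive labels
    restore_best: bool = True  # keep the best-validation-epoch weights

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


class G2Regressor:
    """Convolutional regression of g2(0) from (histogram bins, N_events)."""

    def __init__(self, spec: ModelSpec | None = None, seed: int = 0, dtype=np.float32):
        self.spec = spec or ModelSpec()
        self.dtype = dtype
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0)))
        s = self.spec
        self.convs = []
        c_in = 1
        for _ in range(s.conv_layers):
            self.convs.append(Conv1DSame(c_in, s.filters_per_layer, s.kernel_size, rng, dtype))
            c_in = s.filters_per_layer
        self.pool = MaxPool1D(s.pool_size)
        self.dropout = Dropout(s.dropout_rate)
        flat = (s.input_bins // s.pool_size) * s.filters_per_layer + 1  # +1 for N_events
        self.fcs = []
        n_in = flat
        for width in s.fc_sizes:
            self.fcs.append(Dense(n_in, width, rng, dtype))
            n_in = width
        self.out = Dense(n_in, 1, rng, dtype)

    # ------------------------------------------------------------------ #

    @property
    def _layers_with_params(self):
        return [*self.convs, *self.fcs, self.out]

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers_with_params for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._layers_with_params for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # ------------------------------------------------------------------ #

    def forward(
        self,
        bins: np.ndarray,
        n_events: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Predict g2(0) for a batch.  ``bins``: (B, input_bins) raw counts;
        ``n_events``: (B,).  Returns (B,) raw (unclamped) predictions."""
        if bins.shape[1] != self.spec.input_bins:
            raise ValueError(
                f"expected {self.spec.input_bins} bins, got {bins.shape[1]}"
            )
        x = np.ascontiguousarray(bins, dtype=self.dtype)[:, :, None]
        self._acts = []
        for conv in self.convs:
            x = relu(conv.forward(x, train=train))
            if train:
                self._acts.append(x)
        x = self.pool.forward(x, train=train)
        x = self.dropout.forward(x, train=train, rng=rng)
        B = x.shape[0]
        flat = x.reshape(B, -1)
        z = np.concatenate(
            [flat, np.asarray(n_events, dtype=self.dtype).reshape(B, 1)], axis=1
        )
        self._fc_acts = []
        for fc in self.fcs:
            z = relu(fc.forward(z, train=train))
            if train:
                self._fc_acts.append(z)
        y = self.out.forward(z, train=train)
        return y[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        """Backpropagate a (B,) output gradient; populates layer grads."""
        dz = self.out.backward(dy[:, None])
        for fc, act in zip(reversed(self.fcs), reversed(self._fc_acts)):
            dz = fc.backward(relu_backward(dz, act))
        dflat = dz[:, :-1]  # strip the N_events column
        B = dflat.shape[0]
        Lo = self.spec.input_bins // self.spec.pool_size
        dpool = dflat.reshape(B, Lo, self.spec.filters_per_layer)
        dpool = self.dropout.backward(dpool)
        dx = self.pool.backward(dpool)
        for i, (conv, act) in enumerate(
            zip(reversed(self.convs), reversed(self._acts))
        ):
            last = i == len(self.convs) - 1
            dx = conv.backward(relu_backward(dx, act), need_dx=not last)
        self._acts = []
        self._fc_acts = []

    # ------------------------------------------------------------------ #

    def fit(
        self,
        bins: np.ndarray,
        n_events: np.ndarray,
        labels: np.ndarray,
        cfg: TrainConfig,
        val: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
        verbose: bool = False,
    ) -> TrainingHistory:
        """Train with Adamax on MAPE loss; returns the loss history.

        Labels are clamped to ``cfg.label_floor`` (MAPE needs nonzero
        denominators).  Deterministic given ``cfg.seed``.
        """
        if bins.shape[0] == 0:
            raise ValueError("empty training corpus")
        y = np.maximum(np.asarray(labels, dtype=self.dtype), cfg.label_floor)
        n = bins.shape[0]
        opt = Adamax(
            self.parameters(), lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2
        )
        shuffle_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x5F)))
        drop_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xD0)))
        history = TrainingHistory()
        best_val = np.inf
        best_params: list[np.ndarray] | None = None
        for epoch in range(cfg.epochs):
            order = shuffle_rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                pred = self.forward(bins[idx], n_events[idx], train=True, rng=drop_rng)
                loss, dpred = mape_loss(pred, y[idx])
                self.backward(dpred)
                opt.step(self.gradients())
                losses.append(loss)
            history.train_loss.append(float(np.mean(losses)))
            if val is not None:
                vb, vn, vy = val
                vpred = self.predict(vb, vn)
                vloss, _ = mape_loss(vpred, np.maximum(vy, cfg.label_floor))
                history.val_loss.append(vloss)
                if cfg.restore_best and vloss < best_val:
                    best_val = vloss
                    best_params = [p.copy() for p in self.parameters()]
            if verbose:
                msg = f"epoch {epoch + 1:3d}/{cfg.epochs}  train MAPE {history.train_loss[-1]:7.2f}%"
                if val is not None:
                    msg += f"  val MAPE {history.val_loss[-1]:7.2f}%"
                print(msg)
        if best_params is not None:
            # checkpoint restore: per-epoch validation loss is noisy and the
            # final epoch is not reliably the best one
            for p, b in zip(self.parameters(), best_params):
                p[...] = b
        return history

    def predict(self, bins: np.ndarray, n_events: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference, clamped to the physical range [0, 1.5]."""
        outs = []
        for start in range(0, bins.shape[0], batch_size):
            sl = slice(start, start + batch_size)
            outs.append(self.forward(bins[sl], n_events[sl], train=False))
        return np.clip(np.concatenate(outs), 0.0, 1.5)

    # ------------------------------------------------------------------ #

    def save(self, path: str | Path) -> None:
        """Persist weights (.npz) plus a JSON sidecar with the topology."""
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, **arrays)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"model_spec": self.spec.to_dict()}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "G2Regressor":
        path = Path(path)
        if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
            path = path.with_suffix(path.suffix + ".npz")
        sidecar = path.with_suffix(path.suffix + ".json")
        spec = ModelSpec()
        if sidecar.exists():
            spec = ModelSpec.from_dict(json.loads(sidecar.read_text())["model_spec"])
        model = cls(spec)
        data = np.load(path)
        for i, p in enumerate(model.parameters()):
            loaded = data[f"p{i}"]
            if loaded.shape != p.shape:
                raise ValueError(
                    f"parameter {i} shape {loaded.shape} does not match spec {p.shape}"
                )
            p[...] = loaded
        return model
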