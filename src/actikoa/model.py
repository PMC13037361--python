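"""The multi-modal diurnal activity classifier and its training loop.

The network fuses three input streams: the 24-hour activity profile through
two 1D convolutional blocks (16 then 32 filters, each batch-normalized and
ReLU-activated) followed by global average pooling over the 24 positions;
month and sex through learned embeddings; and age and weight through a
single dense projector with ReLU. The concatenated representation passes
through a two-layer classifier head to class logits. Training minimizes
softmax cross-entropy with Adam for a fixed number of epochs over shuffled
mini-batches; no early stopping or regularization is applied.

Inputs are z-scored per hourly feature and per numeric covariate using
statistics of the training split only; batch-norm statistics are frozen at
inference (running averages), so prediction is batch-size independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .nn import Adam, BatchNorm1d, Conv1dSame, Embedding, Linear, ReLU, cross_entropy, softmax
from .records import HOURS

N_MONTHS = 12
N_SEXES = 2


class SingleClassError(ValueError):
    """Training requires at least two examples of each class."""


@dataclass(frozen=True)
class ModelConfig:
    conv_filters: tuple[int, int] = (16, 32)
    kernel_size: int = 3
    embed_dim_month: int = 4
    embed_dim_sex: int = 2
    projector_dim: int = 8
    classifier_hidden: int = 32
    n_classes: int = 2
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        dims = (*self.conv_filters, self.embed_dim_month, self.embed_dim_sex,
                self.projector_dim, self.classifier_hidden, self.n_classes)
        if any(d < 1 for d in dims):
            raise ValueError("all architecture dimensions must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_filters"] = list(self.conv_filters)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        d = dict(d)
        if "conv_filters" in d:
            d["conv_filters"] = tuple(d["conv_filters"])
        return cls(**d)


@dataclass
class Scaler:
    """Input standardization state, fitted on the training fold only.

    The 24-hour profile is standardized with a single global mean and SD
    (over all hours and training participants) rather than per hour: the
    convolutional encoder pools its feature maps uniformly over time, so
    the diurnal level differences between hours are the only positional
    cue it has, and per-hour centring would erase them. Age and weight are
    z-scored per covariate.
    """

    hour_mean: np.ndarray
    hour_sd: np.ndarray
    num_mean: np.ndarray  # (age, weight)
    num_sd: np.ndarray

    @classmethod
    def fit(cls, profile: np.ndarray, age: np.ndarray, weight: np.ndarray) -> "Scaler":
        num = np.column_stack([age, weight])
        global_sd = profile.std()
        num_sd = num.std(axis=0)
        return cls(
            hour_mean=np.full(HOURS, profile.mean()),
            hour_sd=np.full(HOURS, global_sd if global_sd > 0 else 1.0),
            num_mean=num.mean(axis=0),
            num_sd=np.where(num_sd > 0, num_sd, 1.0),
        )

    def transform(self, arrays: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        profile = (np.asarray(arrays["profile"], float) - self.hour_mean) / self.hour_sd
        num = np.column_stack([arrays["age"], arrays["weight"]])
        return {
            "profile": profile,
            "numeric": (num - self.num_mean) / self.num_sd,
            "month_idx": np.asarray(arrays["month"], int) - 1,
            "sex_idx": np.asarray(arrays["sex"], int),
        }

    def to_dict(self) -> dict:
        return {k: np.asarray(v).tolist() for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scaler":
        return cls(**{k: np.asarray(v, float) for k, v in d.items()})


class DiurnalNet:
    """Conv encoder + categorical embeddings + numeric projector + classifier."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        c1, c2 = config.conv_filters
        self.config = config
        self.conv1 = Conv1dSame(1, c1, config.kernel_size, rng)
        self.bn1 = BatchNorm1d(c1)
        self.relu1 = ReLU()
        self.conv2 = Conv1dSame(c1, c2, config.kernel_size, rng)
        self.bn2 = BatchNorm1d(c2)
        self.relu2 = ReLU()
        self.emb_month = Embedding(N_MONTHS, config.embed_dim_month, rng, "emb.month")
        self.emb_sex = Embedding(N_SEXES, config.embed_dim_sex, rng, "emb.sex")
        self.projector = Linear(2, config.projector_dim, rng, "proj")
        self.relu_proj = ReLU()
        fused = c2 + config.embed_dim_month + config.embed_dim_sex + config.projector_dim
        self.fc1 = Linear(fused, config.classifier_hidden, rng, "head1")
        self.relu_head = ReLU()
        self.fc2 = Linear(config.classifier_hidden, config.n_classes, rng, "head2")
        self._fused_dims = (c2, config.embed_dim_month, config.embed_dim_sex,
                            config.projector_dim)

    # -- plumbing ---------------------------------------------------------
    def parameters(self):
        params = []
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2, self.emb_month,
                      self.emb_sex, self.projector, self.fc1, self.fc2):
            params.extend(layer.parameters())
        return params

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward / backward ----------------------------------------------
    def forward(self, batch: Mapping[str, np.ndarray], train: bool = False) -> np.ndarray:
        x = np.asarray(batch["profile"], float)[:, None, :]  # (B, 1, 24)
        if x.shape[2] != HOURS:
            raise ValueError(f"profile must have {HOURS} values, got {x.shape[2]}")
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x), train))
        h = self.relu2.forward(self.bn2.forward(self.conv2.forward(h), train))
        pooled = h.mean(axis=2)  # global average pooling over 24 positions
        m = self.emb_month.forward(batch["month_idx"])
        s = self.emb_sex.forward(batch["sex_idx"])
        z = self.relu_proj.forward(self.projector.forward(batch["numeric"]))
        fused = np.concatenate([pooled, m, s, z], axis=1)
        return self.fc2.forward(self.relu_head.forward(self.fc1.forward(fused)))

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.fc1.backward(self.relu_head.backward(self.fc2.backward(dlogits)))
        c2, dm, ds, dp = self._fused_dims
        g_pool, g_m, g_s, g_z = np.split(g, np.cumsum([c2, dm, ds])[:3].tolist(), axis=1)
        self.emb_month.backward(g_m)
        self.emb_sex.backward(g_s)
        self.projector.backward(self.relu_proj.backward(g_z))
        gh = np.repeat(g_pool[:, :, None] / HOURS, HOURS, axis=2)
        gh = self.conv2.backward(self.bn2.backward(self.relu2.backward(gh)))
        self.conv1.backward(self.bn1.backward(self.relu1.backward(gh)))

    # -- serialization ----------------------------------------------------
    def state_dict(self) -> dict:
        state = {p.name + f"#{i}": p.data.tolist() for i, p in enumerate(self.parameters())}
        state["bn1.running"] = [self.bn1.running_mean.tolist(), self.bn1.running_var.tolist()]
        state["bn2.running"] = [self.bn2.running_mean.tolist(), self.bn2.running_var.tolist()]
        return state

    def load_state_dict(self, state: Mapping) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[p.name + f"#{i}"], float)
        self.bn1.running_mean = np.asarray(state["bn1.running"][0], float)
        self.bn1.running_var = np.asarray(state["bn1.running"][1], float)
        self.bn2.running_mean = np.asarray(state["bn2.running"][0], float)
        self.bn2.running_var = np.asarray(state["bn2.running"][1], float)


def expected_num_parameters(config: ModelConfig) -> int:
    """Closed-form weight-plus-bias count, layer by layer."""
    c1, c2 = config.conv_filters
    k = config.kernel_size
    fused = c2 + config.embed_dim_month + config.embed_dim_sex + config.projector_dim
    return (
        c1 * (1 * k) + c1          # conv1
        + 2 * c1                   # bn1 gamma/beta
        + c2 * (c1 * k) + c2       # conv2
        + 2 * c2                   # bn2
        + N_MONTHS * config.embed_dim_month
        + N_SEXES * config.embed_dim_sex
        + 2 * config.projector_dim + config.projector_dim
        + fused * config.classifier_hidden + config.classifier_hidden
        + config.classifier_hidden * config.n_classes + config.n_classes
    )


@dataclass
class TrainedModel:
    """A fitted classifier bundled with its preprocessing state."""

    net: DiurnalNet
    scaler: Scaler
    config: ModelConfig
    training_log: list[float] = field(default_factory=list)

    def predict_proba(self, arrays: Mapping[str, np.ndarray],
                      batch_size: int = 512) -> np.ndarray:
        """Class probabilities in evaluation mode (frozen batch-norm stats)."""
        batch = self.scaler.transform(arrays)
        n = batch["profile"].shape[0]
        if n == 0:
            return np.zeros((0, self.config.n_classes))
        out = []
        for start in range(0, n, batch_size):
            sl = slice(start, start + batch_size)
            sub = {k: v[sl] for k, v in batch.items()}
            out.append(softmax(self.net.forward(sub, train=False)))
        return np.vstack(out)

    def save(self, path: str | Path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "scaler": self.scaler.to_dict(),
            "state": self.net.state_dict(),
            "training_log": self.training_log,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        config = ModelConfig.from_dict(payload["config"])
        net = DiurnalNet(config, np.random.default_rng(config.seed))
        net.load_state_dict(payload["state"])
        return cls(net=net, scaler=Scaler.from_dict(payload["scaler"]),
                   config=config, training_log=list(payload["training_log"]))


def _as_arrays(data) -> dict[str, np.ndarray]:
    if hasattr(data, "to_arrays"):
        return data.to_arrays()
    return {k: np.asarray(v) for k, v in data.items()}


def train_fold(train_data, config: ModelConfig) -> TrainedModel:
    """Fit the classifier on one training split.

    Runs exactly ``config.epochs`` passes over shuffled mini-batches of
    ``config.batch_size``, minimizing cross-entropy with Adam at
    ``config.learning_rate``; the final-epoch model is returned (no early
    stopping). Fully determined by ``config.seed`` and the data.
    """
    arrays = _as_arrays(train_data)
    y = np.asarray(arrays["y"], int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise SingleClassError(
            f"training requires >= 2 examples per class, got counts {dict(zip(classes.tolist(), counts.tolist()))}"
        )

    rng = np.random.default_rng(config.seed)
    net = DiurnalNet(config, rng)
    scaler = Scaler.fit(np.asarray(arrays["profile"], float),
                        np.asarray(arrays["age"], float),
                        np.asarray(arrays["weight"], float))
    batch_all = scaler.transform(arrays)
    n = len(y)
    optimizer = Adam(net.parameters(), lr=config.learning_rate)
    log: list[float] = []
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            sub = {k: v[idx] for k, v in batch_all.items()}
            optimizer.zero_grad()
            logits = net.forward(sub, train=True)
            loss, dlogits = cross_entropy(logits, y[idx])
            net.backward(dlogits)
            optimizer.step()
            epoch_loss += loss * idx.size
        log.append(epoch_loss / n)
    return TrainedModel(net=net, scaler=scaler, config=config, training_log=log)


def predict(model: TrainedModel, data) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels (argmax) and class-1 probabilities for a dataset."""
    arrays = _as_arrays(data)
    probs = model.predict_proba(arrays)
    if probs.shape[0] == 0:
        return np.zeros(0, dtype=int), np.zeros(0)
    return probs.argmax(axis=1), probs[:, 1]


def forward(profile: Sequence[float], month: int, sex: str | int, age: float,
            weight: float, model: TrainedModel) -> np.ndarray:
    """Class probabilities for a single participant."""
    if len(profile) != HOURS:
        raise ValueError(f"profile must have {HOURS} values, got {len(profile)}")
    if isinstance(sex, str):
        if sex not in ("male", "female"):
            raise ValueError(f"unknown sex category {sex!r}")
        sex = 1 if sex == "male" else 0
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    arrays = {
        "profile": np.asarray(profile, float)[None, :],
        "month": np.array([month]),
        "sex": np.array([sex]),
        "age": np.array([age], float),
        "weight": np.array([weight], float),
    }
    return model.predict_proba(arrays)[0]
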