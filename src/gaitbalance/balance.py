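"""Five class-balancing strategies behind a single dispatcher.

* ``undersample`` — randomly delete majority rows down to the minority size;
* ``oversample`` — duplicate rows (sampling with replacement) until both
  classes reach half of the requested total;
* ``smote`` — synthetic minority samples by linear interpolation towards one
  of the k=4 nearest same-class neighbours;
* ``gan`` — an adversarial generator trained on the minority rows only
  (dense 128 + LeakyReLU(0.01) + batch-norm + tanh generator vs a dense
  64 + LeakyReLU + sigmoid discriminator, binary cross-entropy, Adam);
* ``ctgan`` — the conditional variant trained on the full labelled table,
  with the one-hot class label concatenated to the generator noise input and
  to the discriminator feature input so samples can be drawn per class.

All augmentation strategies preserve every real row; every output row
carries a ``provenance`` flag (``real`` / ``synthetic``) and the indices of
the real rows it derives from, enabling leakage audits downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from . import _nets
from .prep import feature_columns

STRATEGIES = ("none", "undersample", "oversample", "smote", "gan", "ctgan")


@dataclass
class GanConfig:
    """Architecture and training hyperparameters of the (ct)GAN."""

    noise_dim: int = 32
    gen_hidden: int = 128
    disc_hidden: int = 64
    leaky_alpha: float = 0.01
    epochs: int = 2000
    batch_size: int = 16
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    conditional: bool = False

    def validate(self) -> None:
        if min(self.noise_dim, self.gen_hidden, self.disc_hidden,
               self.epochs, self.batch_size) <= 0:
            raise ValueError("all GAN counts must be > 0")
        if not 0.0 < self.leaky_alpha < 1.0:
            raise ValueError("leaky_alpha must lie in (0, 1)")


@dataclass
class BalanceConfig:
    """Which strategy to run and at what target size."""

    strategy: str = "ctgan"
    target_total: int = 200
    k_neighbors: int = 4
    net_config: GanConfig = field(default_factory=GanConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")
        if self.target_total % 2:
            raise ValueError("target_total must be even for a 1:1 balance")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class BalancedDataset:
    """Feature table plus per-row provenance produced by one strategy."""

    frame: pd.DataFrame          # includes a "provenance" column
    strategy: str
    class_counts: dict
    n_real: int
    n_synth: int
    source_rows: list            # per-row tuples of originating real indices

    def synthetic_frame(self) -> pd.DataFrame:
        return self.frame[self.frame["provenance"] == "synthetic"]

    def real_frame(self) -> pd.DataFrame:
        return self.frame[self.frame["provenance"] == "real"]


def _class_split(df: pd.DataFrame):
    counts = df["class"].value_counts()
    minority = counts.idxmin()
    majority = counts.idxmax()
    if minority == majority:  # equal counts: keep deterministic order
        labels = sorted(counts.index)
        minority, majority = labels[0], labels[1]
    return minority, majority


def _finish(frames: list[pd.DataFrame], strategy: str,
            source_rows: list) -> BalancedDataset:
    for fr in frames:  # attrs may hold DataFrames, which break concat
        fr.attrs = {}
    out = pd.concat(frames, ignore_index=True)
    n_real = int((out["provenance"] == "real").sum())
    return BalancedDataset(
        frame=out, strategy=strategy,
        class_counts=out["class"].value_counts().to_dict(),
        n_real=n_real, n_synth=len(out) - n_real,
        source_rows=source_rows,
    )


def _real_part(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["provenance"] = "real"
    return out


def undersample(df: pd.DataFrame, seed: int = 0) -> BalancedDataset:
    """Randomly delete majority rows (without replacement) to the minority size."""
    rng = np.random.default_rng(seed)
    minority, majority = _class_split(df)
    minor = df[df["class"] == minority]
    major = df[df["class"] == majority]
    keep = rng.choice(major.index.to_numpy(), size=len(minor), replace=False)
    kept = df.loc[np.concatenate([minor.index.to_numpy(), np.sort(keep)])]
    sources = [(i,) for i in kept.index]
    return _finish([_real_part(kept)], "undersample", sources)


def oversample(df: pd.DataFrame, target_total: int = 200,
               seed: int = 0) -> BalancedDataset:
    """Duplicate rows with replacement until each class holds target_total/2."""
    rng = np.random.default_rng(seed)
    per_class = target_total // 2
    frames, sources = [], []
    for label in sorted(df["class"].unique()):
        block = df[df["class"] == label]
        if len(block) > per_class:
            raise ValueError(
                f"target_total/2 = {per_class} below current size of class "
                f"{label!r} ({len(block)} rows)")
        frames.append(_real_part(block))
        sources.extend([(i,) for i in block.index])
        extra = per_class - len(block)
        if extra:
            picks = rng.choice(block.index.to_numpy(), size=extra, replace=True)
            dup = df.loc[picks].copy()
            dup["provenance"] = "synthetic"
            dup["subject_id"] = [f"dup_{label}_{k}" for k in range(extra)]
            frames.append(dup)
            sources.extend([(i,) for i in picks])
    return _finish(frames, "oversample", sources)


def smote(df: pd.DataFrame, k: int = 4, target_total: int = 200,
          seed: int = 0) -> BalancedDataset:
    """SMOTE: synthetic minority rows by interpolation to a random k-NN.

    Each synthetic row is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0, 1)`` and
    ``x_nn`` one of the k Euclidean nearest minority neighbours of ``x_i``.
    The majority class is topped up by plain resampling if it is below
    target_total/2.
    """
    rng = np.random.default_rng(seed)
    minority, majority = _class_split(df)
    minor = df[df["class"] == minority]
    if len(minor) <= k:
        raise ValueError(
            f"minority size {len(minor)} must exceed k={k}; lower k_neighbors")
    per_class = target_total // 2
    feats = feature_columns(df)
    X = minor[feats].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, neigh = nn.kneighbors(X)
    neigh = neigh[:, 1:]  # drop self

    frames, sources = [_real_part(df)], [(i,) for i in df.index]
    n_needed = per_class - len(minor)
    rows = []
    for s in range(max(n_needed, 0)):
        i = rng.integers(len(X))
        j = neigh[i, rng.integers(k)]
        u = rng.random()
        rows.append(X[i] + u * (X[j] - X[i]))
        sources.append((minor.index[i], minor.index[j]))
    if rows:
        synth = pd.DataFrame(rows, columns=feats)
        synth["class"] = minority
        synth["subject_id"] = [f"smote_{s}" for s in range(len(rows))]
        synth["provenance"] = "synthetic"
        frames.append(synth)

    major = df[df["class"] == majority]
    extra = per_class - len(major)
    if extra > 0:
        picks = rng.choice(major.index.to_numpy(), size=extra, replace=True)
        dup = df.loc[picks].copy()
        dup["provenance"] = "synthetic"
        dup["subject_id"] = [f"dup_{majority}_{s}" for s in range(extra)]
        frames.append(dup)
        sources.extend([(i,) for i in picks])
    elif extra < 0:
        raise ValueError("target_total/2 below current majority size")
    return _finish(frames, "smote", sources)


# ---------------------------------------------------------------------------
# GAN / ctGAN
# ---------------------------------------------------------------------------


class _MinMaxScaler:
    """Map features to [-1, 1] (tanh range) and back."""

    def fit(self, X: np.ndarray):
        self.lo = X.min(axis=0)
        self.hi = X.max(axis=0)
        span = self.hi - self.lo
        self.span = np.where(span > 0, span, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (X - self.lo) / self.span - 1.0

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return (Z + 1.0) / 2.0 * self.span + self.lo


class GanHandle:
    """Trained generator with its feature scaler and loss history."""

    def __init__(self, layers, scaler, config: GanConfig, n_features: int,
                 loss_history: pd.DataFrame, class_labels=None):
        self._layers = layers
        self._scaler = scaler
        self.config = config
        self.n_features = n_features
        self.loss_history = loss_history
        self.class_labels = class_labels  # None for the unconditional GAN

    def _gen_forward(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        d1, act, bn, d2 = self._layers
        h = bn.forward(act.forward(d1.forward(z)), train=train)
        return np.tanh(d2.forward(h))

    def sample(self, n: int, seed: int = 0, label=None) -> pd.DataFrame:
        """Draw ``n`` synthetic rows (for ctGAN, of class ``label``)."""
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, self.config.noise_dim))
        if self.class_labels is not None:
            if label is None:
                raise ValueError("conditional generator requires a class label")
            onehot = np.zeros((n, len(self.class_labels)))
            onehot[:, list(self.class_labels).index(label)] = 1.0
            z = np.column_stack([z, onehot])
        out = self._gen_forward(z, train=False)
        return self._scaler.inverse(out)

    def sample_raw(self, n: int, seed: int = 0, label=None) -> np.ndarray:
        """Generator output before inverse scaling (values in [-1, 1])."""
        df = self.sample(n, seed=seed, label=label)
        return self._scaler.transform(np.asarray(df))


def _train_adversarial(X: np.ndarray, cond: np.ndarray | None,
                       config: GanConfig, seed: int,
                       class_labels=None) -> GanHandle:
    """Shared training loop for the GAN (cond=None) and ctGAN."""
    config.validate()
    rng = np.random.default_rng(seed)
    n, d = X.shape
    n_cond = 0 if cond is None else cond.shape[1]

    scaler = _MinMaxScaler().fit(X)
    Xs = scaler.transform(X)

    g_d1 = _nets.Dense(config.noise_dim + n_cond, config.gen_hidden, rng)
    g_act = _nets.LeakyReLU(config.leaky_alpha)
    g_bn = _nets.BatchNorm(config.gen_hidden)
    g_d2 = _nets.Dense(config.gen_hidden, d, rng)
    d_d1 = _nets.Dense(d + n_cond, config.disc_hidden, rng)
    d_act = _nets.LeakyReLU(config.leaky_alpha)
    d_d2 = _nets.Dense(config.disc_hidden, 1, rng)

    g_params = g_d1.params + g_bn.params + g_d2.params
    d_params = d_d1.params + d_d2.params
    opt_g = _nets.Adam(g_params, lr=config.learning_rate, beta1=config.adam_beta1)
    opt_d = _nets.Adam(d_params, lr=config.learning_rate, beta1=config.adam_beta1)

    def disc_forward(x):
        return d_d2.forward(d_act.forward(d_d1.forward(x)))[:, 0]

    def disc_backward(grad):
        return d_d1.backward(d_act.backward(d_d2.backward(grad[:, None])))

    def gen_forward(z, train=True):
        h = g_bn.forward(g_act.forward(g_d1.forward(z)), train=train)
        t = g_d2.forward(h)
        return np.tanh(t)

    def gen_backward(grad_out, tanh_out):
        grad = grad_out * (1.0 - tanh_out**2)
        g_d1.backward(g_act.backward(g_bn.backward(g_d2.backward(grad))))

    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            bs = len(idx)
            real = Xs[idx]
            real_in = real if cond is None else np.column_stack([real, cond[idx]])

            z = rng.standard_normal((bs, config.noise_dim))
            cbatch = None if cond is None else cond[idx]
            z_in = z if cbatch is None else np.column_stack([z, cbatch])
            fake = gen_forward(z_in, train=True)
            fake_in = fake if cbatch is None else np.column_stack([fake, cbatch])

            # --- discriminator update (real -> 1, fake -> 0)
            logits = disc_forward(np.vstack([real_in, fake_in]))
            targets = np.concatenate([np.ones(bs), np.zeros(bs)])
            d_loss, gl = _nets.bce_with_logits(logits, targets)
            disc_backward(gl)
            opt_d.step(d_d1.grads + d_d2.grads)
            if not np.isfinite(d_loss):
                raise FloatingPointError("discriminator loss diverged")

            # --- generator update (non-saturating: fake -> 1)
            z = rng.standard_normal((bs, config.noise_dim))
            z_in = z if cbatch is None else np.column_stack([z, cbatch])
            fake = gen_forward(z_in, train=True)
            fake_in = fake if cbatch is None else np.column_stack([fake, cbatch])
            logits = disc_forward(fake_in)
            g_loss, gl = _nets.bce_with_logits(logits, np.ones(bs))
            grad_fake = disc_backward(gl)[:, :d]
            gen_backward(grad_fake, fake)
            opt_g.step(g_d1.grads + g_bn.grads + g_d2.grads)
            if not np.isfinite(g_loss):
                raise FloatingPointError("generator loss diverged")
            d_losses.append(d_loss)
            g_losses.append(g_loss)
        history.append({"epoch": epoch,
                        "d_loss": float(np.mean(d_losses)),
                        "g_loss": float(np.mean(g_losses))})

    return GanHandle([g_d1, g_act, g_bn, g_d2], scaler, config, d,
                     pd.DataFrame(history), class_labels=class_labels)


def train_gan(minority_df: pd.DataFrame, config: GanConfig | None = None,
              seed: int = 0) -> GanHandle:
    """Train the unconditional GAN on the minority-class rows."""
    config = config or GanConfig()
    feats = feature_columns(minority_df)
    X = minority_df[feats].to_numpy(dtype=float)
    handle = _train_adversarial(X, None, replace(config, conditional=False), seed)
    handle.features = feats
    return handle


def train_ctgan(df: pd.DataFrame, config: GanConfig | None = None,
                seed: int = 0) -> GanHandle:
    """Train the conditional GAN on the full labelled table.

    The one-hot class label is concatenated to the generator noise input and
    to the discriminator feature input, so sampling accepts per-class counts.
    """
    config = config or GanConfig(conditional=True)
    labels = sorted(df["class"].unique())
    if len(labels) < 2:
        raise ValueError("ctGAN requires both classes in the training table")
    feats = feature_columns(df)
    X = df[feats].to_numpy(dtype=float)
    onehot = np.zeros((len(df), len(labels)))
    for j, lab in enumerate(labels):
        onehot[df["class"].to_numpy() == lab, j] = 1.0
    handle = _train_adversarial(X, onehot, replace(config, conditional=True),
                                seed, class_labels=labels)
    handle.features = feats
    return handle


def _synth_frame(handle: GanHandle, n: int, label, feats, seed: int,
                 tag: str) -> pd.DataFrame:
    vals = handle.sample(n, seed=seed,
                         label=label if handle.class_labels is not None else None)
    synth = pd.DataFrame(np.asarray(vals), columns=feats)
    synth["class"] = label
    synth["subject_id"] = [f"{tag}_{label}_{i}" for i in range(n)]
    synth["provenance"] = "synthetic"
    return synth


def gan_balance(df: pd.DataFrame, config: BalanceConfig) -> BalancedDataset:
    """Minority-only GAN augmentation; majority topped up by plain resampling."""
    rng = np.random.default_rng(config.seed)
    minority, majority = _class_split(df)
    minor = df[df["class"] == minority]
    per_class = config.target_total // 2
    feats = feature_columns(df)
    handle = train_gan(minor, config.net_config, seed=config.seed)

    frames, sources = [_real_part(df)], [(i,) for i in df.index]
    n_minor = per_class - len(minor)
    if n_minor > 0:
        frames.append(_synth_frame(handle, n_minor, minority, feats,
                                   seed=config.seed + 1, tag="gan"))
        sources.extend([tuple(minor.index)] * n_minor)
    major = df[df["class"] == majority]
    extra = per_class - len(major)
    if extra > 0:
        picks = rng.choice(major.index.to_numpy(), size=extra, replace=True)
        dup = df.loc[picks].copy()
        dup["provenance"] = "synthetic"
        dup["subject_id"] = [f"dup_{majority}_{i}" for i in range(extra)]
        frames.append(dup)
        sources.extend([(i,) for i in picks])
    elif extra < 0:
        raise ValueError("target_total/2 below current majority size")
    ds = _finish(frames, "gan", sources)
    ds.handle = handle
    return ds


def ctgan_balance(df: pd.DataFrame, config: BalanceConfig) -> BalancedDataset:
    """Conditional GAN augmentation of both classes up to target_total/2 each."""
    per_class = config.target_total // 2
    feats = feature_columns(df)
    handle = train_ctgan(df, config.net_config, seed=config.seed)
    frames, sources = [_real_part(df)], [(i,) for i in df.index]
    for j, label in enumerate(sorted(df["class"].unique())):
        block = df[df["class"] == label]
        n_extra = per_class - len(block)
        if n_extra < 0:
            raise ValueError("target_total/2 below current size of a class")
        if n_extra:
            frames.append(_synth_frame(handle, n_extra, label, feats,
                                       seed=config.seed + 1 + j, tag="ctgan"))
            sources.extend([tuple(df.index)] * n_extra)
    ds = _finish(frames, "ctgan", sources)
    ds.handle = handle
    return ds


def balance(df: pd.DataFrame, config: BalanceConfig) -> BalancedDataset:
    """Dispatch to the configured balancing strategy."""
    config.validate()
    if config.strategy == "none":
        ds = _finish([_real_part(df)], "none", [(i,) for i in df.index])
        return ds
    if config.strategy == "undersample":
        return undersample(df, seed=config.seed)
    if config.strategy == "oversample":
        return oversample(df, target_total=config.target_total, seed=config.seed)
    if config.strategy == "smote":
        return smote(df, k=config.k_neighbors,
                     target_total=config.target_total, seed=config.seed)
    if config.strategy == "gan":
        return gan_balance(df, config)
    return ctgan_balance(df, config)
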