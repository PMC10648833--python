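"""Metric-learning feature extractor producing 128-d unit embeddings.

The embedding network maps a body-crop image to a point on the unit
hypersphere in R^128.  It is trained with a three-stage triplet-mining
curriculum — semi-hard, then hard, then hardest negatives — under the hinge
triplet loss on squared Euclidean distances,

    L(a, p, n) = max(0, d^2(a, p) - d^2(a, n) + margin),

plus a global orthogonal regularizer that pushes the pairwise dot products
of different-identity embeddings toward the statistics of uniformly spread
unit vectors (first moment 0, second moment 1/d).

The default backbone is a compact two-block strided convolutional network
with a dense 128-d head, implemented directly on numpy (im2col convolutions,
analytic backprop, Adam).  It is sized for CPU-scale experiments; anything
honoring the embed() contract (unit-norm 128-vector per image) can stand in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

EMBEDDING_DIM = 128
MINING_MODES = ("semi_hard", "hard", "hardest")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters for the staged triplet curriculum.

    ``margin`` is the triplet hinge margin on squared distances;
    ``batch_identities`` (P) and ``images_per_identity`` (K) define the
    P x K batch composition that guarantees every anchor has a positive.
    """

    margin: float = 0.2
    gor_weight: float = 1.0
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    patience: int = 5
    max_epochs: int = 100
    stages: tuple[str, ...] = ("semi_hard", "hard", "hardest")
    batch_identities: int = 4
    images_per_identity: int = 4
    val_fraction: float = 0.2
    seed: int = 0
    input_size: int = 32

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if not self.stages:
            raise ValueError("stages must be non-empty")
        for stage in self.stages:
            _check_mode(stage)


def _check_mode(mode: str) -> None:
    if mode not in MINING_MODES:
        raise ValueError(f"unknown mining mode {mode!r}; expected one of {MINING_MODES}")


@dataclass
class EmbeddingDataset:
    """Images with identity labels, the unit of training."""

    images: np.ndarray  # (N, H, W, 3) floats in [0, 1]
    labels: np.ndarray  # (N,) identity tokens

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SplitDataset:
    train: EmbeddingDataset
    val: EmbeddingDataset


def split_dataset(dataset: EmbeddingDataset, val_fraction: float, seed: int) -> SplitDataset:
    """Stratified train/validation split (per-class round-up rule)."""
    from .evaluation import stratified_split

    train_idx, val_idx = stratified_split(dataset.labels, test_fraction=val_fraction, seed=seed)
    return SplitDataset(
        train=EmbeddingDataset(dataset.images[train_idx], dataset.labels[train_idx]),
        val=EmbeddingDataset(dataset.images[val_idx], dataset.labels[val_idx]),
    )


# ---------------------------------------------------------------------------
# losses and mining


def triplet_loss(d2_ap: float, d2_an: float, margin: float) -> float:
    """Hinge triplet loss max(0, d2_ap - d2_an + margin) on squared distances."""
    if d2_ap < 0 or d2_an < 0:
        raise ValueError("squared distances must be nonnegative")
    return max(0.0, d2_ap - d2_an + margin)


def gor_term(embeddings: np.ndarray, labels: Sequence) -> float:
    """Global orthogonal regularizer over different-label embedding pairs.

    With s_ij the dot products over all pairs (i, j), i < j, with differing
    labels, M1 their mean and M2 the mean of their squares, returns
    M1^2 + max(0, M2 - 1/d).  Zero when no different-label pair exists.
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    if emb.ndim != 2:
        raise ValueError("embeddings must be a 2-d array (n, d)")
    if len(emb) != len(labels):
        raise ValueError("embeddings and labels must have equal length")
    n, d = emb.shape
    if n < 2:
        return 0.0
    dots = emb @ emb.T
    diff = labels[:, None] != labels[None, :]
    iu = np.triu_indices(n, k=1)
    mask = diff[iu]
    if not mask.any():
        return 0.0
    s = dots[iu][mask]
    m1 = float(s.mean())
    m2 = float((s**2).mean())
    return m1**2 + max(0.0, m2 - 1.0 / d)


def squared_distances(embeddings: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distance matrix, clipped at zero."""
    emb = np.asarray(embeddings, dtype=np.float64)
    sq = (emb**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (emb @ emb.T)
    return np.maximum(d2, 0.0)


def mine_triplets(
    embeddings: np.ndarray,
    labels: Sequence,
    mode: str,
    margin: float,
) -> list[tuple[int, int, int]]:
    """Select (anchor, positive, negative) index triples by difficulty.

    With D2 the squared-distance matrix:
      * ``semi_hard`` keeps triples with D2[a,p] < D2[a,n] < D2[a,p] + margin,
      * ``hard`` keeps D2[a,n] < D2[a,p],
      * ``hardest`` keeps, per (a, p), only the negative minimizing D2[a,n]
        (ties broken by the lowest negative index).

    Anchors without a positive are skipped.  Triples are emitted in
    (anchor, positive, negative) lexicographic order.
    """
    _check_mode(mode)
    labels = np.asarray(labels)
    emb = np.asarray(embeddings, dtype=np.float64)
    if len(emb) != len(labels):
        raise ValueError("embeddings and labels must have equal length")
    n = len(labels)
    d2 = squared_distances(emb)
    triplets: list[tuple[int, int, int]] = []
    for a in range(n):
        same = labels == labels[a]
        positives = np.flatnonzero(same)
        positives = positives[positives != a]
        negatives = np.flatnonzero(~same)
        if len(positives) == 0 or len(negatives) == 0:
            continue
        for p in positives:
            d2_ap = d2[a, p]
            d2_an = d2[a, negatives]
            if mode == "semi_hard":
                keep = negatives[(d2_ap < d2_an) & (d2_an < d2_ap + margin)]
            elif mode == "hard":
                keep = negatives[d2_an < d2_ap]
            else:  # hardest: stable argmin -> lowest index on ties
                keep = np.asarray([negatives[int(np.argmin(d2_an))]])
            triplets.extend((a, int(p), int(nn)) for nn in keep)
    return triplets


# ---------------------------------------------------------------------------
# the convolutional embedder


def _conv_indices(channels: int, height: int, width: int, ksize: int, stride: int, pad: int):
    out_h = (height + 2 * pad - ksize) // stride + 1
    out_w = (width + 2 * pad - ksize) // stride + 1
    i0 = np.tile(np.repeat(np.arange(ksize), ksize), channels)
    j0 = np.tile(np.arange(ksize), ksize * channels)
    i1 = stride * np.repeat(np.arange(out_h), out_w)
    j1 = stride * np.tile(np.arange(out_w), out_h)
    i = i0[:, None] + i1[None, :]
    j = j0[:, None] + j1[None, :]
    c = np.repeat(np.arange(channels), ksize * ksize)[:, None]
    return c, i, j, out_h, out_w


class _ConvLayer:
    """3x3 strided convolution via im2col; channels-first layout."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        fan_in = in_ch * 9
        self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.bias = np.zeros(out_ch)
        self.stride = stride
        self.in_ch = in_ch
        self._idx_cache: dict[tuple[int, int], tuple] = {}

    def _indices(self, height: int, width: int):
        key = (height, width)
        if key not in self._idx_cache:
            self._idx_cache[key] = _conv_indices(self.in_ch, height, width, 3, self.stride, 1)
        return self._idx_cache[key]

    def forward(self, x: np.ndarray):
        n, _, height, width = x.shape
        c, i, j, out_h, out_w = self._indices(height, width)
        x_pad = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = x_pad[:, c, i, j]  # (N, in_ch*9, L)
        out = np.einsum("fk,nkl->nfl", self.weight, cols) + self.bias[None, :, None]
        cache = (cols, x.shape, (c, i, j))
        return out.reshape(n, -1, out_h, out_w), cache

    def backward(self, dout: np.ndarray, cache):
        cols, x_shape, (c, i, j) = cache
        n, _, out_h, out_w = dout.shape
        dflat = dout.reshape(n, -1, out_h * out_w)
        d_weight = np.einsum("nfl,nkl->fk", dflat, cols)
        d_bias = dflat.sum(axis=(0, 2))
        dcols = np.einsum("fk,nfl->nkl", self.weight, dflat)
        _, _, height, width = x_shape
        dx_pad = np.zeros((n, x_shape[1], height + 2, width + 2))
        np.add.at(dx_pad, (slice(None), c, i, j), dcols)
        return dx_pad[:, :, 1:-1, 1:-1], d_weight, d_bias


class ConvEmbedder:
    """Compact strided CNN mapping images to unit-norm 128-d embeddings.

    Architecture: conv3x3/2 (3 -> c1) - ReLU - conv3x3/2 (c1 -> c2) - ReLU -
    flatten - dense -> 128 - L2 normalize.  Inputs are square RGB images in
    [0, 1]; other sizes are resized bilinearly on entry.
    """

    def __init__(self, input_size: int = 32, channels: tuple[int, int] = (12, 24), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_size = int(input_size)
        self.channels = tuple(channels)
        self.seed = int(seed)
        c1, c2 = channels
        self.conv1 = _ConvLayer(3, c1, stride=2, rng=rng)
        self.conv2 = _ConvLayer(c1, c2, stride=2, rng=rng)
        feat = c2 * (input_size // 4) ** 2
        self.dense_w = rng.normal(0.0, np.sqrt(2.0 / feat), size=(feat, EMBEDDING_DIM))
        self.dense_b = np.zeros(EMBEDDING_DIM)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        return {
            "conv1_w": self.conv1.weight, "conv1_b": self.conv1.bias,
            "conv2_w": self.conv2.weight, "conv2_b": self.conv2.bias,
            "dense_w": self.dense_w, "dense_b": self.dense_b,
        }

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for key, value in state.items():
            params[key][...] = value

    def save(self, path: str | Path) -> None:
        meta = np.array([self.input_size, *self.channels, self.seed])
        np.savez(path, _meta=meta, **self.get_state())

    @classmethod
    def load(cls, path: str | Path) -> "ConvEmbedder":
        with np.load(path) as data:
            meta = data["_meta"].astype(int)
            model = cls(input_size=int(meta[0]), channels=(int(meta[1]), int(meta[2])),
                        seed=int(meta[3]))
            model.set_state({k: data[k] for k in data.files if k != "_meta"})
        return model

    # -- forward / backward -------------------------------------------------
    def _prepare(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[None]
        if images.shape[1] != self.input_size or images.shape[2] != self.input_size:
            images = np.stack([self._resize(im) for im in images])
        return images.transpose(0, 3, 1, 2)  # NHWC -> NCHW

    def _resize(self, image: np.ndarray) -> np.ndarray:
        arr = (np.clip(image, 0, 1) * 255).astype(np.uint8)
        out = Image.fromarray(arr).resize((self.input_size, self.input_size), Image.BILINEAR)
        return np.asarray(out, dtype=np.float64) / 255.0

    def forward(self, images: np.ndarray):
        x = self._prepare(images)
        h1, cache1 = self.conv1.forward(x)
        r1 = np.maximum(h1, 0.0)
        h2, cache2 = self.conv2.forward(r1)
        r2 = np.maximum(h2, 0.0)
        flat = r2.reshape(len(r2), -1)
        z = flat @ self.dense_w + self.dense_b
        norm = np.linalg.norm(z, axis=1, keepdims=True)
        norm = np.maximum(norm, 1e-12)
        emb = z / norm
        cache = (cache1, h1, cache2, h2, r2.shape, flat, emb, norm)
        return emb, cache

    def backward(self, d_emb: np.ndarray, cache) -> dict[str, np.ndarray]:
        cache1, h1, cache2, h2, r2_shape, flat, emb, norm = cache
        # through L2 normalization: dz = (de - e (e . de)) / ||z||
        dz = (d_emb - emb * (emb * d_emb).sum(axis=1, keepdims=True)) / norm
        d_dense_w = flat.T @ dz
        d_dense_b = dz.sum(axis=0)
        dflat = dz @ self.dense_w.T
        dr2 = dflat.reshape(r2_shape)
        dh2 = dr2 * (h2 > 0)
        dr1, d_c2w, d_c2b = self.conv2.backward(dh2, cache2)
        dh1 = dr1 * (h1 > 0)
        _, d_c1w, d_c1b = self.conv1.backward(dh1, cache1)
        return {
            "conv1_w": d_c1w, "conv1_b": d_c1b,
            "conv2_w": d_c2w, "conv2_b": d_c2b,
            "dense_w": d_dense_w, "dense_b": d_dense_b,
        }

    # -- inference ----------------------------------------------------------
    def embed_batch(self, images: np.ndarray) -> np.ndarray:
        emb, _ = self.forward(images)
        return emb

    def embed(self, image: np.ndarray) -> np.ndarray:
        """Embed one image to a unit-norm 128-d vector."""
        return self.embed_batch(image)[0]


class RandomProjectionEmbedder:
    """Untrained baseline: seeded random projection of raw pixels to the sphere.

    Useful as a cheap stand-in where only the embed() contract matters
    (store bookkeeping, capacity properties) and no learning is needed.
    """

    def __init__(self, input_size: int = 16, seed: int = 0):
        self.input_size = int(input_size)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self._proj = rng.normal(0.0, 1.0, size=(input_size * input_size * 3, EMBEDDING_DIM))

    def embed_batch(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[None]
        if images.shape[1] != self.input_size:
            resized = []
            for im in images:
                arr = (np.clip(im, 0, 1) * 255).astype(np.uint8)
                out = Image.fromarray(arr).resize(
                    (self.input_size, self.input_size), Image.BILINEAR)
                resized.append(np.asarray(out, dtype=np.float64) / 255.0)
            images = np.stack(resized)
        z = images.reshape(len(images), -1) @ self._proj
        return z / np.maximum(np.linalg.norm(z, axis=1, keepdims=True), 1e-12)

    def embed(self, image: np.ndarray) -> np.ndarray:
        return self.embed_batch(image)[0]


# ---------------------------------------------------------------------------
# training


class EarlyStopper:
    """Patience-based early stopping with best-epoch bookkeeping.

    ``update`` is called once per epoch with the validation loss; it returns
    True when training should stop (no improvement over the best loss for
    ``patience`` consecutive epochs).
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self._bad_epochs = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self._bad_epochs = 0
        else:
            self._bad_epochs += 1
        return self._bad_epochs >= self.patience


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1: float, beta2: float,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, grad in grads.items():
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * grad
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * grad**2
            m_hat = self.m[key] / (1 - self.beta1**self.t)
            v_hat = self.v[key] / (1 - self.beta2**self.t)
            params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _batch_objective(emb: np.ndarray, labels: np.ndarray, mode: str, config: TrainConfig):
    """Mean triplet loss over mined triples + GOR penalty; returns (loss, d_emb)."""
    n, d = emb.shape
    grad = np.zeros_like(emb)
    triplets = mine_triplets(emb, labels, mode, config.margin)
    loss = 0.0
    if triplets:
        tri = np.asarray(triplets)
        a, p, nn = tri[:, 0], tri[:, 1], tri[:, 2]
        d2_ap = ((emb[a] - emb[p]) ** 2).sum(axis=1)
        d2_an = ((emb[a] - emb[nn]) ** 2).sum(axis=1)
        viol = d2_ap - d2_an + config.margin
        active = viol > 0
        loss += float(np.maximum(viol, 0.0).mean())
        if active.any():
            scale = 1.0 / len(tri)
            aa, pp, nnn = a[active], p[active], nn[active]
            np.add.at(grad, aa, 2.0 * scale * (emb[nnn] - emb[pp]))
            np.add.at(grad, pp, 2.0 * scale * (emb[pp] - emb[aa]))
            np.add.at(grad, nnn, 2.0 * scale * (emb[aa] - emb[nnn]))
    if config.gor_weight > 0:
        diff = labels[:, None] != labels[None, :]
        iu = np.triu_indices(n, k=1)
        mask = diff[iu]
        if mask.any():
            rows, cols = iu[0][mask], iu[1][mask]
            s = (emb[rows] * emb[cols]).sum(axis=1)
            n_pairs = len(s)
            m1 = s.mean()
            m2 = (s**2).mean()
            loss += config.gor_weight * (m1**2 + max(0.0, m2 - 1.0 / d))
            ds = np.full(n_pairs, 2.0 * m1 / n_pairs)
            if m2 > 1.0 / d:
                ds = ds + 2.0 * s / n_pairs
            ds *= config.gor_weight
            np.add.at(grad, rows, ds[:, None] * emb[cols])
            np.add.at(grad, cols, ds[:, None] * emb[rows])
    return loss, grad


def _evaluation_loss(model: ConvEmbedder, dataset: EmbeddingDataset, mode: str,
                     config: TrainConfig) -> float:
    emb = model.embed_batch(dataset.images)
    loss, _ = _batch_objective(emb, dataset.labels, mode, config)
    return loss


def _make_batches(labels: np.ndarray, config: TrainConfig, rng: np.random.Generator):
    """P x K batches: P identities per batch, K images per identity."""
    classes = np.unique(labels)
    by_class = {c: np.flatnonzero(labels == c) for c in classes}
    order = rng.permutation(len(classes))
    p = min(config.batch_identities, len(classes))
    batches = []
    for start in range(0, len(classes), p):
        chosen = classes[order[start:start + p]]
        if len(chosen) < 2 and len(classes) >= 2:
            continue  # a single-identity tail batch mines nothing
        idx = []
        for c in chosen:
            pool = by_class[c]
            take = rng.choice(pool, size=config.images_per_identity,
                              replace=len(pool) < config.images_per_identity)
            idx.extend(take.tolist())
        batches.append(np.asarray(idx))
    return batches


def train_stage(model: ConvEmbedder, dataset: SplitDataset, mode: str,
                config: TrainConfig) -> tuple[ConvEmbedder, list[dict]]:
    """One curriculum stage: Adam on mined-triplet loss + GOR, early stopped.

    Runs at most ``config.max_epochs`` epochs; stops when the validation
    loss has not improved for ``config.patience`` consecutive epochs, and
    restores the best-validation weights.  Returns (model, history) where
    history holds one dict per epoch with train/val losses.
    """
    _check_mode(mode)
    if len(np.unique(dataset.train.labels)) < 2:
        raise ValueError("training requires at least 2 identities")
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    optimizer = _Adam(params, config.learning_rate, config.beta1, config.beta2)
    stopper = EarlyStopper(config.patience)
    best_state = model.get_state()
    history: list[dict] = []
    for epoch in range(1, config.max_epochs + 1):
        epoch_losses = []
        for idx in _make_batches(dataset.train.labels, config, rng):
            emb, cache = model.forward(dataset.train.images[idx])
            loss, d_emb = _batch_objective(emb, dataset.train.labels[idx], mode, config)
            epoch_losses.append(loss)
            if np.any(d_emb):
                grads = model.backward(d_emb, cache)
                optimizer.step(params, grads)
        val_loss = _evaluation_loss(model, dataset.val, mode, config)
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)) if epoch_losses else 0.0,
            "val_loss": float(val_loss),
        })
        improved = val_loss < stopper.best_loss
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_state = model.get_state()
        if stop:
            break
    model.set_state(best_state)
    return model, history


def staged_train(model: ConvEmbedder, dataset: EmbeddingDataset | SplitDataset,
                 config: TrainConfig) -> tuple[ConvEmbedder, list[list[dict]]]:
    """Run the full mining curriculum (one train_stage per configured stage).

    An unsplit dataset is stratified-split at (1 - val_fraction) : val_fraction
    first.  Returns (model, histories) with one history per stage.
    """
    if isinstance(dataset, EmbeddingDataset):
        dataset = split_dataset(dataset, config.val_fraction, config.seed)
    histories = []
    for mode in config.stages:
        model, history = train_stage(model, dataset, mode, config)
        histories.append(history)
    return model, histories


def fine_tune(model: ConvEmbedder, dataset: EmbeddingDataset | SplitDataset,
              config: TrainConfig) -> tuple[ConvEmbedder, list[dict]]:
    """Adapt a trained extractor to relabeled data.

    A single hardest-mode stage at one tenth of the configured learning
    rate — enough to follow gradual appearance drift without unlearning the
    original metric.  The spread regularizer is off during fine-tuning (the
    embedding layout is already established), and the incoming weights are
    kept unless the stage actually improves the validation loss, so
    fine-tuning never degrades a model that still fits the data.
    """
    if isinstance(dataset, EmbeddingDataset):
        dataset = split_dataset(dataset, config.val_fraction, config.seed)
    ft_config = replace(config, learning_rate=config.learning_rate * 0.1,
                        gor_weight=0.0)
    if ft_config.max_epochs < 1:
        return model, []
    initial_state = model.get_state()
    initial_val = _evaluation_loss(model, dataset.val, "hardest", ft_config)
    model, history = train_stage(model, dataset, "hardest", ft_config)
    best_val = min(row["val_loss"] for row in history)
    if initial_val <= best_val:
        model.set_state(initial_state)
    return model, history


def embeddings_to_frame(embeddings: np.ndarray, identity_ids, session_ids):
    """Tabulate embeddings as (identity_id, session_id, v0..v127) for CSV export."""
    import pandas as pd

    emb = np.asarray(embeddings)
    data = {"identity_id": list(identity_ids), "session_id": list(session_ids)}
    for j in range(emb.shape[1]):
        data[f"v{j}"] = emb[:, j]
    return pd.DataFrame(data)
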