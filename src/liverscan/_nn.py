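"""Compact fully-connected networks on numpy.

Two network families are used throughout the pipeline:

* :class:`SoftmaxMLP` — the classification head used at every hierarchy
  stage: two fully connected layers (one hidden layer + linear output)
  trained with cross-entropy, AdamW (lr 1e-4), and early stopping with
  patience 10 on a held-out validation split.
* :class:`TripletEncoder` — a three-layer MLP (batch normalization +
  leaky ReLU after the hidden layers) mapping stage features to a 64-d
  metric space, trained with the squared-distance triplet hinge

      L(a, p, n) = max(|a - p|^2 - |a - n|^2 + alpha, 0)

  using online batch-hard mining: within each minibatch every sample is
  an anchor paired with its hardest (farthest) positive and hardest
  (closest) negative.

Everything is deterministic given a seed: initialization, minibatch
shuffling and the validation split all draw from one Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class DataError(ValueError):
    """Training data violates a precondition (missing class, too few samples)."""


# ---------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-style init, suited to (leaky-)ReLU nonlinearities
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [("W", self, "gW", True), ("b", self, "gb", False)]


class _LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)

    def params(self):
        return []


class _ReLU(_LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class _BatchNorm:
    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.ggamma = np.zeros(n)
        self.gbeta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training and x.shape[0] > 1:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        m = grad.shape[0]
        self.ggamma = (grad * self._xhat).sum(axis=0)
        self.gbeta = grad.sum(axis=0)
        gxhat = grad * self.gamma
        return (
            gxhat - gxhat.mean(axis=0) - self._xhat * (gxhat * self._xhat).mean(axis=0)
        ) / self._std

    def params(self):
        return [("gamma", self, "ggamma", False), ("beta", self, "gbeta", False)]


class _Net:
    """A feed-forward stack with AdamW updates."""

    def __init__(self, layers: list):
        self.layers = layers
        self._opt_state: dict = {}
        self._t = 0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def adamw_step(
        self, lr: float, weight_decay: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8
    ) -> None:
        self._t += 1
        for li, layer in enumerate(self.layers):
            for name, obj, gname, decay in layer.params():
                key = (li, name)
                p = getattr(obj, name)
                g = getattr(obj, gname)
                if key not in self._opt_state:
                    self._opt_state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self._opt_state[key]
                m = beta1 * m + (1 - beta1) * g
                v = beta2 * v + (1 - beta2) * g * g
                self._opt_state[key] = (m, v)
                mhat = m / (1 - beta1**self._t)
                vhat = v / (1 - beta2**self._t)
                step = mhat / (np.sqrt(vhat) + eps)
                if decay:  # decoupled weight decay on weight matrices only
                    step = step + weight_decay * p
                setattr(obj, name, p - lr * step)

    def state(self) -> list:
        out = []
        for layer in self.layers:
            d = {}
            for attr in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                if hasattr(layer, attr):
                    d[attr] = getattr(layer, attr).copy()
            out.append(d)
        return out

    def load_state(self, state: list) -> None:
        for layer, d in zip(self.layers, state):
            for attr, val in d.items():
                setattr(layer, attr, val.copy())


# ---------------------------------------------------------------------
# softmax classifier (two fully connected layers)
# ---------------------------------------------------------------------


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _validation_mask(
    y_idx: np.ndarray,
    k: int,
    groups: Optional[np.ndarray],
    val_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Early-stopping validation split.

    When ``groups`` (e.g. subject ids) are given and at least three
    groups carry every class, one whole group is held out: validation
    then measures inter-subject generalization, the quantity early
    stopping is meant to protect, instead of within-subject fit (which a
    network can improve by memorizing subject-specific appearance).
    Otherwise falls back to a stratified random split.
    """
    n = len(y_idx)
    val_mask = np.zeros(n, dtype=bool)
    if groups is not None:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        if len(uniq) >= 3:
            candidates = []
            for g in uniq:
                rest = y_idx[groups != g]
                if len(np.unique(rest)) == k and np.bincount(rest, minlength=k).min() >= 2:
                    candidates.append(g)
            if candidates:
                held = candidates[int(rng.integers(len(candidates)))]
                val_mask[groups == held] = True
                return val_mask
    for c in range(k):
        members = np.nonzero(y_idx == c)[0]
        members = members[rng.permutation(len(members))]
        n_val = max(1, int(round(val_fraction * len(members)))) if len(members) > 1 else 0
        val_mask[members[:n_val]] = True
    return val_mask


@dataclass
class TrainConfig:
    """Optimization settings shared by the pipeline's classifiers.

    Learning rate 1e-4 with AdamW and patience-10 early stopping on
    validation loss; the epoch cap exists only as a safety net, early
    stopping is the intended termination.
    """

    lr: float = 1e-4
    weight_decay: float = 0.01
    batch_size: int = 64
    max_epochs: int = 500
    patience: int = 10
    val_fraction: float = 0.15
    hidden: int = 256
    seed: int = 0


class SoftmaxMLP:
    """Hidden layer + linear output, cross-entropy, AdamW, early stopping.

    Inputs are standardized with the training mean/std (constant features
    are left untouched).  Classes are remapped to a dense 0..K-1 range
    internally; `classes_` records the original labels.
    """

    def __init__(self, config: Optional[TrainConfig] = None):
        self.config = config or TrainConfig()
        self.net: Optional[_Net] = None
        self.classes_: Optional[np.ndarray] = None
        self.loss_history_: list = []

    def fit(
        self, X: np.ndarray, y: np.ndarray, groups: Optional[np.ndarray] = None
    ) -> "SoftmaxMLP":
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        k = len(self.classes_)
        if k < 2:
            raise DataError("need at least 2 classes to train a classifier")
        rng = np.random.default_rng(cfg.seed)

        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - self._mu) / self._sd

        val_mask = _validation_mask(y_idx, k, groups, cfg.val_fraction, rng)
        Xtr, ytr = Xs[~val_mask], y_idx[~val_mask]
        Xva, yva = Xs[val_mask], y_idx[val_mask]
        if len(Xva) == 0:  # tiny datasets: validate on the training set
            Xva, yva = Xtr, ytr

        net = _Net(
            [
                _Dense(X.shape[1], cfg.hidden, rng),
                _ReLU(),
                _Dense(cfg.hidden, k, rng),
            ]
        )
        best_state, best_val, since_best = net.state(), np.inf, 0
        self.loss_history_ = []
        n = len(Xtr)
        for _epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = Xtr[idx], ytr[idx]
                probs = _softmax(net.forward(xb, training=True))
                epoch_loss += -np.log(probs[np.arange(len(yb)), yb] + 1e-12).sum()
                grad = probs.copy()
                grad[np.arange(len(yb)), yb] -= 1.0
                net.backward(grad / len(yb))
                net.adamw_step(cfg.lr, cfg.weight_decay)
            probs = _softmax(net.forward(Xva, training=False))
            val_loss = -np.log(probs[np.arange(len(yva)), yva] + 1e-12).mean()
            self.loss_history_.append((epoch_loss / n, float(val_loss)))
            if val_loss < best_val - 1e-6:
                best_val, best_state, since_best = val_loss, net.state(), 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        net.load_state(best_state)
        self.net = net
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self._mu) / self._sd
        return _softmax(self.net.forward(Xs, training=False))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def state_dict(self) -> dict:
        return {
            "net": self.net.state(),
            "mu": self._mu,
            "sd": self._sd,
            "classes": self.classes_,
            "hidden": self.config.hidden,
        }

    @classmethod
    def from_state(cls, state: dict, config: Optional[TrainConfig] = None) -> "SoftmaxMLP":
        obj = cls(config or TrainConfig(hidden=int(state["hidden"])))
        d_in = state["net"][0]["W"].shape[0]
        k = state["net"][-1]["W"].shape[1]
        rng = np.random.default_rng(0)
        obj.net = _Net([_Dense(d_in, obj.config.hidden, rng), _ReLU(), _Dense(obj.config.hidden, k, rng)])
        obj.net.load_state(state["net"])
        obj._mu, obj._sd = state["mu"], state["sd"]
        obj.classes_ = state["classes"]
        return obj


# ---------------------------------------------------------------------
# triplet loss + encoder
# ---------------------------------------------------------------------


def triplet_loss(a: np.ndarray, p: np.ndarray, n: np.ndarray, margin: float = 1.0) -> float:
    """Hinge on the squared-distance difference:
    max(|a-p|^2 - |a-n|^2 + margin, 0)."""
    a, p, n = (np.asarray(v, dtype=float) for v in (a, p, n))
    if not (a.shape == p.shape == n.shape):
        raise ValueError(f"triplet dimensions differ: {a.shape}, {p.shape}, {n.shape}")
    d_ap = float(np.sum((a - p) ** 2))
    d_an = float(np.sum((a - n) ** 2))
    return max(d_ap - d_an + margin, 0.0)


def _pairwise_sq_dists(z: np.ndarray) -> np.ndarray:
    sq = np.sum(z * z, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (z @ z.T)
    return np.maximum(d2, 0.0)


@dataclass
class TripletConfig:
    """Encoder settings: three layers to a 64-d embedding, margin 1,
    batch normalization and leaky-ReLU after the hidden layers.

    The hidden width is kept small and the weight decay relatively
    strong: the encoder is fitted on the clear subset of a single fold's
    training subjects, and an over-parameterized metric net collapses the
    mined triplet loss to zero by memorizing those subjects, which ruins
    the embedding for unseen subjects.  Early stopping monitors the
    mined loss on a held-out validation fraction of the clear data."""

    embedding_dim: int = 64
    hidden: int = 64
    leaky_slope: float = 0.2
    margin: float = 1.0
    lr: float = 1e-3
    weight_decay: float = 0.05
    batch_size: int = 64
    max_epochs: int = 500
    patience: int = 10
    val_fraction: float = 0.2
    monitor: str = "loss"  # "loss": mined triplet loss; "knn": held-out 3-NN accuracy
    pca_components: Optional[int] = 64  # projection front end; None disables
    pca_whiten: bool = False  # equalize component variances (off: keep raw metric)
    l2_normalize: bool = True  # unit-norm embeddings (cosine KNN geometry)
    residual: bool = True  # zero-init last layer + whitened-PCA skip path
    seed: int = 0


class TripletEncoder:
    """Three-layer metric-learning MLP trained with batch-hard triplets.

    Stops when the epoch-mean mined loss fails to improve for `patience`
    epochs; the best-loss weights are restored.  `loss_history_` records
    the mean mined loss per epoch.
    """

    def __init__(self, config: Optional[TripletConfig] = None):
        self.config = config or TripletConfig()
        self.net: Optional[_Net] = None
        self.loss_history_: list = []
        self.val_loss_history_: list = []

    def _build(self, d_in: int, rng: np.random.Generator) -> _Net:
        cfg = self.config
        return _Net(
            [
                _Dense(d_in, cfg.hidden, rng),
                _BatchNorm(cfg.hidden),
                _LeakyReLU(cfg.leaky_slope),
                _Dense(cfg.hidden, cfg.hidden, rng),
                _BatchNorm(cfg.hidden),
                _LeakyReLU(cfg.leaky_slope),
                _Dense(cfg.hidden, cfg.embedding_dim, rng),
            ]
        )

    def fit(
        self, X: np.ndarray, y: np.ndarray, groups: Optional[np.ndarray] = None
    ) -> "TripletEncoder":
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise DataError("triplet training needs >= 2 classes")
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            few = classes[counts < 2]
            raise DataError(f"each class needs >= 2 samples; too few for: {list(few)}")
        rng = np.random.default_rng(cfg.seed)
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - self._mu) / self._sd
        self._pca_mean = None
        self._pca_proj = None
        if cfg.pca_components is not None:
            # whitening front end: project onto the leading principal axes
            # and equalize their variance, so the metric net starts from a
            # well-conditioned, low-dimensional view of the features
            from sklearn.decomposition import PCA

            n_comp = min(cfg.pca_components, Xs.shape[0] - 1, Xs.shape[1])
            pca = PCA(n_components=n_comp, random_state=cfg.seed).fit(Xs)
            self._pca_mean = pca.mean_
            proj = pca.components_.T
            if cfg.pca_whiten:
                proj = proj / np.sqrt(pca.explained_variance_)
            self._pca_proj = proj.copy()
            Xs = (Xs - self._pca_mean) @ self._pca_proj

        # early stopping monitors mined loss on held-out samples (a whole
        # subject when possible), not the (memorizable) training loss
        val_mask = _validation_mask(y_idx, len(classes), groups, cfg.val_fraction, rng)
        if (~val_mask).sum() < 3 or len(np.unique(y_idx[~val_mask])) < 2:
            val_mask[:] = False
        Xtr, ytr = Xs[~val_mask], y_idx[~val_mask]
        Xva, yva = Xs[val_mask], y_idx[val_mask]
        use_val = len(Xva) >= 3 and len(np.unique(yva)) >= 2

        def mined_loss(xb: np.ndarray, yb: np.ndarray) -> float:
            z = self._embed_fn(xb, False)
            d2 = _pairwise_sq_dists(z)
            same = yb[:, None] == yb[None, :]
            np.fill_diagonal(same, False)
            diff = yb[:, None] != yb[None, :]
            has_pos = same.any(axis=1) & diff.any(axis=1)
            if not has_pos.any():
                return 0.0
            pos = np.argmax(np.where(same, d2, -np.inf), axis=1)
            neg = np.argmin(np.where(diff, d2, np.inf), axis=1)
            a = np.nonzero(has_pos)[0]
            return float(np.maximum(d2[a, pos[a]] - d2[a, neg[a]] + cfg.margin, 0.0).mean())

        def val_monitor() -> float:
            # model-selection criterion: the embedding exists to support
            # nearest-prototype voting, so score held-out samples by 3-NN
            # against the training embeddings (lower = better, negated acc)
            if cfg.monitor == "loss" or not use_val:
                return mined_loss(Xva, yva) if use_val else -1.0
            ztr = self._embed_fn(Xtr, False)
            zva = self._embed_fn(Xva, False)
            sq = np.sum(ztr * ztr, axis=1)
            d2 = np.maximum(
                np.sum(zva * zva, axis=1)[:, None] + sq[None, :] - 2.0 * zva @ ztr.T, 0.0
            )
            k = min(3, len(ztr))
            nn = np.argsort(d2, axis=1, kind="stable")[:, :k]
            correct = 0
            for i in range(len(zva)):
                votes = np.bincount(ytr[nn[i]], minlength=len(classes))
                top = np.flatnonzero(votes == votes.max())
                pred = top[0] if len(top) == 1 else ytr[nn[i][0]]
                correct += int(pred == yva[i])
            return -correct / len(zva)

        net = self._build(Xs.shape[1], rng)
        self.net = net
        self._use_skip = bool(cfg.residual and self._pca_proj is not None)
        if self._use_skip:
            # start exactly at the whitened-PCA metric: the last layer is
            # zeroed and the projected input is added to the output, so the
            # net learns a residual refinement of an already-usable metric
            net.layers[-1].W[:] = 0.0
            net.layers[-1].b[:] = 0.0

        def embed(xb: np.ndarray, training: bool) -> np.ndarray:
            z = net.forward(xb, training)
            if self._use_skip:
                z = z + self._skip(xb)
            return z

        self._embed_fn = embed
        # the untrained (pure-skip) state competes in model selection
        best_state, since_best = net.state(), 0
        best_loss = val_monitor() if use_val else np.inf
        self.loss_history_ = []
        n = len(Xtr)
        for _epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            total, total_n = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = Xtr[idx], ytr[idx]
                # a usable batch needs a positive and a negative for someone
                if len(np.unique(yb)) < 2 or len(xb) < 3:
                    continue
                z = self._embed_fn(xb, True)
                d2 = _pairwise_sq_dists(z)
                same = yb[:, None] == yb[None, :]
                np.fill_diagonal(same, False)
                diff = yb[:, None] != yb[None, :]
                has_pos = same.any(axis=1)
                # batch-hard: farthest positive, closest negative
                pos_idx = np.argmax(np.where(same, d2, -np.inf), axis=1)
                neg_idx = np.argmin(np.where(diff, d2, np.inf), axis=1)
                anchors = np.nonzero(has_pos)[0]
                d_ap = d2[anchors, pos_idx[anchors]]
                d_an = d2[anchors, neg_idx[anchors]]
                losses = d_ap - d_an + cfg.margin
                active = losses > 0
                total += float(np.maximum(losses, 0.0).sum())
                total_n += len(anchors)
                grad = np.zeros_like(z)
                act = anchors[active]
                if len(act):
                    scale = 2.0 / len(anchors)
                    for i, pi, ni in zip(act, pos_idx[act], neg_idx[act]):
                        grad[i] += scale * ((z[ni] - z[pi]))
                        grad[pi] += scale * (z[pi] - z[i])
                        grad[ni] += scale * (z[i] - z[ni])
                net.backward(grad)
                net.adamw_step(cfg.lr, cfg.weight_decay)
            mean_loss = total / max(total_n, 1)
            self.loss_history_.append(mean_loss)
            monitor = val_monitor() if use_val else mean_loss
            self.val_loss_history_.append(monitor)
            if monitor < best_loss - 1e-6:
                best_loss, best_state, since_best = monitor, net.state(), 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        net.load_state(best_state)
        return self

    def _skip(self, xp: np.ndarray) -> np.ndarray:
        d = self.config.embedding_dim
        if xp.shape[1] >= d:
            return xp[:, :d]
        return np.pad(xp, ((0, 0), (0, d - xp.shape[1])))

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self._mu) / self._sd
        if self._pca_proj is not None:
            Xs = (Xs - self._pca_mean) @ self._pca_proj
        z = self.net.forward(Xs, training=False)
        if self._use_skip:
            z = z + self._skip(Xs)
        if self.config.l2_normalize:
            z = z / np.maximum(np.linalg.norm(z, axis=1, keepdims=True), 1e-12)
        return z

    def state_dict(self) -> dict:
        out = {
            "net": self.net.state(),
            "mu": self._mu,
            "sd": self._sd,
            "config": {
                "embedding_dim": self.config.embedding_dim,
                "hidden": self.config.hidden,
                "margin": self.config.margin,
                "leaky_slope": self.config.leaky_slope,
                "l2_normalize": self.config.l2_normalize,
                "pca_whiten": self.config.pca_whiten,
                "residual": self.config.residual,
            },
        }
        out["use_skip"] = np.array(self._use_skip)
        if self._pca_proj is not None:
            out["pca_mean"] = self._pca_mean
            out["pca_proj"] = self._pca_proj
        return out

    @classmethod
    def from_state(cls, state: dict) -> "TripletEncoder":
        cfg = TripletConfig(**dict(state["config"]))
        obj = cls(cfg)
        d_in = state["net"][0]["W"].shape[0]
        obj.net = obj._build(d_in, np.random.default_rng(0))
        obj.net.load_state(state["net"])
        obj._mu, obj._sd = state["mu"], state["sd"]
        obj._pca_mean = state.get("pca_mean")
        obj._pca_proj = state.get("pca_proj")
        obj._use_skip = bool(state.get("use_skip", False))
        return obj
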