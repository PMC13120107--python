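"""Straight-through-estimator training of the binarized CNN.

Training keeps real-valued latent weights; the forward pass binarizes them
with sign (sign(0) = +1, matching the bit decoding used at inference) and
the backward pass treats sign as the identity inside [-1, 1] (the
straight-through estimator), after which latent weights are clipped back to
[-1, 1]. Activations binarize the batch-norm output with sign; their
gradient is the hard-tanh window 1{|y| <= 1}.

After training, every batch norm is folded into a per-channel integer
popcount threshold (T = mu - (beta/gamma) sqrt(sigma2 + eps), converted to
the popcount grid) and the latent weights are hardened to bits, yielding a
:class:`~radarfall.bcnn.BCNNModel` whose integer inference reproduces the
eval-mode float network exactly.

Implemented directly on numpy: the networks involved are a few tens of
thousands of binary weights, for which explicit im2col forward/backward
passes are entirely adequate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .bcnn import (
    FALL,
    NON_FALL,
    BCNNModel,
    NetworkSpec,
    TrainConfig,
    infer,
    popcount_threshold_from_real,
)

__all__ = [
    "SpectrogramDataset",
    "TrainResult",
    "EvalResult",
    "train",
    "train_detailed",
    "evaluate_kfold",
    "predict_batch",
]

BN_EPS = 1e-5
BN_MOMENTUM = 0.1


@dataclass
class SpectrogramDataset:
    """Labeled binary spectrograms: x is (n, 1, 24, 24) bits, y is 0/1
    (non-fall / fall); activity codes and subject ids ride along for
    stratification and LOSO grouping."""

    x: np.ndarray
    y: np.ndarray
    codes: Optional[np.ndarray] = None
    subject_ids: Optional[np.ndarray] = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.uint8)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.x.ndim == 3:
            self.x = self.x[:, None, :, :]
        if len(self.x) != len(self.y):
            raise ValueError("x and y lengths differ")

    def __len__(self) -> int:
        return len(self.y)


# ---------------------------------------------------------------------------
# layer machinery


class _Adam:
    def __init__(self, shape):
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def step(self, param, grad, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        self.m = b1 * self.m + (1 - b1) * grad
        self.v = b2 * self.v + (1 - b2) * grad * grad
        mhat = self.m / (1 - b1**self.t)
        vhat = self.v / (1 - b2**self.t)
        return param - lr * mhat / (np.sqrt(vhat) + eps)


def _sign_pm1(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, 1.0, -1.0)


class _BatchNorm:
    """Per-channel batch norm over all remaining axes (channel axis 1)."""

    def __init__(self, channels: int):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.opt_g = _Adam(channels)
        self.opt_b = _Adam(channels)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        shape = (1, -1) + (1,) * (x.ndim - 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // x.shape[1]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = (1 - BN_MOMENTUM) * self.running_mean + BN_MOMENTUM * mean
            self.running_var = (1 - BN_MOMENTUM) * self.running_var + BN_MOMENTUM * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + BN_EPS)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        if train:
            self._cache = (xhat, inv_std, axes, shape)
        return self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)

    def backward(self, dy: np.ndarray, lr: float) -> np.ndarray:
        xhat, inv_std, axes, shape = self._cache
        n = dy.size // dy.shape[1]
        dgamma = (dy * xhat).sum(axis=axes)
        dbeta = dy.sum(axis=axes)
        dxhat = dy * self.gamma.reshape(shape)
        dx = (
            inv_std.reshape(shape)
            / n
            * (n * dxhat - dxhat.sum(axis=axes).reshape(shape) - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape))
        )
        self.gamma = self.opt_g.step(self.gamma, dgamma, lr)
        self.beta = self.opt_b.step(self.beta, dbeta, lr)
        return dx


class _BinConv:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (c_in * k * k + c_out * k * k))
        self.w = rng.uniform(-limit, limit, size=(c_out, c_in, k, k))
        self.k = k
        self.opt = _Adam(self.w.shape)
        self.bn = _BatchNorm(c_out)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, h, w = x.shape
        k = self.k
        oh, ow = h - k + 1, w - k + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        patches = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, oh * ow, c * k * k)
        wb = _sign_pm1(self.w).reshape(self.w.shape[0], -1)
        pre = patches @ wb.T  # (B, P, C_out)
        if train:
            self._cache = (patches, x.shape, (oh, ow))
        return pre.transpose(0, 2, 1).reshape(b, -1, oh, ow)

    def backward(self, dpre: np.ndarray, lr: float) -> np.ndarray:
        patches, in_shape, (oh, ow) = self._cache
        b, c_out = dpre.shape[:2]
        k, c_in = self.k, in_shape[1]
        dflat = dpre.reshape(b, c_out, oh * ow).transpose(0, 2, 1)  # (B, P, C_out)
        dw = np.einsum("bpc,bpn->cn", dflat, patches).reshape(self.w.shape)
        wb = _sign_pm1(self.w).reshape(c_out, -1)
        dcols = dflat @ wb  # (B, P, N)
        dcols = dcols.reshape(b, oh, ow, c_in, k, k)
        dx = np.zeros(in_shape)
        for di in range(k):
            for dj in range(k):
                dx[:, :, di : di + oh, dj : dj + ow] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        # STE through sign(w): gradient passes unchanged; clip latent after step
        self.w = np.clip(self.opt.step(self.w, dw, lr), -1.0, 1.0)
        return dx


class _BinFC:
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator, with_bn: bool):
        limit = np.sqrt(6.0 / (f_in + f_out))
        self.w = rng.uniform(-limit, limit, size=(f_out, f_in))
        self.opt = _Adam(self.w.shape)
        self.bn = _BatchNorm(f_out) if with_bn else None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._cache = x
        return x @ _sign_pm1(self.w).T

    def backward(self, dpre: np.ndarray, lr: float) -> np.ndarray:
        x = self._cache
        dw = dpre.T @ x
        dx = dpre @ _sign_pm1(self.w)
        self.w = np.clip(self.opt.step(self.w, dw, lr), -1.0, 1.0)
        return dx


class _FloatBCNN:
    """The latent-weight network. Train-mode forward/backward implement the
    STE recipe; eval-mode forward is the pre-fold float reference (running
    batch-norm statistics, sign activations)."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        self.convs: List[_BinConv] = []
        c_in = spec.input_shape[0]
        for i, c_out in enumerate(spec.conv_channels):
            self.convs.append(_BinConv(c_in, c_out, spec.kernel(i), rng))
            c_in = c_out
        self.fcs: List[_BinFC] = []
        f_in = spec.flat_features()
        for j, f_out in enumerate(spec.fc_sizes):
            self.fcs.append(_BinFC(f_in, f_out, rng, with_bn=j < len(spec.fc_sizes) - 1))
            f_in = f_out

    # -- shared blocks ------------------------------------------------------
    def _pool_forward(self, a: np.ndarray, train: bool):
        b, c, h, w = a.shape
        oh, ow = h // 2, w // 2
        win = a[:, :, : oh * 2, : ow * 2].reshape(b, c, oh, 2, ow, 2)
        win = win.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, oh, ow, 4)
        out = win.max(axis=-1)
        cache = None
        if train:
            onehot = np.zeros_like(win)
            idx = win.argmax(axis=-1)
            np.put_along_axis(onehot, idx[..., None], 1.0, axis=-1)
            cache = (onehot, (b, c, h, w))
        return out, cache

    def _pool_backward(self, dout: np.ndarray, cache):
        onehot, (b, c, h, w) = cache
        oh, ow = h // 2, w // 2
        dwin = onehot * dout[..., None]
        dwin = dwin.reshape(b, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((b, c, h, w))
        dx[:, :, : oh * 2, : ow * 2] = dwin.reshape(b, c, oh * 2, ow * 2)
        return dx

    # -- training pass ------------------------------------------------------
    def train_step(self, xb: np.ndarray, yb: np.ndarray, lr: float) -> float:
        caches = []
        a = xb
        for conv in self.convs:
            pre = conv.forward(a, train=True)
            y = conv.bn.forward(pre, train=True)
            act = _sign_pm1(y)
            pooled, pc = self._pool_forward(act, train=True)
            caches.append((y, pc))
            a = pooled
        b = a.shape[0]
        a = a.reshape(b, -1)
        fc_caches = []
        for fc in self.fcs[:-1]:
            pre = fc.forward(a, train=True)
            y = fc.bn.forward(pre, train=True)
            fc_caches.append(y)
            a = _sign_pm1(y)
        scores = self.fcs[-1].forward(a, train=True)

        # softmax cross-entropy on temperature-scaled logits: raw scores are
        # integers in [-N, N] (N = final fan-in) and would saturate the
        # softmax; dividing by sqrt(N) keeps gradients alive without
        # changing the argmax the deployed model computes
        temp = np.sqrt(self.fcs[-1].w.shape[1])
        z = scores / temp
        z = z - z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        loss = float(-np.log(p[np.arange(b), yb] + 1e-12).mean())
        dscores = p.copy()
        dscores[np.arange(b), yb] -= 1.0
        dscores /= b * temp

        da = self.fcs[-1].backward(dscores, lr)
        for fc, y in zip(reversed(self.fcs[:-1]), reversed(fc_caches)):
            dy = da * (np.abs(y) <= 1.0)  # STE through sign activation
            dpre = fc.bn.backward(dy, lr)
            da = fc.backward(dpre, lr)
        da = da.reshape(a.shape[0], *self._pooled_shape())
        for conv, (y, pc) in zip(reversed(self.convs), reversed(caches)):
            dact = self._pool_backward(da, pc)
            dy = dact * (np.abs(y) <= 1.0)
            dpre = conv.bn.backward(dy, lr)
            da = conv.backward(dpre, lr)
        return loss

    def _pooled_shape(self):
        side = self.spec.spatial_trace()[-1]
        return (self.spec.conv_channels[-1], side, side)

    # -- eval pass (pre-fold float reference) -------------------------------
    def forward_eval(self, xb: np.ndarray) -> np.ndarray:
        a = xb
        for conv in self.convs:
            pre = conv.forward(a, train=False)
            y = conv.bn.forward(pre, train=False)
            a, _ = self._pool_forward(_sign_pm1(y), train=False)
        a = a.reshape(a.shape[0], -1)
        for fc in self.fcs[:-1]:
            y = fc.bn.forward(fc.forward(a, train=False), train=False)
            a = _sign_pm1(y)
        return self.fcs[-1].forward(a, train=False)

    def predict(self, bits: np.ndarray) -> np.ndarray:
        xb = np.where(np.asarray(bits, dtype=np.float64) > 0, 1.0, -1.0)
        if xb.ndim == 3:
            xb = xb[:, None]
        scores = self.forward_eval(xb)
        return (scores[:, FALL] > scores[:, NON_FALL]).astype(np.int64)

    # -- folding ------------------------------------------------------------
    def fold(self, meta: Optional[dict] = None) -> BCNNModel:
        spec = self.spec
        fans = spec.layer_fan_ins()
        weights, bn_pairs = [], []
        layers: List = list(self.convs) + list(self.fcs)
        for i, layer in enumerate(layers):
            weights.append((layer.w >= 0).astype(np.uint8))
            bn = layer.bn
            if bn is None:
                continue
            gs = np.empty(len(bn.gamma), dtype=np.int64)
            thr = np.empty(len(bn.gamma), dtype=np.int64)
            for c in range(len(bn.gamma)):
                t_real = bn.running_mean[c] - (bn.beta[c] / bn.gamma[c]) * np.sqrt(
                    bn.running_var[c] + BN_EPS
                )
                gs[c], thr[c] = popcount_threshold_from_real(
                    t_real, fans[i], 1 if bn.gamma[c] > 0 else -1
                )
            bn_pairs.append((gs, thr))
        model = BCNNModel(spec=spec, weights=weights, bn=bn_pairs, trained_meta=meta or {})
        model.validate_counts()
        return model


@dataclass
class TrainResult:
    model: BCNNModel
    float_net: _FloatBCNN
    train_idx: np.ndarray
    test_idx: np.ndarray
    losses: List[float] = field(default_factory=list)


@dataclass
class EvalResult:
    fold_accuracies: np.ndarray
    mean: float
    sd: float


def predict_batch(model: BCNNModel, bits: np.ndarray) -> np.ndarray:
    """Folded integer-model predictions for a batch of spectrogram bit maps."""
    return np.array([infer(model, b)[0] for b in np.asarray(bits, dtype=np.uint8)])


def _fit(
    x: np.ndarray, y: np.ndarray, spec: NetworkSpec, cfg: TrainConfig, rng: np.random.Generator
) -> tuple[_FloatBCNN, List[float]]:
    net = _FloatBCNN(spec, rng)
    xb_all = np.where(x > 0, 1.0, -1.0).astype(np.float64)
    if xb_all.ndim == 3:
        xb_all = xb_all[:, None]
    n = len(y)
    losses = []
    for epoch in range(cfg.epochs):
        lr = cfg.lr_at(epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            if len(sel) < 2:
                continue  # batch norm needs more than one sample
            epoch_loss += net.train_step(xb_all[sel], y[sel], lr) * len(sel)
        losses.append(epoch_loss / n)
    return net, losses


def train_detailed(
    dataset: SpectrogramDataset, spec: NetworkSpec, cfg: TrainConfig
) -> TrainResult:
    """Shuffle, split 80/20, run the STE recipe, fold, and report both the
    folded integer model and the pre-fold float reference."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    classes = np.unique(dataset.y)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(dataset))
    n_test = int(round(cfg.test_fraction * len(dataset)))
    test_idx, train_idx = order[:n_test], order[n_test:]
    if len(np.unique(dataset.y[train_idx])) < 2:
        raise ValueError("training split became single-class; provide more data")

    net, losses = _fit(dataset.x[train_idx], dataset.y[train_idx], spec, cfg, rng)

    meta = {
        "seed": cfg.seed,
        "epochs": cfg.epochs,
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
        "final_loss": losses[-1] if losses else None,
    }
    model = net.fold(meta)
    preds_train = predict_batch(model, dataset.x[train_idx])
    meta["train_accuracy"] = float((preds_train == dataset.y[train_idx]).mean())
    if n_test:
        preds = predict_batch(model, dataset.x[test_idx])
        meta["test_accuracy"] = float((preds == dataset.y[test_idx]).mean())
    model.trained_meta = meta
    return TrainResult(model=model, float_net=net, train_idx=train_idx, test_idx=test_idx, losses=losses)


def train(dataset: SpectrogramDataset, spec: NetworkSpec, cfg: TrainConfig) -> BCNNModel:
    """STE training entry point; returns the folded deployable model."""
    return train_detailed(dataset, spec, cfg).model


def evaluate_kfold(
    dataset: SpectrogramDataset,
    spec: NetworkSpec,
    cfg: TrainConfig,
    k: int = 5,
    protocol: str = "kfold",
) -> EvalResult:
    """Stratified k-fold (or leave-one-subject-out) evaluation: trains one
    model per fold and reports per-fold accuracy, mean and sd."""
    from sklearn.model_selection import LeaveOneGroupOut, StratifiedKFold

    if len(dataset) < k:
        raise ValueError("dataset smaller than the number of folds")
    if protocol == "kfold":
        if k < 2:
            raise ValueError("k must be >= 2")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
        splits = splitter.split(dataset.x, dataset.y)
    elif protocol == "loso":
        if dataset.subject_ids is None:
            raise ValueError("LOSO evaluation requires subject ids")
        splits = LeaveOneGroupOut().split(dataset.x, dataset.y, groups=dataset.subject_ids)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    rng = np.random.default_rng(cfg.seed)
    accs = []
    for train_ix, test_ix in splits:
        if len(np.unique(dataset.y[train_ix])) < 2:
            raise ValueError("fold training split is single-class")
        net, _ = _fit(dataset.x[train_ix], dataset.y[train_ix], spec, cfg, rng)
        model = net.fold()
        preds = predict_batch(model, dataset.x[test_ix])
        accs.append(float((preds == dataset.y[test_ix]).mean()))
    accs = np.array(accs)
    return EvalResult(fold_accuracies=accs, mean=float(accs.mean()), sd=float(accs.std(ddof=0)))
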