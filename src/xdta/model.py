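"""Two-branch 1D-CNN binding-affinity regressor.

One-hot protein and SMILES inputs run through parallel stacks of 1D
convolutions (ReLU, stride 1, length-preserving zero padding), each branch
ends in global max pooling, the pooled vectors are concatenated and fed to
a fully-connected stack (ReLU, dropout between dense layers) closing in a
single linear output neuron that predicts pKd.  Training minimizes mean
squared error with Adam, monitors validation RMSE every epoch, stops after
``patience`` epochs without improvement and restores the best checkpoint.

The network is implemented directly on NumPy arrays with hand-written
backpropagation.  Besides weight gradients this exposes the exact gradient
of the prediction with respect to the last convolutional feature maps of
either branch, which is what gradient-weighted regression activation
mapping consumes.  Same-padding keeps one feature-map position per input
position, so localization maps align 1:1 with residues/characters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = ["NetworkSpec", "AffinityCNN", "train", "TrainResult"]

DTYPE = np.float32


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture + optimizer hyperparameters.

    ``prot_conv``/``smiles_conv`` are lists of (num_filters, filter_length)
    per convolutional layer; ``dense`` the hidden-layer widths of the
    feed-forward head (the single-output layer is implicit).
    """

    prot_conv: tuple[tuple[int, int], ...] = ((64, 5), (96, 5), (128, 5))
    smiles_conv: tuple[tuple[int, int], ...] = ((64, 4), (96, 4), (128, 4))
    dense: tuple[int, ...] = (1024, 1024, 512)
    dropout_rate: float = 0.1
    learning_rate: float = 1e-4

    def __post_init__(self) -> None:
        if not self.prot_conv or not self.smiles_conv:
            raise ValueError("each branch needs at least one conv layer")
        if not self.dense:
            raise ValueError("need at least one dense layer")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0,1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @staticmethod
    def from_dict(d: dict) -> "NetworkSpec":
        return NetworkSpec(
            prot_conv=tuple(tuple(x) for x in d["prot_conv"]),
            smiles_conv=tuple(tuple(x) for x in d["smiles_conv"]),
            dense=tuple(d["dense"]),
            dropout_rate=d["dropout_rate"],
            learning_rate=d["learning_rate"],
        )


def _same_pad(k: int) -> tuple[int, int]:
    # TF 'same' convention: left pad floor((k-1)/2), right pad ceil((k-1)/2)
    return (k - 1) // 2, k - 1 - (k - 1) // 2


def _conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """x: (N,L,Cin); w: (k,Cin,Cout); b: (Cout,) -> (out, cache)."""
    n, length, cin = x.shape
    k, _, cout = w.shape
    lp, rp = _same_pad(k)
    xp = np.zeros((n, length + lp + rp, cin), dtype=x.dtype)
    xp[:, lp : lp + length] = x
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (N,L,Cin,k)
    cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(n * length, k * cin)
    out = (cols @ w.reshape(k * cin, cout)).reshape(n, length, cout) + b
    return out, (cols, x.shape, k, lp)


def _conv1d_backward(dout: np.ndarray, w: np.ndarray, cache):
    cols, xshape, k, lp = cache
    n, length, cin = xshape
    cout = w.shape[2]
    dflat = dout.reshape(n * length, cout)
    dw = (cols.T @ dflat).reshape(k, cin, cout)
    db = dflat.sum(axis=0)
    dcols = (dflat @ w.reshape(k * cin, cout).T).reshape(n, length, k, cin)
    rp = k - 1 - lp
    dxp = np.zeros((n, length + lp + rp, cin), dtype=dout.dtype)
    for t in range(k):
        dxp[:, t : t + length] += dcols[:, :, t, :]
    return dxp[:, lp : lp + length], dw, db


class AffinityCNN:
    """The two-branch CNN-FCNN regressor with explicit parameter arrays."""

    def __init__(self, spec: NetworkSpec, prot_len: int, prot_dict_size: int,
                 smiles_len: int, smiles_dict_size: int, seed: int = 0) -> None:
        self.spec = spec
        self.prot_len = prot_len
        self.smiles_len = smiles_len
        self.prot_dict_size = prot_dict_size
        self.smiles_dict_size = smiles_dict_size
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        self._init_params(rng)

    # -- initialization -------------------------------------------------
    def _he(self, rng, shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)

    def _init_params(self, rng) -> None:
        p = self.params
        for branch, convs, cin in (
            ("p", self.spec.prot_conv, self.prot_dict_size),
            ("s", self.spec.smiles_conv, self.smiles_dict_size),
        ):
            for li, (cout, k) in enumerate(convs):
                p[f"{branch}_conv{li}_w"] = self._he(rng, (k, cin, cout), k * cin)
                p[f"{branch}_conv{li}_b"] = np.zeros(cout, dtype=DTYPE)
                cin = cout
        din = self.spec.prot_conv[-1][0] + self.spec.smiles_conv[-1][0]
        for li, width in enumerate(self.spec.dense):
            p[f"dense{li}_w"] = self._he(rng, (din, width), din)
            p[f"dense{li}_b"] = np.zeros(width, dtype=DTYPE)
            din = width
        p["out_w"] = self._he(rng, (din, 1), din)
        p["out_b"] = np.zeros(1, dtype=DTYPE)

    # -- forward --------------------------------------------------------
    def _branch_forward(self, x: np.ndarray, branch: str, cache: dict | None):
        convs = self.spec.prot_conv if branch == "p" else self.spec.smiles_conv
        a = x.astype(DTYPE, copy=False)
        for li in range(len(convs)):
            z, cv_cache = _conv1d_forward(a, self.params[f"{branch}_conv{li}_w"],
                                          self.params[f"{branch}_conv{li}_b"])
            a = np.maximum(z, 0.0)
            if cache is not None:
                cache[f"{branch}_conv{li}"] = (cv_cache, z > 0)
        if cache is not None:
            cache[f"{branch}_lastA"] = a
        return a  # last conv activations, shape (N, L, C_last)

    def _head_forward(self, pooled: np.ndarray, cache: dict | None,
                      train_mode: bool = False, rng=None):
        """pooled: (N, Cp+Cs) -> (N,) prediction."""
        h = pooled
        rate = self.spec.dropout_rate
        for li in range(len(self.spec.dense)):
            z = h @ self.params[f"dense{li}_w"] + self.params[f"dense{li}_b"]
            h_pre = np.maximum(z, 0.0)
            if train_mode and rate > 0.0:
                mask = (rng.random(h_pre.shape) >= rate).astype(DTYPE) / (1.0 - rate)
                h_new = h_pre * mask
            else:
                mask = None
                h_new = h_pre
            if cache is not None:
                cache[f"dense{li}"] = (h, z > 0, mask)
            h = h_new
        y = (h @ self.params["out_w"] + self.params["out_b"]).reshape(-1)
        if cache is not None:
            cache["out_in"] = h
        return y

    def _pool(self, a: np.ndarray, cache: dict | None, branch: str):
        arg = a.argmax(axis=1)  # (N, C): first max position per filter
        pooled = np.take_along_axis(a, arg[:, None, :], axis=1)[:, 0, :]
        if cache is not None:
            cache[f"{branch}_argmax"] = arg
        return pooled

    def forward(self, xp: np.ndarray, xs: np.ndarray, train_mode: bool = False,
                rng=None, cache: dict | None = None) -> np.ndarray:
        ap = self._branch_forward(xp, "p", cache)
        as_ = self._branch_forward(xs, "s", cache)
        pp = self._pool(ap, cache, "p")
        ps = self._pool(as_, cache, "s")
        pooled = np.concatenate([pp, ps], axis=1)
        return self._head_forward(pooled, cache, train_mode=train_mode, rng=rng)

    def predict(self, xp: np.ndarray, xs: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Deterministic predictions (dropout off), batch-order preserving."""
        if xp.shape[0] != xs.shape[0]:
            raise ValueError("protein and SMILES batches differ in size")
        self._check_shapes(xp, xs)
        outs = []
        for lo in range(0, xp.shape[0], batch_size):
            outs.append(self.forward(xp[lo : lo + batch_size], xs[lo : lo + batch_size]))
        return np.concatenate(outs) if outs else np.zeros(0, dtype=DTYPE)

    def _check_shapes(self, xp, xs) -> None:
        if xp.shape[1:] != (self.prot_len, self.prot_dict_size):
            raise ValueError(f"protein input shape {xp.shape[1:]} != "
                             f"({self.prot_len}, {self.prot_dict_size})")
        if xs.shape[1:] != (self.smiles_len, self.smiles_dict_size):
            raise ValueError(f"SMILES input shape {xs.shape[1:]} != "
                             f"({self.smiles_len}, {self.smiles_dict_size})")

    # -- gradients ------------------------------------------------------
    def _head_backward(self, dy: np.ndarray, cache: dict, grads: dict | None):
        """dy: (N,) dLoss/dy -> gradient w.r.t. pooled concat vector."""
        h = cache["out_in"]
        dyc = dy[:, None].astype(DTYPE)
        if grads is not None:
            grads["out_w"] = h.T @ dyc
            grads["out_b"] = dyc.sum(axis=0)
        dh = dyc @ self.params["out_w"].T
        for li in range(len(self.spec.dense) - 1, -1, -1):
            h_in, relu_mask, drop_mask = cache[f"dense{li}"]
            if drop_mask is not None:
                dh = dh * drop_mask
            dz = dh * relu_mask
            if grads is not None:
                grads[f"dense{li}_w"] = h_in.T @ dz
                grads[f"dense{li}_b"] = dz.sum(axis=0)
            dh = dz @ self.params[f"dense{li}_w"].T
        return dh

    def _unpool(self, dpooled: np.ndarray, cache: dict, branch: str, length: int):
        arg = cache[f"{branch}_argmax"]  # (N, C)
        n, c = dpooled.shape
        da = np.zeros((n, length, c), dtype=DTYPE)
        np.put_along_axis(da, arg[:, None, :], dpooled[:, None, :], axis=1)
        return da

    def _branch_backward(self, da: np.ndarray, branch: str, cache: dict,
                         grads: dict | None):
        convs = self.spec.prot_conv if branch == "p" else self.spec.smiles_conv
        for li in range(len(convs) - 1, -1, -1):
            cv_cache, relu_mask = cache[f"{branch}_conv{li}"]
            dz = da * relu_mask
            da, dw, db = _conv1d_backward(dz, self.params[f"{branch}_conv{li}_w"], cv_cache)
            if grads is not None:
                grads[f"{branch}_conv{li}_w"] = dw
                grads[f"{branch}_conv{li}_b"] = db
        return da

    def loss_and_grads(self, xp, xs, y, rng=None, train_mode: bool = True):
        """MSE loss and gradients for one minibatch."""
        cache: dict = {}
        pred = self.forward(xp, xs, train_mode=train_mode, rng=rng, cache=cache)
        n = y.shape[0]
        resid = (pred - y).astype(DTYPE)
        loss = float(np.mean(resid**2))
        dy = (2.0 / n) * resid
        grads: dict[str, np.ndarray] = {}
        dpooled = self._head_backward(dy, cache, grads)
        cp = self.spec.prot_conv[-1][0]
        dap = self._unpool(dpooled[:, :cp], cache, "p", self.prot_len)
        das = self._unpool(dpooled[:, cp:], cache, "s", self.smiles_len)
        self._branch_backward(dap, "p", cache, grads)
        self._branch_backward(das, "s", cache, grads)
        return loss, grads

    def feature_map_gradients(self, xp: np.ndarray, xs: np.ndarray, branch: str):
        """Last-conv activations A and exact dy/dA for one branch.

        Returns (activations, gradients), each (N, L, C_last).  The gradient
        is of the scalar prediction of each sample w.r.t. that sample's own
        feature map (dropout off).
        """
        if branch not in ("protein", "smiles"):
            raise ValueError(f"unknown branch {branch!r}")
        b = "p" if branch == "protein" else "s"
        cache: dict = {}
        self.forward(xp, xs, cache=cache)
        n = xp.shape[0]
        dy = np.ones(n, dtype=DTYPE)  # d(y_i)/d(y_i)
        dpooled = self._head_backward(dy, cache, grads=None)
        cp = self.spec.prot_conv[-1][0]
        if b == "p":
            da = self._unpool(dpooled[:, :cp], cache, "p", self.prot_len)
        else:
            da = self._unpool(dpooled[:, cp:], cache, "s", self.smiles_len)
        return cache[f"{b}_lastA"].copy(), da

    def predict_from_feature_maps(self, ap: np.ndarray, as_: np.ndarray) -> np.ndarray:
        """Prediction from given last-conv activations (pool + dense head only).

        Used by finite-difference checks of ``feature_map_gradients``.
        """
        cache: dict = {}
        pp = self._pool(ap.astype(DTYPE), cache, "p")
        ps = self._pool(as_.astype(DTYPE), cache, "s")
        return self._head_forward(np.concatenate([pp, ps], axis=1), None)

    # -- serialization --------------------------------------------------
    def save(self, prefix) -> None:
        """Write ``<prefix>.npz`` (weights) and ``<prefix>.json`` (sidecar)."""
        np.savez(str(prefix) + ".npz", **self.params)
        sidecar = {
            "spec": asdict(self.spec),
            "prot_len": self.prot_len,
            "smiles_len": self.smiles_len,
            "prot_dict_size": self.prot_dict_size,
            "smiles_dict_size": self.smiles_dict_size,
        }
        with open(str(prefix) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, prefix) -> "AffinityCNN":
        with open(str(prefix) + ".json") as fh:
            sc = json.load(fh)
        net = cls(NetworkSpec.from_dict(sc["spec"]), sc["prot_len"],
                  sc["prot_dict_size"], sc["smiles_len"], sc["smiles_dict_size"])
        with np.load(str(prefix) + ".npz") as data:
            net.params = {k: data[k] for k in data.files}
        return net


@dataclass
class TrainResult:
    net: AffinityCNN
    best_val_rmse: float
    best_epoch: int
    history: list[dict] = field(default_factory=list)


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train(
    net: AffinityCNN,
    train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    max_epochs: int,
    patience: int = 30,
    batch_size: int = 32,
    seed: int = 0,
    verbose: bool = False,
) -> TrainResult:
    """Adam/MSE training with per-epoch validation RMSE early stopping.

    ``train_data``/``val_data`` are (X_protein, X_smiles, y) triples of
    one-hot arrays and pKd labels.  The parameters achieving the best
    validation RMSE are restored before returning.  ``seed`` drives batch
    shuffling and dropout masks, so identical inputs + seed reproduce the
    run exactly.
    """
    xp_tr, xs_tr, y_tr = train_data
    xp_va, xs_va, y_va = val_data
    if y_tr.shape[0] == 0 or y_va.shape[0] == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(seed)
    opt = _Adam(net.params, net.spec.learning_rate)
    best = {k: v.copy() for k, v in net.params.items()}
    best_rmse = float("inf")
    best_epoch = -1
    waited = 0
    history = []
    n = y_tr.shape[0]
    y_tr = y_tr.astype(DTYPE)
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for lo in range(0, n, batch_size):
            sel = order[lo : lo + batch_size]
            loss, grads = net.loss_and_grads(xp_tr[sel], xs_tr[sel], y_tr[sel], rng=rng)
            opt.step(net.params, grads)
            ep_loss += loss * len(sel)
        val_pred = net.predict(xp_va, xs_va)
        val_rmse = float(np.sqrt(np.mean((val_pred - y_va) ** 2)))
        history.append({"epoch": epoch, "train_mse": ep_loss / n, "val_rmse": val_rmse})
        if verbose:
            print(f"epoch {epoch}: train MSE {ep_loss / n:.4f}  val RMSE {val_rmse:.4f}")
        if val_rmse < best_rmse:
            best_rmse = val_rmse
            best_epoch = epoch
            best = {k: v.copy() for k, v in net.params.items()}
            waited = 0
        else:
            waited += 1
            if waited >= max(patience, 1):
                break
    net.params = best
    return TrainResult(net=net, best_val_rmse=best_rmse, best_epoch=best_epoch,
                       history=history)
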