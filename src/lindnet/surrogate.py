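"""1D-convolutional surrogate network: 105 input features -> 13-target row.

Architecture (the fixed reference topology):

    input (105, 1)
    conv1d  90 filters, kernel 3, valid, relu   -> (103, 90)      360 params
    conv1d  70 filters, kernel 3, same,  relu   -> (103, 70)   18,970
    maxpool size 2 (floor)                      -> (51, 70)         0
    flatten                                     -> 3570             0
    dense 512, relu                                          1,828,352
    dense 512, relu                                            262,656
    dense 512, relu                                            262,656
    dense 13, linear                                             6,669
                                               total         2,379,663

Only this valid/same/floor combination reproduces every intermediate
shape and parameter count of that topology, so it is asserted at
construction.

The network is implemented directly on numpy (float32 GEMM via im2col,
explicit backprop, Adam, seeded Glorot-uniform initialisation): no deep
learning framework is required at train or inference time, and a few
thousand Adam steps run in minutes on one CPU core.  Training minimises
mean squared error, shuffles with a seeded generator, and checkpoints the
best-validation weights.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SurrogateSpec",
    "SurrogateCNN",
    "TrainedSurrogate",
    "build_model",
    "train",
]


@dataclass(frozen=True)
class SurrogateSpec:
    """Hyperparameters of the surrogate CNN (defaults: the reference topology)."""

    n_features: int = 105
    n_targets: int = 13
    conv_filters: tuple = (90, 70)
    kernel_size: int = 3
    pool_size: int = 2
    dense_units: tuple = (512, 512, 512)
    learning_rate: float = 1e-3
    batch_size: int = 512
    epochs: int = 900

    # -- shape bookkeeping -------------------------------------------------
    @property
    def conv1_len(self) -> int:  # valid convolution
        return self.n_features - self.kernel_size + 1

    @property
    def pooled_len(self) -> int:  # floor division, second conv is same-padded
        return self.conv1_len // self.pool_size

    @property
    def flat_width(self) -> int:
        return self.pooled_len * self.conv_filters[1]

    def layer_table(self) -> list[tuple[str, tuple, int]]:
        """(layer, output shape, trainable parameters) for every layer."""
        k, (f1, f2) = self.kernel_size, self.conv_filters
        rows = [
            ("conv1d_valid_relu", (self.conv1_len, f1), k * 1 * f1 + f1),
            ("conv1d_same_relu", (self.conv1_len, f2), k * f1 * f2 + f2),
            ("maxpool", (self.pooled_len, f2), 0),
            ("flatten", (self.flat_width,), 0),
        ]
        w = self.flat_width
        for u in self.dense_units:
            rows.append(("dense_relu", (u,), w * u + u))
            w = u
        rows.append(("dense_linear", (self.n_targets,), w * self.n_targets + self.n_targets))
        return rows

    def total_params(self) -> int:
        return sum(p for _, _, p in self.layer_table())


def _glorot(rng, shape, fan_in, fan_out, dtype=np.float32) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class SurrogateCNN:
    """The surrogate network with explicit forward/backward passes."""

    def __init__(
        self,
        spec: SurrogateSpec = SurrogateSpec(),
        seed: int = 0,
        dtype=np.float32,
    ):
        if spec.kernel_size != 3 or spec.pool_size != 2:
            raise NotImplementedError("kernel size 3 and pool size 2 are assumed")
        self.spec = spec
        self.seed = int(seed)
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(self.seed)
        k, (f1, f2) = spec.kernel_size, spec.conv_filters
        p: dict[str, np.ndarray] = {}
        p["Wc1"] = _glorot(rng, (k, f1), k * 1, k * f1, self.dtype)
        p["bc1"] = np.zeros(f1, dtype=self.dtype)
        p["Wc2"] = _glorot(rng, (k * f1, f2), k * f1, k * f2, self.dtype)
        p["bc2"] = np.zeros(f2, dtype=self.dtype)
        w_in = spec.flat_width
        for i, u in enumerate(spec.dense_units, start=1):
            p[f"Wd{i}"] = _glorot(rng, (w_in, u), w_in, u, self.dtype)
            p[f"bd{i}"] = np.zeros(u, dtype=self.dtype)
            w_in = u
        p["Wo"] = _glorot(rng, (w_in, spec.n_targets), w_in, spec.n_targets, self.dtype)
        p["bo"] = np.zeros(spec.n_targets, dtype=self.dtype)
        self.params = p
        self._buf: dict = {}  # reusable per-batch scratch arrays
        self._audit()

    def _scratch(self, key, shape) -> np.ndarray:
        buf = self._buf.get(key)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=self.dtype)
            self._buf[key] = buf
        return buf

    def _bool(self, key, shape) -> np.ndarray:
        buf = self._buf.get(key)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=bool)
            self._buf[key] = buf
        return buf

    # -- construction audit -------------------------------------------------
    def _audit(self) -> None:
        expected = {name: nparams for name, _, nparams in [
            (f"{i}:{n}", s, c) for i, (n, s, c) in enumerate(self.spec.layer_table())
        ]}
        counts = {
            "0:conv1d_valid_relu": self.params["Wc1"].size + self.params["bc1"].size,
            "1:conv1d_same_relu": self.params["Wc2"].size + self.params["bc2"].size,
        }
        for i in range(len(self.spec.dense_units)):
            counts[f"{4 + i}:dense_relu"] = (
                self.params[f"Wd{i+1}"].size + self.params[f"bd{i+1}"].size
            )
        counts[f"{4 + len(self.spec.dense_units)}:dense_linear"] = (
            self.params["Wo"].size + self.params["bo"].size
        )
        for name, got in counts.items():
            if expected.get(name, got) != got:
                raise ValueError(
                    f"layer {name}: {got} parameters, expected {expected[name]}"
                )

    @property
    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())

    # -- forward ------------------------------------------------------------
    def _forward(self, X: np.ndarray, want_cache: bool):
        """X: (B, n_features) in the model dtype. Returns (B, n_targets).

        All large intermediates live in reused scratch buffers (keyed by
        batch size); relu is applied in place and masks for backprop are
        recovered from the activations themselves.
        """
        spec = self.spec
        p = self.params
        k = spec.kernel_size
        L = spec.conv1_len
        B = X.shape[0]
        f1, f2 = spec.conv_filters

        # conv1, valid: im2col (B*L, k) @ (k, f1) as one flat GEMM
        X3 = self._scratch(("X3", B), (B, L, k))
        for i in range(k):
            X3[:, :, i] = X[:, i : i + L]
        a1 = self._scratch(("a1", B), (B, L, f1))
        np.matmul(X3.reshape(B * L, k), p["Wc1"], out=a1.reshape(B * L, f1))
        a1 += p["bc1"]
        np.maximum(a1, 0.0, out=a1)

        # conv2, same: shift-and-copy im2col, zero boundary slices only
        cols = self._scratch(("cols", B), (B, L, k * f1))
        cols[:, 1:, :f1] = a1[:, : L - 1]
        cols[:, 0, :f1] = 0.0
        cols[:, :, f1 : 2 * f1] = a1
        cols[:, : L - 1, 2 * f1 :] = a1[:, 1:]
        cols[:, L - 1, 2 * f1 :] = 0.0
        a2 = self._scratch(("a2", B), (B, L, f2))
        np.matmul(cols.reshape(B * L, k * f1), p["Wc2"], out=a2.reshape(B * L, f2))
        a2 += p["bc2"]
        np.maximum(a2, 0.0, out=a2)

        # maxpool size 2, floor: drop the trailing odd position
        Lp = spec.pooled_len
        lo, hi = a2[:, : 2 * Lp : 2], a2[:, 1 : 2 * Lp : 2]
        first_wins = self._bool(("fw", B), lo.shape)
        np.greater_equal(lo, hi, out=first_wins)
        pooled = self._scratch(("pool", B), lo.shape)
        pooled[...] = hi
        np.copyto(pooled, lo, where=first_wins)
        flat = pooled.reshape(B, spec.flat_width)

        acts = [flat]
        h = flat
        for i in range(1, len(spec.dense_units) + 1):
            u = p[f"Wd{i}"].shape[1]
            z = self._scratch((f"h{i}", B), (B, u))
            np.matmul(h, p[f"Wd{i}"], out=z)
            z += p[f"bd{i}"]
            np.maximum(z, 0.0, out=z)
            acts.append(z)
            h = z
        out = h @ p["Wo"] + p["bo"]

        if want_cache:
            return out, dict(
                X3=X3, a1=a1, cols=cols, a2=a2, first_wins=first_wins, acts=acts
            )
        return out

    def predict(self, X: np.ndarray, batch: int = 4096) -> np.ndarray:
        """Deterministic batched inference; X is (N, n_features)."""
        X = np.ascontiguousarray(X, dtype=self.dtype)
        if X.ndim != 2 or X.shape[1] != self.spec.n_features:
            raise ValueError(
                f"expected input width {self.spec.n_features}, got {X.shape}"
            )
        outs = [self._forward(X[i : i + batch], False) for i in range(0, len(X), batch)]
        return np.concatenate(outs, axis=0)

    # -- backward -----------------------------------------------------------
    def _grad_buffers(self):
        g = self._buf.get("grads")
        if g is None:
            g = {k: np.empty_like(v) for k, v in self.params.items()}
            self._buf["grads"] = g
        return g

    def _backward(self, X, Y):
        """Mean-squared-error loss and parameter gradients for one batch.

        Gradients are written into persistent buffers owned by the model
        (valid until the next call); relu masks are taken from the cached
        activations (a > 0).
        """
        spec = self.spec
        p = self.params
        X = np.ascontiguousarray(X, dtype=self.dtype)
        Y = np.ascontiguousarray(Y, dtype=self.dtype)
        B = X.shape[0]
        out, c = self._forward(X, True)
        diff = out - Y
        loss = float(np.mean(diff * diff))
        g = self._grad_buffers()

        dout = diff
        dout *= self.dtype.type(2.0 / diff.size)
        np.matmul(c["acts"][-1].T, dout, out=g["Wo"])
        dout.sum(axis=0, out=g["bo"])
        dh = dout @ p["Wo"].T
        for i in range(len(spec.dense_units), 0, -1):
            dh *= c["acts"][i] > 0
            np.matmul(c["acts"][i - 1].T, dh, out=g[f"Wd{i}"])
            dh.sum(axis=0, out=g[f"bd{i}"])
            dh = dh @ p[f"Wd{i}"].T

        # through flatten + maxpool (size-2: route gradient to the winner)
        Lp = spec.pooled_len
        f2 = spec.conv_filters[1]
        k, f1 = spec.kernel_size, spec.conv_filters[0]
        L = spec.conv1_len
        dpool = dh.reshape(B, Lp, f2)
        fw = c["first_wins"]
        da2 = self._scratch(("da2", B), (B, L, f2))
        da2[:, 2 * Lp :] = 0.0
        delo, dehi = da2[:, : 2 * Lp : 2], da2[:, 1 : 2 * Lp : 2]
        delo[...] = 0.0
        np.copyto(delo, dpool, where=fw)
        dehi[...] = dpool
        np.copyto(dehi, 0.0, where=fw)

        da2 *= c["a2"] > 0
        dz2_2d = da2.reshape(B * L, f2)
        np.matmul(c["cols"].reshape(B * L, k * f1).T, dz2_2d, out=g["Wc2"])
        dz2_2d.sum(axis=0, out=g["bc2"])

        # col2im for the same-padded conv: sum the three shifted slices
        dcols = self._scratch(("dcols", B), (B, L, k * f1))
        np.matmul(dz2_2d, p["Wc2"].T, out=dcols.reshape(B * L, k * f1))
        da1 = self._scratch(("da1", B), (B, L, f1))
        da1[...] = dcols[:, :, f1 : 2 * f1]
        da1[:, : L - 1] += dcols[:, 1:, :f1]
        da1[:, 1:] += dcols[:, : L - 1, 2 * f1 :]

        da1 *= c["a1"] > 0
        np.matmul(c["X3"].reshape(B * L, k).T, da1.reshape(B * L, f1), out=g["Wc1"])
        da1.reshape(B * L, f1).sum(axis=0, out=g["bc1"])
        return loss, g

    def evaluate_mse(self, X, Y, batch: int = 4096) -> float:
        pred = self.predict(X, batch=batch)
        d = pred - np.asarray(Y, dtype=np.float32)
        return float(np.mean(d * d))


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, gr in grads.items():
            m = self.m[k]
            v = self.v[k]
            m += (1 - self.b1) * (gr - m)
            v += (1 - self.b2) * (gr * gr - v)
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedSurrogate:
    """A trained network plus the metadata needed to use it portably.

    ``feature_meta`` carries the normalisation constants and feature order
    copied from the dataset so predictions are reproducible from raw
    parameters; ``history`` logs per-epoch train/validation MSE.
    """

    model: SurrogateCNN
    feature_meta: dict = field(default_factory=dict)
    history: dict = field(default_factory=lambda: {"train_mse": [], "val_mse": []})
    seed: int = 0

    def predict_rows(self, X: np.ndarray) -> np.ndarray:
        """Batched, deterministic inference on (N, 105) feature records."""
        return self.model.predict(X)

    # -- persistence ---------------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **self.model.params)
        side = {
            "spec": asdict(self.model.spec),
            "seed": self.seed,
            "feature_meta": self.feature_meta,
            "history": self.history,
            "n_params": self.model.n_params,
        }
        (d / "model.json").write_text(json.dumps(side, indent=1))

    @classmethod
    def load(cls, directory) -> "TrainedSurrogate":
        d = Path(directory)
        side = json.loads((d / "model.json").read_text())
        spec_d = side["spec"]
        for key in ("conv_filters", "dense_units"):
            spec_d[key] = tuple(spec_d[key])
        spec = SurrogateSpec(**spec_d)
        model = SurrogateCNN(spec, seed=side["seed"])
        with np.load(d / "weights.npz") as zz:
            for k in model.params:
                model.params[k] = zz[k].astype(np.float32)
        if model.n_params != side["n_params"]:
            raise ValueError("loaded weights do not match the stored spec")
        return cls(
            model=model,
            feature_meta=side["feature_meta"],
            history=side["history"],
            seed=side["seed"],
        )


def build_model(spec: SurrogateSpec = SurrogateSpec(), seed: int = 0) -> SurrogateCNN:
    """Construct the network; construction fails if any layer's parameter
    count disagrees with the spec's layer table."""
    return SurrogateCNN(spec, seed=seed)


def train(
    model: SurrogateCNN,
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    Y_val: np.ndarray | None = None,
    *,
    epochs: int | None = None,
    batch_size: int | None = None,
    learning_rate: float | None = None,
    seed: int = 0,
    feature_meta: dict | None = None,
    verbose: bool = False,
) -> TrainedSurrogate:
    """Minimise MSE with Adam; fully seeded; checkpoints best-validation weights.

    Raises on a non-finite loss with the offending epoch/lr/batch in the
    message.  Returns a TrainedSurrogate holding the checkpointed weights
    (falling back to final weights when no validation set is given).
    """
    spec = model.spec
    epochs = spec.epochs if epochs is None else int(epochs)
    batch_size = spec.batch_size if batch_size is None else int(batch_size)
    lr = spec.learning_rate if learning_rate is None else float(learning_rate)

    X_train = np.ascontiguousarray(X_train, dtype=np.float32)
    Y_train = np.ascontiguousarray(Y_train, dtype=np.float32)
    has_val = X_val is not None and len(X_val) > 0
    if has_val:
        X_val = np.ascontiguousarray(X_val, dtype=np.float32)
        Y_val = np.ascontiguousarray(Y_val, dtype=np.float32)

    rng = np.random.default_rng(seed)
    opt = _Adam(model.params, lr=lr)
    hist = {"train_mse": [], "val_mse": []}
    best_val = np.inf
    best_weights = None
    n = len(X_train)
    for epoch in range(epochs):
        order = rng.permutation(n)
        running = 0.0
        seen = 0
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            loss, grads = model._backward(X_train[idx], Y_train[idx])
            if not np.isfinite(loss):
                raise ArithmeticError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={lr}, batch={batch_size})"
                )
            opt.step(model.params, grads)
            running += loss * len(idx)
            seen += len(idx)
        hist["train_mse"].append(running / seen)
        if has_val:
            vm = model.evaluate_mse(X_val, Y_val)
            hist["val_mse"].append(vm)
            if vm < best_val:
                best_val = vm
                best_weights = {k: v.copy() for k, v in model.params.items()}
        if verbose and (epoch % 10 == 0 or epoch == epochs - 1):
            msg = f"epoch {epoch:4d}  train {hist['train_mse'][-1]:.3e}"
            if has_val:
                msg += f"  val {hist['val_mse'][-1]:.3e}"
            print(msg, flush=True)
    if best_weights is not None:
        model.params = best_weights
    return TrainedSurrogate(
        model=model, feature_meta=feature_meta or {}, history=hist, seed=seed
    )
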