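"""Multi-label feed-forward classifier over fused drug-pair embeddings.

Architecture: input -> [linear -> (batchnorm after the first hidden layer
only) -> leaky-ReLU -> dropout] per hidden layer -> linear -> sigmoid, one
output unit per side effect. Trained with binary focal cross-entropy to
down-weight the many easy negatives of the imbalanced multi-label target,
an Adam optimizer whose base rate follows an exponential decay schedule
(lr_t = lr * decay^t per epoch), and early stopping on validation loss with
the best-validation checkpoint restored.

Implemented directly on NumPy with hand-written gradients; the forward pass
in evaluation mode is deterministic (dropout off, batchnorm running stats).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class MLPConfig:
    hidden_sizes: list[int] = field(default_factory=lambda: [512, 1024, 2048])
    leaky_slope: float = 0.1
    dropout: float = 0.2
    batchnorm_after_first: bool = True
    output_dim: int = 964
    lr: float = 0.005
    lr_decay: float = 0.96
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")
        for name in ("dropout", "lr", "lr_decay"):
            v = getattr(self, name)
            if not 0 < v < 1 and name != "dropout":
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if not 0 <= self.dropout < 1:
            raise ValueError(f"dropout must lie in [0, 1); got {self.dropout}")


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class RowSplit:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    folds: list[np.ndarray]  # partition of train+val for cross-validation


def split_rows(table_size: int, spec: SplitSpec) -> RowSplit:
    """Disjoint, exhaustive train/val/test row partition plus CV folds.

    Folds tile the shuffled train+val indices only; test rows never appear
    in any fold. Deterministic given the spec's seed.
    """
    if table_size < spec.n_folds:
        raise ValueError(f"need at least n_folds={spec.n_folds} rows, got {table_size}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(table_size)
    n_train = int(table_size * spec.fractions[0])
    n_val = int(table_size * spec.fractions[1])
    train, val = perm[:n_train], perm[n_train : n_train + n_val]
    test = perm[n_train + n_val :]
    trainval = perm[: n_train + n_val]
    folds = [np.sort(trainval[i :: spec.n_folds]) for i in range(spec.n_folds)]
    return RowSplit(np.sort(train), np.sort(val), np.sort(test), folds)


def focal_bce_loss(
    pred: np.ndarray,
    target: np.ndarray,
    gamma: float = 2.0,
    alpha: float = 0.25,
) -> float:
    """Binary focal cross-entropy, mean over all elements.

    Per element: -alpha_t * (1 - p_t)^gamma * log(p_t), with p_t = p for
    target 1 and 1-p otherwise, alpha_t = alpha for target 1 and 1-alpha
    otherwise. gamma = 0, alpha = 0.5 reduces to half the ordinary BCE.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = np.clip(pred, _EPS, 1 - _EPS)
    p_t = np.where(target == 1, p, 1 - p)
    alpha_t = np.where(target == 1, alpha, 1 - alpha)
    return float(np.mean(-alpha_t * (1 - p_t) ** gamma * np.log(p_t)))


def _focal_grad_wrt_logit(p: np.ndarray, target: np.ndarray, gamma: float, alpha: float) -> np.ndarray:
    """d(focal loss element)/d(logit), before the mean reduction."""
    p = np.clip(p, _EPS, 1 - _EPS)
    p_t = np.where(target == 1, p, 1 - p)
    alpha_t = np.where(target == 1, alpha, 1 - alpha)
    # dL/dp_t = alpha_t * [gamma (1-p_t)^(g-1) log p_t - (1-p_t)^g / p_t]
    one_minus = 1 - p_t
    dL_dpt = alpha_t * (
        (gamma * one_minus ** (gamma - 1) * np.log(p_t) if gamma != 0 else 0.0)
        - one_minus**gamma / p_t
    )
    # dp_t/dz = +p(1-p) for target 1, -p(1-p) for target 0
    sign = np.where(target == 1, 1.0, -1.0)
    return dL_dpt * sign * p * (1 - p)


def toy_config(output_dim: int, seed: int = 7) -> MLPConfig:
    """Training preset for small planted fixtures (~10^2 rows, ~10 inputs).

    The full-scale 512/1024/2048 stack is sized for tens of thousands of
    rows and hundreds of labels; at fixture scale two 64-unit layers and a
    small batch reach the same planted structure in seconds.
    """
    return MLPConfig(
        hidden_sizes=[64, 64], output_dim=output_dim, batch_size=64, seed=seed
    )


class MLPClassifier:
    """The multi-label perceptron, exposing forward/predict and training state."""

    def __init__(self, config: MLPConfig, input_dim: int):
        if input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        self.config = config
        self.input_dim = input_dim
        rng = np.random.default_rng(config.seed)
        dims = [input_dim, *config.hidden_sizes, config.output_dim]
        self.params: dict[str, np.ndarray] = {}
        for i in range(len(dims) - 1):
            fan_in = dims[i]
            self.params[f"W{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in), (dims[i], dims[i + 1]))
            self.params[f"b{i}"] = np.zeros(dims[i + 1])
        self.n_layers = len(dims) - 1
        if config.batchnorm_after_first:
            w = config.hidden_sizes[0]
            self.params["bn_gamma"] = np.ones(w)
            self.params["bn_beta"] = np.zeros(w)
            self.bn_mean = np.zeros(w)
            self.bn_var = np.ones(w)
            self.bn_momentum = 0.9

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward -----------------------------------------------------------

    def forward(
        self, X: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, dict]:
        """Probabilities (n, output_dim) and a cache for backprop."""
        if X.shape[1] != self.input_dim:
            raise ValueError(f"expected input width {self.input_dim}, got {X.shape[1]}")
        cfg = self.config
        cache: dict = {"inputs": [], "pre": [], "post": [], "masks": []}
        h = np.asarray(X, dtype=np.float64)
        for i in range(self.n_layers - 1):
            cache["inputs"].append(h)
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if i == 0 and cfg.batchnorm_after_first:
                z, bn_cache = self._bn_forward(z, training)
                cache["bn"] = bn_cache
            cache["pre"].append(z)
            h = np.where(z > 0, z, cfg.leaky_slope * z)
            if training and cfg.dropout > 0:
                mask = (rng.random(h.shape) >= cfg.dropout) / (1 - cfg.dropout)
                h = h * mask
                cache["masks"].append(mask)
            else:
                cache["masks"].append(None)
            cache["post"].append(h)
        cache["inputs"].append(h)
        i = self.n_layers - 1
        logits = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
        cache["logits"] = logits
        probs = 1.0 / (1.0 + np.exp(-logits))
        return probs, cache

    def _bn_forward(self, z: np.ndarray, training: bool) -> tuple[np.ndarray, dict]:
        eps = 1e-5
        if training:
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            self.bn_mean = self.bn_momentum * self.bn_mean + (1 - self.bn_momentum) * mu
            self.bn_var = self.bn_momentum * self.bn_var + (1 - self.bn_momentum) * var
        else:
            mu, var = self.bn_mean, self.bn_var
        inv_std = 1.0 / np.sqrt(var + eps)
        zhat = (z - mu) * inv_std
        out = self.params["bn_gamma"] * zhat + self.params["bn_beta"]
        return out, {"zhat": zhat, "inv_std": inv_std, "training": training}

    # -- backward ----------------------------------------------------------

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        i = self.n_layers - 1
        h = cache["inputs"][i]
        grads[f"W{i}"] = h.T @ dlogits
        grads[f"b{i}"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params[f"W{i}"].T
        for i in range(self.n_layers - 2, -1, -1):
            if cache["masks"][i] is not None:
                dh = dh * cache["masks"][i]
            z = cache["pre"][i]
            dz = dh * np.where(z > 0, 1.0, cfg.leaky_slope)
            if i == 0 and cfg.batchnorm_after_first:
                dz = self._bn_backward(dz, cache["bn"], grads)
            x = cache["inputs"][i]
            grads[f"W{i}"] = x.T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"W{i}"].T
        return grads

    def _bn_backward(self, dout: np.ndarray, bn_cache: dict, grads: dict) -> np.ndarray:
        zhat, inv_std = bn_cache["zhat"], bn_cache["inv_std"]
        n = dout.shape[0]
        grads["bn_gamma"] = (dout * zhat).sum(axis=0)
        grads["bn_beta"] = dout.sum(axis=0)
        dzhat = dout * self.params["bn_gamma"]
        if not bn_cache["training"]:
            return dzhat * inv_std
        return (
            inv_std
            / n
            * (n * dzhat - dzhat.sum(axis=0) - zhat * (dzhat * zhat).sum(axis=0))
        )

    def state_dict(self) -> dict:
        state = {k: v.copy() for k, v in self.params.items()}
        if self.config.batchnorm_after_first:
            state["_bn_mean"] = self.bn_mean.copy()
            state["_bn_var"] = self.bn_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()
        if self.config.batchnorm_after_first:
            self.bn_mean = state["_bn_mean"].copy()
            self.bn_var = state["_bn_var"].copy()


def build_mlp(config: MLPConfig, input_dim: int) -> MLPClassifier:
    return MLPClassifier(config, input_dim)


class AdamState:
    """Minimal Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def train_mlp(
    model: MLPClassifier,
    pair_matrix: np.ndarray,
    targets: np.ndarray,
    split: RowSplit,
    config: MLPConfig | None = None,
) -> tuple[MLPClassifier, list[dict]]:
    """Mini-batch training with lr decay and early stopping on val loss.

    Returns the model restored to its best-validation checkpoint and the
    per-epoch log (train/val loss, val macro-AUROC, learning rate).
    """
    from sklearn.metrics import roc_auc_score

    cfg = config or model.config
    X, Y = np.asarray(pair_matrix, np.float64), np.asarray(targets, np.float64)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("feature rows must align with target rows")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = AdamState(model.params)
    Xtr, Ytr = X[split.train], Y[split.train]
    Xval, Yval = X[split.val], Y[split.val]

    log: list[dict] = []
    best_val = np.inf
    best_state = model.state_dict()
    wait = 0
    for epoch in range(cfg.max_epochs):
        lr = cfg.lr * cfg.lr_decay**epoch
        order = rng.permutation(len(Xtr))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(Xtr), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs, cache = model.forward(Xtr[idx], training=True, rng=rng)
            loss = focal_bce_loss(probs, Ytr[idx], cfg.focal_gamma, cfg.focal_alpha)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; check inputs/lr"
                )
            dlogits = _focal_grad_wrt_logit(probs, Ytr[idx], cfg.focal_gamma, cfg.focal_alpha)
            grads = model.backward(dlogits / dlogits.size, cache)
            opt.step(model.params, grads, lr)
            epoch_loss += loss
            n_batches += 1
        val_probs, _ = model.forward(Xval, training=False)
        val_loss = focal_bce_loss(val_probs, Yval, cfg.focal_gamma, cfg.focal_alpha)
        aucs = [
            roc_auc_score(Yval[:, j], val_probs[:, j])
            for j in range(Y.shape[1])
            if 0 < Yval[:, j].sum() < len(Yval)
        ]
        entry = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_loss": float(val_loss),
            "val_macro_auroc": float(np.mean(aucs)) if aucs else float("nan"),
        }
        log.append(entry)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = model.state_dict()
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                logger.info("early stopping at epoch %d (best val loss %.5f)", epoch, best_val)
                break
    model.load_state_dict(best_state)
    return model, log


def predict_mlp(model: MLPClassifier, pair_matrix: np.ndarray) -> np.ndarray:
    """Per-side-effect probabilities, deterministic (evaluation mode)."""
    X = np.asarray(pair_matrix, dtype=np.float64)
    if X.shape[0] == 0:
        return np.empty((0, model.config.output_dim))
    probs, _ = model.forward(X, training=False)
    return probs
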