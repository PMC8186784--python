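"""Inception-style convolutional classifier of presented vs non-presented
peptides, one model per allele.

The network maps the 11×21 one-hot matrix to a 2-node softmax: three
parallel 2-D convolution branches (8 kernels each, Leaky ReLU α=0.2) whose
kernels span all 21 residue columns and 2/3/4 rows respectively (a
multi-scale reading of 2-, 3- and 4-residue windows; stride 1, no
padding), flattened and concatenated into a 100-unit dense layer with
dropout, then a 2-node softmax. Training uses Adam with standard
parameters, cross-entropy loss, and early stopping on validation loss.

Implemented directly in NumPy: the model is small (11×21 inputs, a few
tens of thousands of parameters), which keeps training CPU-friendly and
bit-reproducible under a seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from appm.codec import (
    FULL_ALPHABET,
    MAX_LENGTH,
    N_COLUMNS,
    Peptide,
    encode_batch,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters of the classifier.

    Defaults: three branches with kernel heights 2/3/4, eight kernels per
    branch, a 100-unit dense layer, Leaky ReLU α=0.2, dropout 0.4, Adam at
    its canonical settings, batch 128, up to 200 epochs with patience 10.
    """

    branch_kernel_heights: Tuple[int, int, int] = (2, 3, 4)
    kernels_per_branch: int = 8
    dense_units: int = 100
    leaky_relu_alpha: float = 0.2
    dropout_rate: float = 0.4
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 128
    max_epochs: int = 200
    early_stopping_patience: int = 10
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.branch_kernel_heights) != 3:
            raise ConfigError(
                f"exactly three convolutional branches required, "
                f"got heights {self.branch_kernel_heights}"
            )
        for h in self.branch_kernel_heights:
            if not 1 <= h <= MAX_LENGTH:
                raise ConfigError(f"kernel height {h} outside [1, {MAX_LENGTH}]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.kernels_per_branch < 1 or self.dense_units < 1:
            raise ConfigError("kernels_per_branch and dense_units must be >= 1")


@dataclass(frozen=True)
class PredictionResult:
    """Per-peptide output: probability of presentation and the binary call."""

    peptide: Peptide
    score: float
    call: int


def _leaky(x: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(x > 0, x, alpha * x)


def _leaky_grad(x: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(x > 0, 1.0, alpha)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _patches(x: np.ndarray, h: int) -> np.ndarray:
    """im2col over rows: (N, 11, 21) -> (N, 12-h, h*21). Kernels span the full
    residue axis, so the convolution reduces to a sliding matmul."""
    windows = np.lib.stride_tricks.sliding_window_view(x, (h, N_COLUMNS), axis=(1, 2))
    n, t = windows.shape[0], windows.shape[1]
    return windows.reshape(n, t, h * N_COLUMNS)


class PresentationCNN:
    """Trainable presentation classifier. See the module docstring for the
    architecture; one instance is trained per HLA allele."""

    def __init__(self, config: Optional[ModelConfig] = None, allele: Optional[str] = None):
        self.config = config or ModelConfig()
        self.allele = allele
        self.history: Dict[str, List[float]] = {}
        self._init_params(np.random.default_rng(self.config.seed))

    # ------------------------------------------------------------------ setup

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        k = cfg.kernels_per_branch
        self.params: Dict[str, np.ndarray] = {}
        for b, h in enumerate(cfg.branch_kernel_heights):
            fan_in = h * N_COLUMNS
            self.params[f"Wc{b}"] = rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, k))
            self.params[f"bc{b}"] = np.zeros(k)
        n_feat = sum((MAX_LENGTH - h + 1) * k for h in cfg.branch_kernel_heights)
        self.params["W1"] = rng.normal(0, np.sqrt(2.0 / n_feat), (n_feat, cfg.dense_units))
        self.params["b1"] = np.zeros(cfg.dense_units)
        self.params["W2"] = rng.normal(0, np.sqrt(2.0 / cfg.dense_units), (cfg.dense_units, 2))
        self.params["b2"] = np.zeros(2)
        self._n_features = n_feat

    @property
    def parameter_count(self) -> int:
        """Total number of trainable parameters."""
        return int(sum(p.size for p in self.params.values()))

    # ---------------------------------------------------------------- forward

    def _forward(
        self, x: np.ndarray, dropout_rng: Optional[np.random.Generator] = None
    ) -> Tuple[np.ndarray, dict]:
        """Forward pass; dropout is active only when a dropout RNG is given."""
        cfg = self.config
        cache: dict = {"x": x, "branches": []}
        feats = []
        for b, h in enumerate(cfg.branch_kernel_heights):
            p = _patches(x, h)
            z = p @ self.params[f"Wc{b}"] + self.params[f"bc{b}"]
            a = _leaky(z, cfg.leaky_relu_alpha)
            cache["branches"].append((p, z))
            feats.append(a.reshape(a.shape[0], -1))
        f = np.concatenate(feats, axis=1)
        z1 = f @ self.params["W1"] + self.params["b1"]
        a1 = _leaky(z1, cfg.leaky_relu_alpha)
        if dropout_rng is not None and cfg.dropout_rate > 0:
            mask = (dropout_rng.random(a1.shape) >= cfg.dropout_rate) / (1 - cfg.dropout_rate)
        else:
            mask = np.ones_like(a1)
        d1 = a1 * mask
        z2 = d1 @ self.params["W2"] + self.params["b2"]
        probs = _softmax(z2)
        cache.update(f=f, z1=z1, mask=mask, d1=d1, probs=probs)
        return probs, cache

    def _backward(self, cache: dict, y: np.ndarray) -> Dict[str, np.ndarray]:
        cfg = self.config
        n = len(y)
        dz2 = cache["probs"].copy()
        dz2[np.arange(n), y] -= 1.0
        dz2 /= n
        grads = {
            "W2": cache["d1"].T @ dz2,
            "b2": dz2.sum(axis=0),
        }
        dd1 = dz2 @ self.params["W2"].T
        dz1 = dd1 * cache["mask"] * _leaky_grad(cache["z1"], cfg.leaky_relu_alpha)
        grads["W1"] = cache["f"].T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        df = dz1 @ self.params["W1"].T
        offset = 0
        k = cfg.kernels_per_branch
        for b, h in enumerate(cfg.branch_kernel_heights):
            t = MAX_LENGTH - h + 1
            p, z = cache["branches"][b]
            da = df[:, offset:offset + t * k].reshape(-1, t, k)
            dz = da * _leaky_grad(z, cfg.leaky_relu_alpha)
            grads[f"Wc{b}"] = np.einsum("nti,ntk->ik", p, dz)
            grads[f"bc{b}"] = dz.sum(axis=(0, 1))
            offset += t * k
        return grads

    # --------------------------------------------------------------- training

    @staticmethod
    def _xent(probs: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))

    def train(
        self,
        train_x: np.ndarray,
        train_y: np.ndarray,
        val_x: np.ndarray,
        val_y: np.ndarray,
        verbose: bool = False,
    ) -> Dict[str, List[float]]:
        """Train with Adam and early stopping on validation loss.

        Halts at ``max_epochs`` or when validation loss fails to improve for
        ``early_stopping_patience`` consecutive epochs (patience 0 stops at
        the first non-improving epoch); the weights from the best validation
        epoch are restored. Returns the per-epoch loss history.
        """
        cfg = self.config
        if len(train_x) == 0 or len(val_x) == 0:
            raise ValueError("training and validation sets must be nonempty")
        if len(np.unique(val_y)) < 2:
            logger.warning(
                "validation set contains a single class; early stopping uses "
                "cross-entropy loss only"
            )
        train_x = np.asarray(train_x, dtype=np.float64)
        val_x = np.asarray(val_x, dtype=np.float64)
        train_y = np.asarray(train_y, dtype=np.int64)
        val_y = np.asarray(val_y, dtype=np.int64)

        rng = np.random.default_rng(self.config.seed + 1)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(val) for k, val in self.params.items()}
        step = 0
        best_loss = np.inf
        best_params = {k: p.copy() for k, p in self.params.items()}
        bad_epochs = 0
        history: Dict[str, List[float]] = {"train_loss": [], "val_loss": []}

        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(train_x))
            epoch_loss = 0.0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = train_x[idx], train_y[idx]
                probs, cache = self._forward(xb, dropout_rng=rng)
                epoch_loss += self._xent(probs, yb) * len(idx)
                grads = self._backward(cache, yb)
                step += 1
                lr_t = cfg.learning_rate * (
                    np.sqrt(1 - cfg.adam_beta2 ** step) / (1 - cfg.adam_beta1 ** step)
                )
                for key, g in grads.items():
                    m[key] = cfg.adam_beta1 * m[key] + (1 - cfg.adam_beta1) * g
                    v[key] = cfg.adam_beta2 * v[key] + (1 - cfg.adam_beta2) * g * g
                    self.params[key] -= lr_t * m[key] / (np.sqrt(v[key]) + cfg.adam_eps)
            train_loss = epoch_loss / len(train_x)
            val_loss = self._xent(self.predict_proba(val_x), val_y)
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            if verbose:
                logger.info("epoch %d: train %.4f val %.4f", epoch, train_loss, val_loss)
            if val_loss < best_loss:
                best_loss = val_loss
                best_params = {k: p.copy() for k, p in self.params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= max(1, cfg.early_stopping_patience):
                    break
        self.params = best_params
        self.history = history
        return history

    # -------------------------------------------------------------- inference

    def predict_proba(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """(N, 11, 21) inputs → (N, 2) softmax probabilities; dropout disabled."""
        x = np.asarray(x, dtype=np.float64)
        out = []
        for start in range(0, len(x), batch_size):
            probs, _ = self._forward(x[start:start + batch_size], dropout_rng=None)
            out.append(probs)
        return np.concatenate(out) if out else np.empty((0, 2))

    def score_peptides(self, peptides: Sequence) -> np.ndarray:
        """Positive-class probability for each peptide, order preserved."""
        if len(peptides) == 0:
            return np.empty(0)
        return self.predict_proba(encode_batch(peptides))[:, 1]

    def predict(self, peptides: Sequence) -> List[PredictionResult]:
        """One :class:`PredictionResult` per peptide, order preserved."""
        scores = self.score_peptides(peptides)
        results = []
        for p, s in zip(peptides, scores):
            pep = p if isinstance(p, Peptide) else Peptide(p)
            results.append(
                PredictionResult(
                    peptide=pep,
                    score=float(s),
                    call=int(s >= self.config.decision_threshold),
                )
            )
        return results

    def input_gradients(self, x: np.ndarray) -> np.ndarray:
        """Gradient of the positive-class logit with respect to each input cell,
        dropout disabled. Used for anchor-position attribution."""
        cfg = self.config
        x = np.asarray(x, dtype=np.float64)
        _, cache = self._forward(x, dropout_rng=None)
        n = len(x)
        dz2 = np.tile(np.array([0.0, 1.0]), (n, 1))
        dd1 = dz2 @ self.params["W2"].T
        dz1 = dd1 * _leaky_grad(cache["z1"], cfg.leaky_relu_alpha)
        df = dz1 @ self.params["W1"].T
        dx = np.zeros_like(x)
        offset = 0
        k = cfg.kernels_per_branch
        for b, h in enumerate(cfg.branch_kernel_heights):
            t = MAX_LENGTH - h + 1
            _, z = cache["branches"][b]
            da = df[:, offset:offset + t * k].reshape(-1, t, k)
            dz = da * _leaky_grad(z, cfg.leaky_relu_alpha)
            dp = dz @ self.params[f"Wc{b}"].T  # (n, t, h*21)
            dp = dp.reshape(n, t, h, N_COLUMNS)
            for i in range(t):
                dx[:, i:i + h, :] += dp[:, i]
            offset += t * k
        return dx

    def saliency_by_position(self, x: np.ndarray) -> np.ndarray:
        """Mean absolute input gradient per row (length 11), averaged over
        samples and residue columns."""
        return np.abs(self.input_gradients(x)).mean(axis=(0, 2))

    # ------------------------------------------------------------ persistence

    def save(self, directory) -> None:
        """Write config + alphabet mapping + seed (JSON) and weights (npz)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": asdict(self.config),
            "allele": self.allele,
            "alphabet": FULL_ALPHABET,
            "history": self.history,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        np.savez(directory / "weights.npz", **self.params)

    @classmethod
    def load(cls, directory) -> "PresentationCNN":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        if meta["alphabet"] != FULL_ALPHABET:
            raise ValueError("checkpoint alphabet mapping does not match this build")
        cfg_dict = meta["config"]
        cfg_dict["branch_kernel_heights"] = tuple(cfg_dict["branch_kernel_heights"])
        model = cls(ModelConfig(**cfg_dict), allele=meta.get("allele"))
        with np.load(directory / "weights.npz") as npz:
            model.params = {k: npz[k] for k in npz.files}
        model.history = meta.get("history", {})
        return model


def build_model(config: Optional[ModelConfig] = None, allele: Optional[str] = None) -> PresentationCNN:
    """Construct an untrained classifier from a config."""
    return PresentationCNN(config, allele=allele)


def percentile_ranks_from_scores(
    query_scores: np.ndarray, background_scores: np.ndarray
) -> np.ndarray:
    """rank(q) = 100 × (1 + #background strictly above q) / (1 + #background).

    Lower is better; ranks lie in (0, 100].
    """
    bg = np.sort(np.asarray(background_scores, dtype=np.float64))
    if bg.size == 0:
        raise ValueError("background must be nonempty")
    q = np.asarray(query_scores, dtype=np.float64)
    n_above = bg.size - np.searchsorted(bg, q, side="right")
    return 100.0 * (1 + n_above) / (1 + bg.size)


def percentile_ranks(
    model: PresentationCNN, query_peptides: Sequence, background_peptides: Sequence
) -> np.ndarray:
    """Percentile ranks of query peptides against a background population,
    using the model's positive-class scores. Rank ≤ 2.0 is the conventional
    binder call."""
    if len(background_peptides) == 0:
        raise ValueError("background must be nonempty")
    return percentile_ranks_from_scores(
        model.score_peptides(query_peptides),
        model.score_peptides(background_peptides),
    )
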