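"""Texture encoding and suppression (TES) as plain-array operations.

A feature map is treated as a bag of N = W*H channel vectors (descriptors).
Each descriptor is compared against K learnable codewords; the residuals
are softly assigned with per-codeword smoothing factors and summed into a
global, orderless K x C encoding.  A suppression step then damps the
per-channel maximum of the encoding by a factor lambda in (0, 1], so that
a single dominant structure (ribs, clavicles) cannot monopolise a channel.

These functions are the reference surface used by tests and the CLI; the
trainable layer in :mod:`pneumotex.nn` implements the same arithmetic with
gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Codebook",
    "compute_residuals",
    "assignment_weights",
    "aggregate_encoding",
    "suppress_encoding",
    "encode",
]


@dataclass
class Codebook:
    """K learnable codewords (K x C) with K smoothing factors."""

    codewords: np.ndarray
    smoothing: np.ndarray

    def __post_init__(self):
        self.codewords = np.asarray(self.codewords, dtype=np.float64)
        self.smoothing = np.asarray(self.smoothing, dtype=np.float64)
        if self.codewords.ndim != 2:
            raise ValueError("codewords must be a K x C matrix")
        if self.smoothing.shape != (self.codewords.shape[0],):
            raise ValueError("smoothing must be a length-K vector")
        if not (np.isfinite(self.codewords).all() and np.isfinite(self.smoothing).all()):
            raise ValueError("codebook entries must be finite")

    @property
    def k(self) -> int:
        return self.codewords.shape[0]

    @property
    def channels(self) -> int:
        return self.codewords.shape[1]

    @classmethod
    def random(cls, k: int, channels: int, seed: int | None = None) -> "Codebook":
        """Dictionary-layer initialization: codewords U(-1/sqrt(K), 1/sqrt(K)), smoothing U(0,1)."""
        rng = np.random.default_rng(seed)
        bound = 1.0 / np.sqrt(k)
        return cls(rng.uniform(-bound, bound, size=(k, channels)), rng.uniform(0.0, 1.0, size=k))

    def save(self, path) -> None:
        np.savez(path, codewords=self.codewords, smoothing=self.smoothing)

    @classmethod
    def load(cls, path) -> "Codebook":
        with np.load(path) as npz:
            return cls(npz["codewords"], npz["smoothing"])


def _as_descriptors(features: np.ndarray) -> np.ndarray:
    """Accept W x H x C or N x C and return the N x C descriptor matrix."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim == 3:
        w, h, c = features.shape
        features = features.reshape(w * h, c)
    if features.ndim != 2 or features.shape[0] < 1 or features.shape[1] < 1:
        raise ValueError(f"features must be N x C (or W x H x C), got shape {features.shape}")
    if not np.isfinite(features).all():
        raise ValueError("feature descriptors must be finite")
    return features


def compute_residuals(features: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Residual tensor r[i, j, :] = x_i - d_j of shape (N, K, C)."""
    x = _as_descriptors(features)
    if x.shape[1] != codebook.channels:
        raise ValueError(
            f"feature channel count {x.shape[1]} does not match codebook channels {codebook.channels}"
        )
    return x[:, None, :] - codebook.codewords[None, :, :]


def assignment_weights(residuals: np.ndarray, smoothing: np.ndarray) -> np.ndarray:
    """Soft-assignment weights w[i, j] = softmax_j(-s_j * ||r_ij||^2), shape (N, K).

    Computed with a per-descriptor log-sum-exp shift for stability.
    """
    residuals = np.asarray(residuals, dtype=np.float64)
    smoothing = np.asarray(smoothing, dtype=np.float64)
    if residuals.ndim != 3 or residuals.shape[1] != smoothing.shape[0]:
        raise ValueError("residuals must be N x K x C with K matching the smoothing vector")
    norms = np.einsum("ikc,ikc->ik", residuals, residuals)
    if not np.isfinite(norms).all():
        raise FloatingPointError("non-finite residual norms")
    logits = -smoothing[None, :] * norms
    logits -= logits.max(axis=1, keepdims=True)
    ex = np.exp(logits)
    return ex / ex.sum(axis=1, keepdims=True)


def aggregate_encoding(residuals: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Orderless aggregation e_j = sum_i w_ij r_ij, shape (K, C)."""
    residuals = np.asarray(residuals, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if residuals.ndim != 3 or weights.ndim != 2 or residuals.shape[:2] != weights.shape:
        raise ValueError(
            f"inconsistent shapes: residuals {residuals.shape}, weights {weights.shape}"
        )
    return np.einsum("ik,ikc->kc", weights, residuals)


def suppress_encoding(encoding: np.ndarray, lam: float) -> np.ndarray:
    """Scale the per-channel maximum of the K x C encoding by lam in (0, 1].

    Each channel is a length-K column; the first entry attaining the column
    maximum (ties broken toward the lowest codeword index) is multiplied by
    lam, all other entries are left untouched.  lam = 1 is the identity.
    """
    if not 0.0 < lam <= 1.0:
        raise ValueError(f"suppression factor must be in (0, 1], got {lam}")
    encoding = np.asarray(encoding, dtype=np.float64)
    if encoding.ndim != 2:
        raise ValueError("encoding must be a K x C matrix")
    out = encoding.copy()
    idx = encoding.argmax(axis=0)             # first max per channel
    cols = np.arange(encoding.shape[1])
    out[idx, cols] *= lam
    return out


def encode(features: np.ndarray, codebook: Codebook, lam: float = 1.0) -> np.ndarray:
    """Full TES operator: residuals -> weights -> aggregation -> suppression."""
    r = compute_residuals(features, codebook)
    w = assignment_weights(r, codebook.smoothing)
    return suppress_encoding(aggregate_encoding(r, w), lam)
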