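"""Training objectives: supervised contrastive loss, ordinal label
distributions, and class-reweighted KL divergence.

Profusion levels form an ordered sequence (0 < 1 < 2 < 3): a radiograph
labelled level t is better described by a distribution peaked at t that
decays over neighbouring levels than by a one-hot label.  The ground-truth
distribution is softmax(-|t - j|) over levels j.  The KL term comparing it
with the predicted softmax is scaled by the inverse training-set frequency
of the true class, which counteracts the strong imbalance of profusion
levels in screening data.  The contrastive term pulls same-level embeddings
together and pushes different levels apart at temperature tau.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "ordinal_label_distribution",
    "predicted_distribution",
    "supcon_loss",
    "supcon_loss_grad",
    "class_frequencies",
    "reweighted_kl_loss",
    "kl_loss_batch",
    "total_loss",
]


def ordinal_label_distribution(level_index: int, level_count: int) -> np.ndarray:
    """Ground-truth ordinal distribution y_j = softmax_j(-|t - j|).

    Levels are unit-spaced integers 0..C-1; the distribution is maximal at
    the true level ``level_index`` and decays exponentially with ordinal
    distance.
    """
    if not 0 <= level_index < level_count:
        raise ValueError(f"level_index {level_index} outside [0, {level_count - 1}]")
    j = np.arange(level_count, dtype=np.float64)
    logits = -np.abs(float(level_index) - j)
    ex = np.exp(logits - logits.max())
    return ex / ex.sum()


def predicted_distribution(scores: np.ndarray) -> np.ndarray:
    """Softmax of the classifier scores, with log-sum-exp stabilization."""
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    ex = np.exp(scores - scores.max(axis=-1, keepdims=True))
    return ex / ex.sum(axis=-1, keepdims=True)


def _similarity_matrix(z: np.ndarray) -> np.ndarray:
    """Cosine similarity matrix of the rows of z."""
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("embeddings must be non-zero for cosine similarity")
    zn = z / norms
    return zn @ zn.T


def supcon_loss(embeddings: np.ndarray, labels: np.ndarray, tau: float = 0.1,
                variant: str = "in") -> float:
    """Supervised contrastive loss over a batch of embeddings.

    For each class subset M_c, every anchor i in M_c contributes a log of
    the ratio between the summed exponentiated similarities to its positives
    (same class, excluding itself) and to all other samples, at temperature
    ``tau``; class contributions are averaged by |M_c| and summed with a
    leading minus.  ``variant="in"`` keeps this log-of-ratio-of-sums form;
    ``variant="out"`` instead averages the log-ratio per positive pair (the
    common form in the contrastive-learning literature).  Classes with a
    single member have no positive and are skipped with a warning.
    """
    loss, _ = _supcon(np.asarray(embeddings, dtype=np.float64),
                      np.asarray(labels), float(tau), variant, want_grad=False)
    return loss


def supcon_loss_grad(embeddings: np.ndarray, labels: np.ndarray, tau: float = 0.1,
                     variant: str = "in") -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the (unnormalized) embeddings."""
    return _supcon(np.asarray(embeddings, dtype=np.float64),
                   np.asarray(labels), float(tau), variant, want_grad=True)


def _supcon(z: np.ndarray, labels: np.ndarray, tau: float, variant: str,
            want_grad: bool):
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("need a batch of at least 2 embedding rows")
    if tau <= 0:
        raise ValueError("temperature tau must be positive")
    if variant not in ("in", "out"):
        raise ValueError(f"unknown supcon variant {variant!r}")
    b = z.shape[0]
    sim = _similarity_matrix(z)
    logits = sim / tau
    np.fill_diagonal(logits, -np.inf)          # self-similarity excluded everywhere
    shift = logits.max(axis=1, keepdims=True)
    ex = np.exp(logits - shift)                # stable: entries in (0, 1]
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)

    denom = ex.sum(axis=1)
    num = (ex * same).sum(axis=1)
    pos_counts = same.sum(axis=1)

    loss = 0.0
    gl = np.zeros_like(sim)                    # d loss / d logits
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size < 2:
            warnings.warn(
                f"class {c} has a single sample in the batch; skipped in the contrastive loss",
                stacklevel=3,
            )
            continue
        inv = 1.0 / members.size
        for i in members:
            if variant == "in":
                loss -= inv * (np.log(num[i]) - np.log(denom[i]))
                if want_grad:
                    gl[i] -= inv * (same[i] * ex[i] / num[i] - ex[i] / denom[i])
            else:
                # per-positive-pair average of log(e_ip / denom_i)
                npos = pos_counts[i]
                pos = np.flatnonzero(same[i])
                loss -= inv / npos * ((logits[i, pos] - shift[i]).sum()
                                      - npos * np.log(denom[i]))
                if want_grad:
                    gl[i, pos] -= inv / npos
                    gl[i] += inv * ex[i] / denom[i]
    if not want_grad:
        return float(loss), None
    gl /= tau
    # backprop through sim = zn zn^T then through row normalization
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    zn = z / norms
    dzn = (gl + gl.T) @ zn
    dz = (dzn - zn * (dzn * zn).sum(axis=1, keepdims=True)) / norms
    return float(loss), dz


def class_frequencies(labels, level_count: int | None = None) -> np.ndarray:
    """Empirical relative frequency pi_c of each level in the training labels."""
    labels = np.asarray(labels, dtype=np.intp)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    c = int(labels.max()) + 1 if level_count is None else int(level_count)
    counts = np.bincount(labels, minlength=c).astype(np.float64)
    return counts / labels.size


def reweighted_kl_loss(y: np.ndarray, p: np.ndarray, prior: np.ndarray,
                       level_index: int) -> float:
    """Class-reweighted KL divergence (1/pi_t) * sum_j y_j ln(y_j / p_j).

    Non-negative, zero only at p = y, and inversely proportional to the
    training-set frequency of the true class, so rare profusion levels
    weigh more.  The 0 * ln 0 terms are taken as 0.
    """
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    prior = np.asarray(prior, dtype=np.float64)
    pi = prior[level_index]
    if pi <= 0:
        raise ValueError(f"class {level_index} has zero training frequency; weight undefined")
    mask = y > 0
    kl = float(np.sum(y[mask] * (np.log(y[mask]) - np.log(p[mask]))))
    return kl / float(pi)


def kl_loss_batch(y: np.ndarray, scores: np.ndarray, prior: np.ndarray,
                  levels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean reweighted KL over a batch, plus its gradient w.r.t. the scores.

    ``y`` is (B, C) ground-truth distributions, ``scores`` the raw classifier
    outputs; the gradient of each sample's term w.r.t. its scores is
    (p - y) / pi_t, divided by the batch size for the mean.
    """
    p = predicted_distribution(scores)
    b = scores.shape[0]
    pis = np.asarray(prior, dtype=np.float64)[levels]
    if np.any(pis <= 0):
        raise ValueError("a batch label has zero training frequency")
    mask = y > 0
    terms = np.where(mask, y * (np.log(np.where(mask, y, 1.0)) - np.log(p)), 0.0).sum(axis=1)
    loss = float((terms / pis).mean())
    grad = (p - y) / pis[:, None] / b
    return loss, grad


def total_loss(supcon: float, kl: float, alpha: float = 0.5, beta: float = 0.5) -> float:
    """Weighted combination alpha * l_sup + beta * l_kl."""
    if alpha < 0 or beta < 0 or alpha + beta <= 0:
        raise ValueError("need alpha, beta >= 0 with alpha + beta > 0")
    return alpha * supcon + beta * kl
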