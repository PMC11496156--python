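"""Loss functions: closed forms, loop oracles, and invariances."""

import math
import warnings

import numpy as np
import pytest

from pneumotex.objectives import (
    class_frequencies,
    kl_loss_batch,
    ordinal_label_distribution,
    predicted_distribution,
    reweighted_kl_loss,
    supcon_loss,
    supcon_loss_grad,
    total_loss,
)


# -- ordinal label distributions ---------------------------------------

def direct_ldl(t, c):
    ex = [math.exp(-abs(t - j)) for j in range(c)]
    return np.array(ex) / sum(ex)


def test_ldl_single_level():
    np.testing.assert_array_equal(ordinal_label_distribution(0, 1), [1.0])


def test_ldl_matches_direct_evaluation():
    np.testing.assert_allclose(ordinal_label_distribution(0, 4), direct_ldl(0, 4), atol=1e-12)
    np.testing.assert_allclose(
        ordinal_label_distribution(0, 4),
        [0.643914260, 0.236882818, 0.087144319, 0.032058603], atol=1e-9)


def test_ldl_mirror_symmetry():
    np.testing.assert_allclose(ordinal_label_distribution(1, 4),
                               ordinal_label_distribution(2, 4)[::-1], atol=1e-15)


@pytest.mark.parametrize("c", range(2, 11))
def test_ldl_contract_all_levels(c):
    for t in range(c):
        y = ordinal_label_distribution(t, c)
        assert abs(y.sum() - 1.0) < 1e-12
        assert y.argmax() == t
        # strictly decreasing away from the mode on both sides
        assert all(y[j] > y[j + 1] for j in range(t, c - 1))
        assert all(y[j] > y[j - 1] for j in range(1, t + 1))
        # strict log-concavity along j
        logs = np.log(y)
        assert all(2 * logs[j] >= logs[j - 1] + logs[j + 1] - 1e-12 for j in range(1, c - 1))


def test_ldl_out_of_range_raises():
    with pytest.raises(ValueError):
        ordinal_label_distribution(4, 4)


# -- predicted distribution --------------------------------------------

def test_softmax_uniform_and_closed_form():
    np.testing.assert_allclose(predicted_distribution(np.zeros(4)), 0.25)
    np.testing.assert_allclose(predicted_distribution(np.array([0.0, 0.0, 0.0, np.log(3)])),
                               [1 / 6, 1 / 6, 1 / 6, 1 / 2], atol=1e-14)


def test_softmax_matches_naive_oracle(rng):
    s = rng.normal(scale=5, size=4)
    naive = np.exp(s) / np.exp(s).sum()
    np.testing.assert_allclose(predicted_distribution(s), naive, atol=1e-12)


# -- supervised contrastive loss ---------------------------------------

def supcon_oracle(z, labels, tau):
    """Brute-force nested-loop evaluation of the log-of-ratio-of-sums form."""
    zn = z / np.linalg.norm(z, axis=1, keepdims=True)
    b = len(z)
    loss = 0.0
    for c in np.unique(labels):
        members = [i for i in range(b) if labels[i] == c]
        if len(members) < 2:
            continue
        for i in members:
            num = sum(math.exp(float(zn[i] @ zn[m]) / tau) for m in members if m != i)
            den = sum(math.exp(float(zn[i] @ zn[j]) / tau) for j in range(b) if j != i)
            loss -= (1.0 / len(members)) * math.log(num / den)
    return loss


@pytest.mark.parametrize("tau", [0.05, 0.1, 1.0])
def test_supcon_identical_embeddings_closed_form(tau):
    z = np.tile([0.6, 0.8], (4, 1))
    labels = np.array([0, 0, 1, 1])
    assert abs(supcon_loss(z, labels, tau) - 2 * math.log(3)) < 1e-9


def test_supcon_rotation_invariant(rng):
    z = rng.normal(size=(8, 5))
    labels = rng.integers(0, 2, size=8)
    labels[:4] = [0, 0, 1, 1]
    q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
    assert abs(supcon_loss(z, labels, 0.1) - supcon_loss(z @ q.T, labels, 0.1)) < 1e-8


def test_supcon_matches_loop_oracle(rng):
    for _ in range(5):
        z = rng.normal(size=(8, 6))
        labels = np.repeat([0, 1, 2], [3, 3, 2])[rng.permutation(8)]
        assert abs(supcon_loss(z, labels, 0.1) - supcon_oracle(z, labels, 0.1)) < 1e-8


def test_supcon_batch_order_invariant(rng):
    z = rng.normal(size=(8, 4))
    labels = np.array([0, 0, 1, 1, 2, 2, 0, 1])
    perm = rng.permutation(8)
    assert abs(supcon_loss(z, labels, 0.1) - supcon_loss(z[perm], labels[perm], 0.1)) < 1e-10


def test_supcon_singleton_class_skipped_with_warning(rng):
    z = rng.normal(size=(5, 4))
    labels = np.array([0, 0, 1, 1, 2])       # class 2 has one member
    with pytest.warns(UserWarning, match="single sample"):
        full = supcon_loss(z, labels, 0.1)
    without = supcon_loss(z[:4], labels[:4], 0.1)
    # the singleton contributes as a negative for other anchors, so the
    # losses differ, but both are finite
    assert np.isfinite(full) and np.isfinite(without)


def test_supcon_gradient_matches_finite_differences(rng):
    z = rng.normal(size=(6, 4))
    labels = np.array([0, 0, 1, 1, 2, 2])
    loss, grad = supcon_loss_grad(z, labels, 0.1)
    for i in range(z.shape[0]):
        for j in range(z.shape[1]):
            old = z[i, j]
            z[i, j] = old + 1e-6
            lp = supcon_loss(z, labels, 0.1)
            z[i, j] = old - 1e-6
            lm = supcon_loss(z, labels, 0.1)
            z[i, j] = old
            fd = (lp - lm) / 2e-6
            assert abs(fd - grad[i, j]) < 1e-5


def test_supcon_out_variant_differs_but_close_on_tight_clusters(rng):
    z = rng.normal(size=(6, 4))
    labels = np.array([0, 0, 0, 1, 1, 1])
    lin = supcon_loss(z, labels, 0.5, variant="in")
    lout = supcon_loss(z, labels, 0.5, variant="out")
    assert np.isfinite(lin) and np.isfinite(lout)
    assert lout >= lin - 1e-12               # Jensen: out-form upper-bounds the in-form


# -- class frequencies and reweighted KL -------------------------------

def test_class_frequencies_balanced_and_skewed():
    np.testing.assert_allclose(class_frequencies([0, 0, 1, 1]), [0.5, 0.5])
    np.testing.assert_allclose(class_frequencies([0, 0, 0, 1]), [0.75, 0.25])


def test_class_frequencies_screening_case_counts():
    # per-level counts typical of an upper-zone screening dataset
    counts = (225, 157, 90, 34)
    labels = np.repeat(np.arange(4), counts)
    np.testing.assert_allclose(class_frequencies(labels), np.array(counts) / 506)


def test_class_frequencies_empty_raises():
    with pytest.raises(ValueError):
        class_frequencies([])


def test_kl_zero_iff_equal():
    y = ordinal_label_distribution(1, 4)
    assert reweighted_kl_loss(y, y, np.array([0.25] * 4), 1) == pytest.approx(0.0, abs=1e-12)


def test_kl_closed_form_with_zero_entry():
    val = reweighted_kl_loss(np.array([1.0, 0.0]), np.array([0.5, 0.5]), np.array([1.0, 1.0]), 0)
    assert val == pytest.approx(math.log(2), abs=1e-12)


def test_kl_scales_as_inverse_frequency(rng):
    y = ordinal_label_distribution(2, 4)
    p = predicted_distribution(rng.normal(size=4))
    unweighted = sum(float(y[j] * math.log(y[j] / p[j])) for j in range(4))
    prior = np.array([0.25, 0.25, 0.25, 0.25])
    assert reweighted_kl_loss(y, p, prior, 2) == pytest.approx(4 * unweighted, rel=1e-12)
    assert reweighted_kl_loss(y, p, prior * 2, 2) == pytest.approx(2 * unweighted, rel=1e-12)


def test_kl_nonnegative_random(rng):
    prior = np.array([0.4, 0.3, 0.2, 0.1])
    for _ in range(20):
        t = int(rng.integers(0, 4))
        y = ordinal_label_distribution(t, 4)
        p = predicted_distribution(rng.normal(scale=3, size=4))
        assert reweighted_kl_loss(y, p, prior, t) >= 0.0


def test_kl_zero_prior_raises():
    y = ordinal_label_distribution(0, 2)
    with pytest.raises(ValueError, match="zero training frequency"):
        reweighted_kl_loss(y, y, np.array([0.0, 1.0]), 0)


def test_kl_batch_gradient_matches_finite_differences(rng):
    scores = rng.normal(size=(3, 4))
    levels = np.array([0, 2, 3])
    prior = np.array([0.4, 0.3, 0.2, 0.1])
    ytab = np.stack([ordinal_label_distribution(t, 4) for t in range(4)])
    loss, grad = kl_loss_batch(ytab[levels], scores, prior, levels)
    for i in range(3):
        for j in range(4):
            old = scores[i, j]
            scores[i, j] = old + 1e-6
            lp, _ = kl_loss_batch(ytab[levels], scores, prior, levels)
            scores[i, j] = old - 1e-6
            lm, _ = kl_loss_batch(ytab[levels], scores, prior, levels)
            scores[i, j] = old
            assert abs((lp - lm) / 2e-6 - grad[i, j]) < 1e-6


# -- combined loss -----------------------------------------------------

def test_total_loss_linearity():
    assert total_loss(2.0, 4.0, alpha=0.0, beta=1.0) == 4.0
    assert total_loss(2.0, 4.0, alpha=1.0, beta=0.0) == 2.0
    assert total_loss(2.0, 4.0, alpha=0.5, beta=0.5) == 3.0


def test_total_loss_rejects_degenerate_weights():
    with pytest.raises(ValueError):
        total_loss(1.0, 1.0, alpha=0.0, beta=0.0)
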