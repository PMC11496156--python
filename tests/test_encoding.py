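"""Texture encoding: vectorized operations against loop oracles, the
suppression contract, orderlessness, and gradient correctness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pneumotex import nn, objectives
from pneumotex.encoding import (
    Codebook,
    aggregate_encoding,
    assignment_weights,
    compute_residuals,
    encode,
    suppress_encoding,
)


# -- independent loop oracles -----------------------------------------

def residuals_oracle(x, d):
    n, c = x.shape
    k = d.shape[0]
    out = np.empty((n, k, c))
    for i in range(n):
        for j in range(k):
            for l in range(c):
                out[i, j, l] = x[i, l] - d[j, l]
    return out


def weights_oracle(residuals, s):
    n, k, _ = residuals.shape
    out = np.empty((n, k))
    for i in range(n):
        e = [np.exp(-s[j] * np.dot(residuals[i, j], residuals[i, j])) for j in range(k)]
        tot = sum(e)
        for j in range(k):
            out[i, j] = e[j] / tot
    return out


def aggregate_oracle(residuals, w):
    n, k, c = residuals.shape
    out = np.zeros((k, c))
    for j in range(k):
        for i in range(n):
            out[j] += w[i, j] * residuals[i, j]
    return out


def suppress_oracle(e, lam):
    out = e.copy()
    for l in range(e.shape[1]):
        out[np.argmax(e[:, l]), l] *= lam
    return out


def encode_oracle(x, cb, lam):
    r = residuals_oracle(x, cb.codewords)
    return suppress_oracle(aggregate_oracle(r, weights_oracle(r, cb.smoothing)), lam)


# -- residuals ---------------------------------------------------------

def test_residuals_identity_and_subtraction():
    cb = Codebook(np.array([[1.0, 1.0]]), np.array([0.5]))
    assert np.all(compute_residuals(np.array([[1.0, 1.0]]), cb) == 0.0)
    r = compute_residuals(np.array([[1.0, 2.0], [3.0, 4.0]]), cb)
    np.testing.assert_array_equal(r[:, 0, :], [[0.0, 1.0], [2.0, 3.0]])


def test_residuals_match_loop_oracle(rng):
    x = rng.normal(size=(16, 8))
    cb = Codebook.random(4, 8, seed=0)
    np.testing.assert_allclose(compute_residuals(x, cb), residuals_oracle(x, cb.codewords),
                               atol=1e-6)


def test_residuals_channel_mismatch_raises():
    cb = Codebook.random(2, 5, seed=0)
    with pytest.raises(ValueError, match="channel"):
        compute_residuals(np.zeros((3, 4)), cb)


# -- assignment weights ------------------------------------------------

def test_weights_zero_smoothing_is_uniform(rng):
    r = rng.normal(size=(6, 4, 3))
    w = assignment_weights(r, np.zeros(4))
    np.testing.assert_allclose(w, 0.25)


def test_weights_single_codeword_is_one(rng):
    w = assignment_weights(rng.normal(size=(5, 1, 3)), np.array([0.7]))
    np.testing.assert_allclose(w, 1.0)


def test_weights_match_naive_formula(rng):
    r = rng.normal(size=(8, 4, 8))
    s = rng.uniform(0, 1, size=4)
    np.testing.assert_allclose(assignment_weights(r, s), weights_oracle(r, s), atol=1e-10)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_weight_rows_sum_to_one(seed):
    g = np.random.default_rng(seed)
    r = g.normal(scale=3.0, size=(g.integers(1, 12), g.integers(1, 6), g.integers(1, 8)))
    s = g.uniform(-0.5, 2.0, size=r.shape[1])
    w = assignment_weights(r, s)
    np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)
    assert (w > 0).all()


# -- aggregation -------------------------------------------------------

def test_aggregate_zero_residual():
    assert np.all(aggregate_encoding(np.zeros((1, 1, 4)), np.ones((1, 1))) == 0.0)


def test_aggregate_permutation_invariant(rng):
    r = rng.normal(size=(10, 3, 5))
    w = rng.dirichlet(np.ones(3), size=10)
    perm = rng.permutation(10)
    np.testing.assert_allclose(aggregate_encoding(r, w),
                               aggregate_encoding(r[perm], w[perm]), atol=1e-12)


def test_aggregate_matches_loop_oracle(rng):
    r = rng.normal(size=(7, 4, 6))
    w = rng.dirichlet(np.ones(4), size=7)
    np.testing.assert_allclose(aggregate_encoding(r, w), aggregate_oracle(r, w), atol=1e-12)


def test_aggregate_shape_mismatch_raises(rng):
    with pytest.raises(ValueError, match="shapes"):
        aggregate_encoding(rng.normal(size=(5, 3, 4)), rng.normal(size=(5, 2)))


# -- suppression -------------------------------------------------------

def test_suppress_column_example():
    e = np.array([[3.0], [1.0], [2.0]])
    np.testing.assert_allclose(suppress_encoding(e, 0.2), [[0.6], [1.0], [2.0]])


def test_suppress_lambda_one_is_identity(rng):
    e = rng.normal(size=(8, 16))
    np.testing.assert_array_equal(suppress_encoding(e, 1.0), e)


def test_suppress_matches_loop_oracle_and_locality(rng):
    e = rng.normal(size=(8, 16))
    out = suppress_encoding(e, 0.5)
    np.testing.assert_allclose(out, suppress_oracle(e, 0.5), atol=1e-12)
    diff = out != e
    assert (diff.sum(axis=0) == 1).all()       # exactly one change per channel
    np.testing.assert_allclose(out[diff], 0.5 * e[diff])


def test_suppress_tie_breaks_to_first_codeword():
    e = np.array([[2.0], [2.0], [1.0]])
    np.testing.assert_allclose(suppress_encoding(e, 0.5), [[1.0], [2.0], [1.0]])


@pytest.mark.parametrize("lam", [0.0, -0.1, 1.5])
def test_suppress_rejects_bad_lambda(lam):
    with pytest.raises(ValueError, match="suppression factor"):
        suppress_encoding(np.ones((2, 2)), lam)


# -- full operator -----------------------------------------------------

def test_encode_zero_when_feature_equals_codeword():
    cb = Codebook(np.array([[0.3, -0.2]]), np.array([1.0]))
    assert np.allclose(encode(np.array([[0.3, -0.2]]), cb, 0.5), 0.0)


def test_encode_is_orderless(rng):
    x = rng.normal(size=(32, 8))
    cb = Codebook.random(4, 8, seed=3)
    base = encode(x, cb, 0.4)
    for _ in range(3):
        np.testing.assert_allclose(encode(x[rng.permutation(32)], cb, 0.4), base, atol=1e-6)


def test_encode_accepts_spatial_layout(rng):
    x = rng.normal(size=(4, 8, 5))    # W x H x C
    cb = Codebook.random(3, 5, seed=1)
    np.testing.assert_allclose(encode(x, cb, 0.7), encode(x.reshape(32, 5), cb, 0.7))


def test_encode_matches_end_to_end_loop_oracle(rng):
    x = rng.normal(size=(16, 8))
    cb = Codebook.random(4, 8, seed=9)
    assert np.abs(encode(x, cb, 0.3) - encode_oracle(x, cb, 0.3)).max() < 1e-5


def test_encode_equals_explicit_composition(rng):
    x = rng.normal(size=(12, 6))
    cb = Codebook.random(5, 6, seed=2)
    r = compute_residuals(x, cb)
    w = assignment_weights(r, cb.smoothing)
    np.testing.assert_allclose(encode(x, cb, 0.6),
                               suppress_encoding(aggregate_encoding(r, w), 0.6))


def test_layer_forward_matches_functional_encode(rng):
    layer = nn.TextureEncoding(4, 6, lam=0.3, rng=np.random.default_rng(0))
    cb = Codebook(layer.codewords.value.astype(np.float64),
                  layer.smoothing.value.astype(np.float64))
    x = rng.normal(size=(2, 10, 6)).astype(np.float32)
    out = layer.forward(x)
    for b in range(2):
        np.testing.assert_allclose(out[b], encode(x[b].astype(np.float64), cb, 0.3), atol=1e-5)


def test_encode_gradients_match_finite_differences():
    """Central finite differences through the TES layer (tiny float64
    instance, N=4 K=2 C=3) agree with the analytic backward pass."""
    g = np.random.default_rng(7)
    layer = nn.TextureEncoding(2, 3, lam=0.5, rng=g)
    for _, p in layer.params():
        p.value = p.value.astype(np.float64)
        p.grad = np.zeros_like(p.value)
    x = g.random((1, 4, 3))
    w = g.normal(size=(2, 3))                 # fixed scalarization weights

    def scalar():
        return float((layer.forward(x)[0] * w).sum())

    layer.forward(x)
    dx = layer.backward(w[None])

    checks = [(p.value, p.grad) for _, p in layer.params()] + [(x, dx)]
    for values, grads in checks:
        flat, gflat = values.ravel(), np.asarray(grads).ravel()
        for i in range(flat.size):
            old = flat[i]
            flat[i] = old + 1e-6
            lp = scalar()
            flat[i] = old - 1e-6
            lm = scalar()
            flat[i] = old
            fd = (lp - lm) / 2e-6
            assert abs(fd - gflat[i]) / max(1e-10, abs(fd) + abs(gflat[i])) < 1e-4


def test_codebook_npz_round_trip(tmp_path):
    cb = Codebook.random(3, 4, seed=5)
    cb.save(tmp_path / "cb.npz")
    loaded = Codebook.load(tmp_path / "cb.npz")
    np.testing.assert_array_equal(loaded.codewords, cb.codewords)
    np.testing.assert_array_equal(loaded.smoothing, cb.smoothing)
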