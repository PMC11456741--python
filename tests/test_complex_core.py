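"""The complex layer primitives against independent oracles and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cvfreq.autodiff as ad
from cvfreq.autodiff import Tensor
from cvfreq.complex_core import (ComplexFeatureMap, ComplexKernelSet, cconv2d,
                                 cmaxpool, cmul, crelu, csigmoid, cupsample,
                                 glorot_variance, init_complex_weights)


def complex_mac_oracle(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Literal complex multiply-accumulate convolution ("same", zero pad)."""
    C, H, W = x.shape
    O, _, kh, kw = k.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
    out = np.zeros((O, H, W), dtype=complex)
    for o in range(O):
        for i in range(H):
            for j in range(W):
                acc = 0.0 + 0.0j
                for c in range(C):
                    for di in range(kh):
                        for dj in range(kw):
                            acc += xp[c, i + di, j + dj] * k[o, c, di, dj]
                out[o, i, j] = acc
    return out


def random_complex(rng, shape):
    return rng.normal(size=shape) + 1j * rng.normal(size=shape)


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("shape", [(1, 4, 4), (2, 8, 8)])
def test_cconv2d_matches_complex_mac_oracle(seed, shape):
    rng = np.random.default_rng(seed)
    x = random_complex(rng, shape)
    k = random_complex(rng, (2, shape[0], 3, 3))
    out = cconv2d(ComplexFeatureMap(x.real, x.imag),
                  ComplexKernelSet(k.real, k.imag)).to_complex()
    ref = complex_mac_oracle(x, k)
    np.testing.assert_allclose(out, ref, rtol=1e-6, atol=1e-9)


def test_cconv2d_identity_kernel(rng):
    x = random_complex(rng, (3, 6, 6))
    k = np.zeros((3, 3, 3, 3), dtype=complex)
    for c in range(3):
        k[c, c, 1, 1] = 1.0  # delta kernel, 1+0i at centre
    out = cconv2d(ComplexFeatureMap(x.real, x.imag),
                  ComplexKernelSet(k.real, k.imag)).to_complex()
    np.testing.assert_allclose(out, x, atol=1e-12)


def test_cconv2d_real_reduction(rng):
    """Purely real input and weights yield purely real output = real conv."""
    x = rng.normal(size=(2, 6, 6))
    k = rng.normal(size=(3, 2, 3, 3))
    out = cconv2d(ComplexFeatureMap(x, np.zeros_like(x)),
                  ComplexKernelSet(k, np.zeros_like(k)))
    assert np.abs(out.imag).max() <= 1e-8
    ref = ad.conv2d(Tensor(x[None]), Tensor(k), padding="same").data[0]
    np.testing.assert_allclose(out.real, ref, rtol=1e-10)


def test_cconv2d_bias_enters_each_part(rng):
    x = random_complex(rng, (1, 4, 4))
    k = np.zeros((2, 1, 3, 3), dtype=complex)
    out = cconv2d(ComplexFeatureMap(x.real, x.imag),
                  ComplexKernelSet(k.real, k.imag,
                                   bias_real=[1.0, 2.0], bias_imag=[-1.0, 0.5]))
    np.testing.assert_allclose(out.real[0], 1.0)
    np.testing.assert_allclose(out.real[1], 2.0)
    np.testing.assert_allclose(out.imag[0], -1.0)
    np.testing.assert_allclose(out.imag[1], 0.5)


def test_cconv2d_shape_mismatch_error(rng):
    x = random_complex(rng, (3, 4, 4))
    k = random_complex(rng, (1, 2, 3, 3))
    with pytest.raises(ValueError, match="channel mismatch"):
        cconv2d(ComplexFeatureMap(x.real, x.imag),
                ComplexKernelSet(k.real, k.imag))


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 10_000),
       st.floats(-2, 2), st.floats(-2, 2), st.floats(-2, 2), st.floats(-2, 2))
def test_cconv2d_complex_linearity(seed, ar, ai, br, bi):
    """cconv2d(aX + bY) = a cconv2d(X) + b cconv2d(Y) for complex scalars (no bias)."""
    rng = np.random.default_rng(seed)
    X = random_complex(rng, (2, 4, 4))
    Y = random_complex(rng, (2, 4, 4))
    K = random_complex(rng, (2, 2, 3, 3))
    a, b = complex(ar, ai), complex(br, bi)
    ker = ComplexKernelSet(K.real, K.imag)

    def f(z):
        return cconv2d(ComplexFeatureMap(z.real, z.imag), ker).to_complex()

    lhs = f(a * X + b * Y)
    rhs = a * f(X) + b * f(Y)
    scale = max(1.0, np.abs(rhs).max())
    np.testing.assert_allclose(lhs / scale, rhs / scale, rtol=0, atol=1e-6)


def test_crelu_splits_signs_and_is_idempotent(rng):
    x = ComplexFeatureMap(np.array([[[1.0]]]), np.array([[[-1.0]]]))
    y = crelu(x)
    assert y.real[0, 0, 0] == 1.0 and y.imag[0, 0, 0] == 0.0
    z = random_complex(rng, (2, 5, 5))
    once = crelu(ComplexFeatureMap(z.real, z.imag))
    twice = crelu(once)
    np.testing.assert_array_equal(once.real, twice.real)
    np.testing.assert_array_equal(once.imag, twice.imag)
    nonneg = ComplexFeatureMap(np.abs(z.real), np.abs(z.imag))
    fixed = crelu(nonneg)
    np.testing.assert_array_equal(fixed.real, nonneg.real)


def test_csigmoid_values_bounds_monotone(rng):
    zero = csigmoid(ComplexFeatureMap(np.zeros((1, 1, 1)), np.zeros((1, 1, 1))))
    assert zero.real[0, 0, 0] == pytest.approx(0.5)
    assert zero.imag[0, 0, 0] == pytest.approx(0.5)
    sat = csigmoid(ComplexFeatureMap(np.full((1, 1, 1), 50.0),
                                     np.full((1, 1, 1), -50.0)))
    assert sat.real[0, 0, 0] == pytest.approx(1.0, abs=1e-9)
    assert sat.imag[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
    # monotone componentwise, against the scalar sigmoid oracle
    a = random_complex(rng, (1, 6, 6))
    b = a + (0.5 + 0.25j)
    ya = csigmoid(ComplexFeatureMap(a.real, a.imag))
    yb = csigmoid(ComplexFeatureMap(b.real, b.imag))
    assert np.all(yb.real > ya.real) and np.all(yb.imag > ya.imag)
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    np.testing.assert_allclose(ya.real, sig(a.real), rtol=1e-12)
    assert 0 < ya.real.min() and ya.real.max() < 1
    assert 0 < ya.imag.min() and ya.imag.max() < 1


def test_cmaxpool_split_parts_can_come_from_different_pixels():
    x = np.array([[[1 + 4j, 2 + 3j], [3 + 2j, 4 + 1j]]])
    out = cmaxpool(ComplexFeatureMap(x.real, x.imag), window=2)
    assert out.to_complex()[0, 0, 0] == 4 + 4j


def test_cmaxpool_matches_split_real_pooling_oracle(rng):
    z = random_complex(rng, (3, 8, 8))
    out = cmaxpool(ComplexFeatureMap(z.real, z.imag), window=2)
    ref_r = ad.maxpool2d(Tensor(z.real), 2).data
    ref_i = ad.maxpool2d(Tensor(z.imag), 2).data
    np.testing.assert_array_equal(out.real, ref_r)
    np.testing.assert_array_equal(out.imag, ref_i)
    const = cmaxpool(ComplexFeatureMap(np.full((1, 4, 4), 2.0),
                                       np.full((1, 4, 4), -1.0)), window=2)
    assert np.all(const.real == 2.0) and np.all(const.imag == -1.0)


def test_cmaxpool_magnitude_variant_keeps_pixel_pairing(rng):
    z = random_complex(rng, (1, 4, 4))
    out = cmaxpool(ComplexFeatureMap(z.real, z.imag), window=2,
                   by_magnitude=True).to_complex()
    # every output value must be one of the input values in its window
    for i in range(2):
        for j in range(2):
            win = z[0, 2 * i:2 * i + 2, 2 * j:2 * j + 2].ravel()
            assert out[0, i, j] in win
            assert np.abs(out[0, i, j]) == np.abs(win).max()


def test_cmaxpool_rejects_non_divisible_dims(rng):
    z = random_complex(rng, (1, 5, 5))
    with pytest.raises(ValueError, match="not divisible"):
        cmaxpool(ComplexFeatureMap(z.real, z.imag), window=2)


@pytest.mark.parametrize("method", ["nearest", "bilinear"])
def test_cupsample_equals_split_real_resampling(method, rng):
    z = random_complex(rng, (2, 4, 4))
    out = cupsample(ComplexFeatureMap(z.real, z.imag), 2, method=method)
    assert out.shape == (2, 8, 8)
    np.testing.assert_allclose(out.real, ad.upsample2d(Tensor(z.real), 2, method).data)
    np.testing.assert_allclose(out.imag, ad.upsample2d(Tensor(z.imag), 2, method).data)
    const = cupsample(ComplexFeatureMap(np.full((1, 2, 2), 3.0),
                                        np.full((1, 2, 2), -2.0)), 2, method=method)
    np.testing.assert_allclose(const.real, 3.0)
    np.testing.assert_allclose(const.imag, -2.0)


def test_cupsample_nearest_replicates_blocks():
    z = np.arange(4).reshape(1, 2, 2).astype(float)
    out = cupsample(ComplexFeatureMap(z, -z), 2, method="nearest")
    expect = np.repeat(np.repeat(z, 2, axis=1), 2, axis=2)
    np.testing.assert_array_equal(out.real, expect)
    np.testing.assert_array_equal(out.imag, -expect)


def test_init_complex_weights_deterministic_and_glorot_scaled():
    shape = (10, 10, 5, 5)  # 10^4 elements per part
    a = init_complex_weights(shape, seed=7)
    b = init_complex_weights(shape, seed=7)
    np.testing.assert_array_equal(a.real, b.real)
    np.testing.assert_array_equal(a.imag, b.imag)
    c = init_complex_weights(shape, seed=8)
    assert not np.array_equal(a.real, c.real)
    mag2 = a.real ** 2 + a.imag ** 2
    target = glorot_variance(shape)
    assert abs(mag2.mean() - target) / target < 0.10
    assert np.all(a.bias_real_t.data == 0)


def test_complex_gradients_via_finite_differences(fd, rng):
    """cconv2d / crelu / csigmoid are differentiable in each part separately."""
    x0 = random_complex(rng, (1, 4, 4))
    x0 += 0.05 * (np.sign(x0.real) + 1j * np.sign(x0.imag))  # off ReLU kinks
    k0 = random_complex(rng, (1, 1, 3, 3))

    def loss_from(xr):
        inp = ComplexFeatureMap(xr, x0.imag)
        out = csigmoid(crelu(cconv2d(inp, ComplexKernelSet(k0.real, k0.imag))))
        return float((ad.mean(ad.square(out.real_t)) +
                      ad.mean(ad.square(out.imag_t))).data)

    xr = Tensor(x0.real, requires_grad=True)
    inp = ComplexFeatureMap(xr, Tensor(x0.imag))
    out = csigmoid(crelu(cconv2d(inp, ComplexKernelSet(k0.real, k0.imag))))
    (ad.mean(ad.square(out.real_t)) + ad.mean(ad.square(out.imag_t))).backward()
    g_fd = fd(loss_from, x0.real)
    np.testing.assert_allclose(xr.grad, g_fd, rtol=1e-4, atol=1e-7)


def test_feature_map_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape mismatch"):
        ComplexFeatureMap(np.zeros((1, 2, 2)), np.zeros((1, 3, 3)))


def test_kernel_requires_odd_dims():
    with pytest.raises(ValueError, match="odd"):
        ComplexKernelSet(np.zeros((1, 1, 2, 2)), np.zeros((1, 1, 2, 2)))


def test_cmul_is_pointwise_complex_product(rng):
    a = random_complex(rng, (2, 3, 3))
    b = random_complex(rng, (2, 3, 3))
    out = cmul(ComplexFeatureMap(a.real, a.imag),
               ComplexFeatureMap(b.real, b.imag)).to_complex()
    np.testing.assert_allclose(out, a * b, rtol=1e-12)
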