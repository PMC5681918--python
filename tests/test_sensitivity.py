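import numpy as np
import pytest

from atriakur.params import N_PARAMS
from atriakur.sensitivity import (SensitivityError, SensitivitySpec,
                                  pls_coefficients, regress,
                                  sample_population)


def test_sigma_zero_gives_unit_factors():
    spec = SensitivitySpec(n_variants=10, sigma=0.0, subset_size=5)
    assert np.allclose(sample_population(spec), 1.0)


def test_population_shape_and_log_sd():
    spec = SensitivitySpec()  # defaults: 900 x 18, sigma 0.1
    sf = sample_population(spec)
    assert sf.shape == (900, N_PARAMS)
    assert np.log(sf).std(ddof=1) == pytest.approx(0.1, abs=0.005)
    assert np.all(sf > 0)


def test_population_reproducible_for_fixed_seed():
    a = sample_population(SensitivitySpec(seed=42))
    b = sample_population(SensitivitySpec(seed=42))
    assert np.array_equal(a, b)


def _linear_instance(rng, n=400, p=6, q=3):
    x = np.exp(rng.normal(0, 0.1, size=(n, p)))
    beta = rng.normal(0, 1, size=(p, q))
    y = np.exp(np.log(x) @ beta)
    return x, y, beta


def test_exact_linear_model_recovered():
    """Y exactly log-linear in X: full-component PLS recovers the
    standardized ground-truth coefficients to 1e-6."""
    rng = np.random.default_rng(0)
    x, y, beta = _linear_instance(rng)
    lx, ly = np.log(x), np.log(y)
    # standardized truth: beta * sd(x_j) / sd(y_i)
    truth = beta * lx.std(0, ddof=1)[:, None] / ly.std(0, ddof=1)[None, :]
    coef = pls_coefficients(lx, ly)
    assert np.max(np.abs(coef - truth.T)) < 1e-6


def test_full_component_pls_equals_ols():
    """On a well-conditioned instance with noise, full-rank PLS equals the
    ordinary least squares solution."""
    rng = np.random.default_rng(1)
    x, y, _ = _linear_instance(rng)
    ly = np.log(y) + rng.normal(0, 0.05, size=y.shape)
    lx = np.log(x)
    xs = (lx - lx.mean(0)) / lx.std(0, ddof=1)
    ys = (ly - ly.mean(0)) / ly.std(0, ddof=1)
    ols = np.linalg.lstsq(xs, ys, rcond=None)[0]
    coef = pls_coefficients(lx, ly)
    assert np.max(np.abs(coef - ols.T)) < 1e-6


def test_regress_subset_statistics_and_reproducibility():
    rng = np.random.default_rng(2)
    n, p = 300, 5
    x = np.exp(rng.normal(0, 0.1, size=(n, p)))
    beta = np.array([[1.0], [-2.0], [0.5], [0.0], [3.0]])
    y = np.exp(np.log(x) @ beta + rng.normal(0, 0.02, size=(n, 1)))
    spec = SensitivitySpec(n_variants=n, subset_size=100, n_subsets=10,
                           parameters=tuple("abcde"), outputs=("y",),
                           seed=9)
    r1 = regress(x, y, spec, rng=np.random.default_rng(5))
    r2 = regress(x, y, spec, rng=np.random.default_rng(5))
    assert np.array_equal(r1.mean, r2.mean)
    assert np.all(r1.sd >= 0)
    # signs of the recovered sensitivities match the generating model
    signs = np.sign(r1.mean[0])
    assert list(signs[[0, 1, 2, 4]]) == [1.0, -1.0, 1.0, 1.0]
    # larger subsets shrink the across-subset SD
    spec_big = SensitivitySpec(n_variants=n, subset_size=250, n_subsets=10,
                               parameters=tuple("abcde"), outputs=("y",))
    r3 = regress(x, y, spec_big, rng=np.random.default_rng(5))
    assert r3.sd.mean() < r1.sd.mean()


def test_regress_excludes_undefined_rows():
    rng = np.random.default_rng(3)
    n, p = 120, 4
    x = np.exp(rng.normal(0, 0.1, size=(n, p)))
    y = np.exp(np.log(x) @ rng.normal(size=(p, 2)))
    y[:5, 0] = np.nan  # repolarization-failure variants
    spec = SensitivitySpec(n_variants=n, subset_size=50, n_subsets=4,
                           parameters=tuple("abcd"), outputs=("u", "v"))
    res = regress(x, y, spec)
    assert res.n_excluded == 5


def test_regress_error_conditions():
    rng = np.random.default_rng(4)
    x = np.exp(rng.normal(0, 0.1, size=(40, 3)))
    y = np.exp(np.log(x) @ rng.normal(size=(3, 1)))
    spec = SensitivitySpec(n_variants=40, subset_size=39, n_subsets=2,
                           parameters=tuple("abc"), outputs=("y",))
    y_bad = y.copy()
    y_bad[:20] = np.nan
    with pytest.raises(SensitivityError):
        regress(x, y_bad, spec)
    x_deg = x.copy()
    x_deg[:, 1] = 1.0
    with pytest.raises(SensitivityError):
        regress(x_deg, y, spec)
    with pytest.raises(SensitivityError):
        SensitivitySpec(n_variants=10, subset_size=20)
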