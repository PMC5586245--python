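import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saskit.fitting import (
    chi2_fit, cormap_test, fit_mixture, longest_run_pvalue, smear_model,
)
from saskit.profiles import GridMismatchError, Profile
from saskit.synthetic import sphere_intensity


# ------------------------------------------------------------ longest run

def _max_run(bits):
    best = run = 1
    for a, b in zip(bits, bits[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


@pytest.mark.parametrize("n", range(1, 17))
def test_pvalue_matches_exhaustive_enumeration(n):
    """Exact null distribution vs brute force over all 2^n sign strings."""
    counts = np.zeros(n + 1)
    for bits in itertools.product((0, 1), repeat=n):
        counts[_max_run(bits)] += 1
    total = 2 ** n
    for L in range(1, n + 1):
        p_ref = counts[L:].sum() / total
        assert longest_run_pvalue(n, L) == pytest.approx(p_ref, abs=1e-12)


def test_pvalue_trivial_cases():
    assert longest_run_pvalue(10, 1) == 1.0
    assert longest_run_pvalue(10, 10) == pytest.approx(2.0 ** -9)
    with pytest.raises(ValueError):
        longest_run_pvalue(5, 6)
    with pytest.raises(ValueError):
        longest_run_pvalue(0, 1)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(n=st.integers(min_value=2, max_value=400))
def test_pvalue_monotone_in_L(n):
    ps = [longest_run_pvalue(n, L) for L in range(1, n + 1)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))
    assert ps[0] == 1.0


def test_cormap_ties_inherit_previous_sign():
    # diffs: +, 0, 0, + -> run of 4 positives
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([0.5, 2.0, 3.0, 3.5])
    res = cormap_test(a, b)
    assert res.L == 4
    # leading tie counts positive
    res2 = cormap_test(np.array([1.0, 2.0, 1.0]), np.array([1.0, 1.0, 2.0]))
    assert res2.L == 2


def test_cormap_identical_curves():
    a = np.linspace(1, 2, 50)
    res = cormap_test(a, a.copy())
    assert res.L == 50            # all ties -> one positive run
    assert res.p_value == pytest.approx(2.0 ** -49)


def test_cormap_alternating():
    a = np.zeros(20)
    b = np.tile([0.1, -0.1], 10)
    res = cormap_test(a, b)
    assert res.L == 1
    assert res.p_value == 1.0


# -------------------------------------------------------------------- chi^2

def test_chi2_perfect_model():
    q = np.linspace(0.01, 0.3, 50)
    i = np.exp(-q ** 2 * 300)
    p = Profile(q=q, intensity=i, sigma=0.01 * i)
    res = chi2_fit(p, i.copy())
    assert res.chi2 == pytest.approx(0.0, abs=1e-20)
    assert res.c == pytest.approx(1.0)
    assert res.constant is None and res.n_fitted_params == 1


def test_chi2_optimal_scale():
    q = np.linspace(0.01, 0.3, 50)
    i = np.exp(-q ** 2 * 300)
    p = Profile(q=q, intensity=i, sigma=0.01 * i)
    res = chi2_fit(p, 2.0 * i)
    assert res.c == pytest.approx(0.5)
    assert res.chi2 == pytest.approx(0.0, abs=1e-20)


def test_chi2_fitted_constant():
    q = np.linspace(0.01, 0.3, 50)
    model = np.exp(-q ** 2 * 300)
    data = 1.7 * model + 0.05
    p = Profile(q=q, intensity=data, sigma=np.full(50, 0.01))
    res = chi2_fit(p, model, fit_constant=True)
    assert res.c == pytest.approx(1.7, rel=1e-9)
    assert res.constant == pytest.approx(0.05, rel=1e-9)
    assert res.n_fitted_params == 2


def test_chi2_calibration():
    """Correctly propagated Gaussian errors: mean reduced chi^2 over 200
    replicates of N = 500 equals 1.00 within 0.01."""
    rng = np.random.default_rng(2024)
    q = np.linspace(0.01, 0.5, 500)
    model = sphere_intensity(q, 30.0) + 0.01
    sigma = 0.05 * model
    chis = [
        chi2_fit(Profile(q=q, intensity=model + rng.normal(0, sigma), sigma=sigma),
                 model).chi2
        for _ in range(200)
    ]
    assert np.mean(chis) == pytest.approx(1.0, abs=0.01)


def test_chi2_grid_mismatch():
    q = np.linspace(0.01, 0.3, 50)
    p = Profile(q=q, intensity=np.ones(50), sigma=np.full(50, 0.1))
    with pytest.raises(GridMismatchError):
        chi2_fit(p, np.ones(49))
    with pytest.raises(ValueError):
        chi2_fit(p, np.zeros(50))


# ------------------------------------------------------------------ mixtures

def test_mixture_70_30_recovery():
    q = np.linspace(0.01, 0.5, 500)
    c1 = sphere_intensity(q, 20.0)
    c2 = 3.0 * sphere_intensity(q, 45.0)
    mix = 0.7 * c1 + 0.3 * c2
    sigma = 0.01 * mix + 1e-6
    noisy = mix + np.random.default_rng(7).normal(0, sigma)
    p = Profile(q=q, intensity=noisy, sigma=sigma)
    res = fit_mixture(p, [c1, c2])
    assert res.weights[0] == pytest.approx(0.7, rel=0.03)
    assert res.weights[1] == pytest.approx(0.3, rel=0.03)
    assert not res.collinear_warning


def test_mixture_weights_nonnegative():
    q = np.linspace(0.01, 0.5, 100)
    c1 = sphere_intensity(q, 20.0)
    c2 = sphere_intensity(q, 25.0)
    # data are pure component 1; nnls must not go negative on component 2
    p = Profile(q=q, intensity=c1, sigma=0.01 * c1 + 1e-9)
    res = fit_mixture(p, [c1, c2])
    assert np.all(res.weights >= 0)
    assert res.weights[0] == pytest.approx(1.0, rel=1e-6)


def test_mixture_collinear_warning():
    q = np.linspace(0.01, 0.5, 100)
    c1 = sphere_intensity(q, 20.0)
    p = Profile(q=q, intensity=c1, sigma=0.01 * c1 + 1e-9)
    res = fit_mixture(p, [c1, c1 * (1 + 1e-12)])
    assert res.collinear_warning


# ------------------------------------------------------------------ smearing

def test_smear_zero_width_is_identity():
    q = np.linspace(0.01, 0.5, 200)
    i = sphere_intensity(q, 30.0)
    assert np.allclose(smear_model(q, i), i)


def test_smear_constant_invariant():
    q = np.linspace(0.01, 0.5, 200)
    c = np.full(200, 3.3)
    assert np.allclose(smear_model(q, c, sigma_q=0.005), c)


def test_smearing_fills_sharp_minima():
    q = np.linspace(0.01, 0.5, 400)
    i = sphere_intensity(q, 30.0)
    sm = smear_model(q, i, dlambda_over_lambda=0.10)
    j = int(np.argmin(i))
    assert sm[j] > 10 * i[j]
    # forward scattering little affected
    assert sm[0] == pytest.approx(i[0], rel=0.01)


def test_smear_width_monotone():
    """Wider kernels fill the first minimum more."""
    q = np.linspace(0.01, 0.5, 400)
    i = sphere_intensity(q, 30.0)
    j = int(np.argmin(i))
    depths = [smear_model(q, i, dlambda_over_lambda=w)[j]
              for w in (0.01, 0.05, 0.10)]
    assert depths == sorted(depths)
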