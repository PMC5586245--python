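"""Model-versus-data fit statistics.

* reduced chi-square with the analytically optimal multiplicative scale ``c``
  (and an optional fitted additive constant), using the 1/N convention;
* error-weighted residuals [I_exp(q) - c I_mod(q) - const] / sigma(q);
* the longest-run goodness-of-fit statistic with its exact fair-coin null
  distribution (the scalar score behind correlation-map comparisons) --
  error-model independent, so it complements chi-square when uncertainty
  estimates are suspect;
* non-negative mixture decomposition I(q) = sum_k n_k I_k(q);
* forward Gaussian resolution smearing of model curves (data are never
  desmeared; models are smeared to match the instrument).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import nnls

from .profiles import GridMismatchError, Profile

__all__ = [
    "FitResult", "CormapResult", "MixtureResult",
    "chi2_fit", "cormap_test", "longest_run_pvalue", "fit_mixture", "smear_model",
]


@dataclass(frozen=True)
class CormapResult:
    n: int          # points compared
    L: int          # longest run of same-sign differences
    p_value: float  # exact P(longest run >= L) under the fair-coin null


@dataclass(frozen=True)
class FitResult:
    chi2: float                # (1/N) sum of squared weighted residuals
    c: float                   # optimal multiplicative scale
    constant: Optional[float]  # fitted additive constant, or None
    N: int
    n_fitted_params: int       # so readers can convert to other dof conventions
    residuals: np.ndarray      # (I_exp - c I_mod - const) / sigma
    cormap: CormapResult


@dataclass(frozen=True)
class MixtureResult:
    weights: np.ndarray   # non-negative number densities, one per component
    chi2: float
    condition_number: float
    collinear_warning: bool


# ----------------------------------------------------------------------------
# longest-run statistic

@lru_cache(maxsize=None)
def _count_max_run_below(n: int, m: int) -> int:
    """Number of binary strings of length n whose longest run (of either
    symbol) is <= m.  Exact integer arithmetic via the composition recursion:
    a string is a sequence of alternating runs, so the count is
    2 * D(n) where D(n) = number of compositions of n with parts <= m.
    """
    if m <= 0:
        return 0 if n > 0 else 1
    if n == 0:
        return 1
    # D via iterative recursion
    D = [0] * (n + 1)
    D[0] = 1
    for i in range(1, n + 1):
        D[i] = sum(D[i - j] for j in range(1, min(m, i) + 1))
    return 2 * D[n]


def longest_run_pvalue(n: int, L: int) -> float:
    """Exact probability that n fair coin flips contain a run of length >= L.

    p = 1 - (# strings with longest run <= L-1) / 2^n; p(L=1) = 1 and
    p(L=n) = 2^(1-n).
    """
    if n < 1 or L < 1 or L > n:
        raise ValueError("need 1 <= L <= n")
    if L == 1:
        return 1.0
    good = _count_max_run_below(n, L - 1)
    from fractions import Fraction
    return float(1 - Fraction(good, 2 ** n))


def _longest_same_sign_run(diff: np.ndarray) -> int:
    """Longest run of same-sign values; exact zeros inherit the previous
    sign (a first-point zero counts as positive)."""
    signs = np.sign(diff).astype(int)
    prev = 1
    for i, s in enumerate(signs):
        if s == 0:
            signs[i] = prev
        else:
            prev = s
    longest = run = 1
    for i in range(1, len(signs)):
        run = run + 1 if signs[i] == signs[i - 1] else 1
        longest = max(longest, run)
    return longest


def cormap_test(a: np.ndarray, b: np.ndarray) -> CormapResult:
    """Longest same-sign run of (a - b) with its exact fair-coin P-value.

    ``a`` and ``b`` are intensity arrays on the same grid (pass
    ``profile.intensity`` for measured curves).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise GridMismatchError("curves must be 1-D arrays on the same grid")
    n = len(a)
    if n < 1:
        raise ValueError("empty curves")
    L = _longest_same_sign_run(a - b)
    return CormapResult(n=n, L=L, p_value=longest_run_pvalue(n, L))


# ----------------------------------------------------------------------------
# chi-square

def chi2_fit(exp: Profile, model: np.ndarray, fit_constant: bool = False) -> FitResult:
    """Reduced chi-square of a model curve against an experimental profile.

    chi^2 = (1/N) sum_q [ (I_exp(q) - c I_mod(q) - const) / sigma(q) ]^2

    with ``c`` the analytically optimal scale (and ``const`` a jointly fitted
    additive constant when ``fit_constant``).  The 1/N convention matches the
    simple definition most modelling software prints; ``n_fitted_params``
    (1 or 2) is reported so a (N - p) normalization can be recovered.
    """
    model = np.asarray(model, dtype=float)
    if model.shape != exp.q.shape:
        raise GridMismatchError("model curve must be on the experimental q-grid")
    i, s = exp.intensity, exp.sigma
    w = 1.0 / s ** 2
    if not np.any(model != 0):
        raise ValueError("degenerate scale: model is identically zero")
    if fit_constant:
        # weighted LS for I_exp ~ c * I_mod + const
        A = np.column_stack([model, np.ones_like(model)])
        Aw = A * np.sqrt(w)[:, None]
        yw = i * np.sqrt(w)
        coef, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
        c, const = float(coef[0]), float(coef[1])
    else:
        c = float(np.sum(w * i * model) / np.sum(w * model ** 2))
        const = 0.0
    resid = (i - c * model - const) / s
    chi2 = float(np.mean(resid ** 2))
    cm = cormap_test(i, c * model + const)
    return FitResult(
        chi2=chi2, c=c,
        constant=const if fit_constant else None,
        N=len(i), n_fitted_params=2 if fit_constant else 1,
        residuals=resid, cormap=cm,
    )


# ----------------------------------------------------------------------------
# mixtures

def fit_mixture(exp: Profile, components: Sequence[np.ndarray],
                condition_limit: float = 1e8) -> MixtureResult:
    """Non-negative weighted least squares for number densities n_k in
    I_exp(q) = sum_k n_k I_k(q).

    Weights are the usual 1/sigma; a large design condition number sets
    ``collinear_warning`` (near-collinear component curves make the split
    ill-determined even when the combined fit is good).
    """
    comps = [np.asarray(ck, dtype=float) for ck in components]
    if len(comps) < 1:
        raise ValueError("need at least one component")
    for ck in comps:
        if ck.shape != exp.q.shape:
            raise GridMismatchError("component curves must be on the experimental q-grid")
    A = np.column_stack(comps) / exp.sigma[:, None]
    y = exp.intensity / exp.sigma
    weights, _ = nnls(A, y)
    resid = y - A @ weights
    chi2 = float(np.mean(resid ** 2))
    svals = np.linalg.svd(A, compute_uv=False)
    cond = float(svals[0] / svals[-1]) if svals[-1] > 0 else np.inf
    return MixtureResult(
        weights=weights, chi2=chi2,
        condition_number=cond,
        collinear_warning=bool(cond > condition_limit),
    )


# ----------------------------------------------------------------------------
# resolution smearing

def smear_model(
    q: np.ndarray,
    model: np.ndarray,
    sigma_q: Optional[Union[float, np.ndarray]] = None,
    dlambda_over_lambda: float = 0.0,
    n_quad: int = 21,
) -> np.ndarray:
    """Forward Gaussian resolution smearing of a model curve.

    The kernel width at each q combines, in quadrature, a geometric
    contribution ``sigma_q`` (scalar or per-q array) and the wavelength
    spread mapped as sigma = q * (dlambda/lambda) / sqrt(8 ln 2) (FWHM of the
    relative wavelength distribution to a Gaussian sigma in q).  The
    convolution integral uses Gauss-Hermite quadrature with the model linearly
    interpolated and reflected about q = 0.
    """
    q = np.asarray(q, dtype=float)
    model = np.asarray(model, dtype=float)
    if sigma_q is None:
        sig_geo = np.zeros_like(q)
    else:
        sig_geo = np.broadcast_to(np.asarray(sigma_q, dtype=float), q.shape).copy()
    sig_wl = q * dlambda_over_lambda / np.sqrt(8.0 * np.log(2.0))
    sig = np.sqrt(sig_geo ** 2 + sig_wl ** 2)
    if np.all(sig == 0):
        return model.copy()
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    weights = weights / np.sqrt(np.pi)
    # evaluate model at q + sqrt(2) sigma x, reflecting negative arguments
    qq = q[:, None] + np.sqrt(2.0) * sig[:, None] * nodes[None, :]
    qq = np.abs(qq)
    vals = np.interp(qq, q, model)  # constant extrapolation beyond the grid
    return vals @ weights
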