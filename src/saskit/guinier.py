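"""Guinier analysis: weighted linear fit of ln I(q) versus q^2.

At low q a monodisperse particle obeys I(q) = I(0) exp(-q^2 Rg^2 / 3), so a
plot of ln I against q^2 is linear with slope -Rg^2/3 and intercept ln I(0).
For a globular particle the linear approximation holds out to roughly
q*Rg < 1.3; for elongated or inhomogeneous particles the usable window is
shorter.  The fit here is weighted with (I/sigma)^2, i.e. with the first-order
propagated error of ln I, sigma_lnI = sigma/I.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .profiles import Profile

__all__ = ["GuinierResult", "guinier_fit", "auto_guinier_range"]

QRG_LIMIT_GLOBULAR = 1.3


class GuinierError(ValueError):
    pass


@dataclass(frozen=True)
class GuinierResult:
    """Radius of gyration and forward scattering from a Guinier fit."""

    Rg: float
    Rg_err: float
    I0: float
    I0_err: float
    q_range: Tuple[float, float]       # q window actually used
    qRg_window: Tuple[float, float]    # (q_min*Rg, q_max*Rg)
    r2: float                          # coefficient of correlation of ln I vs q^2
    n_points: int
    n_truncated_low: int = 0
    qmin_adequate: Optional[bool] = None  # q_min <= pi/d_max check, when d_max known

    def check_qmin_adequacy(self, dmax: float) -> bool:
        """True when the lowest fitted q is below ~pi/d_max, the minimum
        needed to characterize the largest dimension of the particle."""
        return self.q_range[0] <= np.pi / dmax


def _weighted_linfit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares y = a + b x; returns a, b, var_a, var_b, r2."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    sxy = np.sum(w * (x - xm) * (y - ym))
    b = sxy / sxx
    a = ym - b * xm
    n = len(x)
    resid = y - (a + b * x)
    # unbiased residual variance scale on the weighted problem
    dof = max(n - 2, 1)
    s2 = np.sum(w * resid ** 2) / dof
    var_b = s2 / sxx
    var_a = s2 * (1.0 / W + xm ** 2 / sxx)
    syy = np.sum(w * (y - ym) ** 2)
    r2 = 1.0 - np.sum(w * resid ** 2) / syy if syy > 0 else 1.0
    return a, b, var_a, var_b, max(min(r2, 1.0), 0.0)


def guinier_fit(profile: Profile, q_range: Tuple[float, float],
                n_truncated_low: int = 0) -> GuinierResult:
    """Weighted Guinier fit over ``q_range = (q_low, q_high)``.

    Raises
    ------
    GuinierError
        If fewer than 3 points fall in the window, any intensity in the
        window is non-positive, or the fitted slope is non-negative (no
        Guinier decay).
    """
    qlo, qhi = q_range
    m = (profile.q >= qlo) & (profile.q <= qhi)
    if m.sum() < 3:
        raise GuinierError("need at least 3 points in the Guinier window")
    q = profile.q[m]
    i = profile.intensity[m]
    s = profile.sigma[m]
    if np.any(i <= 0):
        raise GuinierError("non-positive intensity inside the Guinier window")
    x = q ** 2
    y = np.log(i)
    w = (i / s) ** 2  # 1 / sigma_lnI^2
    a, b, var_a, var_b, r2 = _weighted_linfit(x, y, w)
    if b >= 0:
        raise GuinierError("no Guinier decay: fitted slope is non-negative")
    Rg = float(np.sqrt(-3.0 * b))
    # Rg = sqrt(-3 b)  =>  dRg/db = -3 / (2 Rg)
    Rg_err = float(1.5 * np.sqrt(var_b) / Rg)
    I0 = float(np.exp(a))
    I0_err = float(I0 * np.sqrt(var_a))
    return GuinierResult(
        Rg=Rg, Rg_err=Rg_err, I0=I0, I0_err=I0_err,
        q_range=(float(q[0]), float(q[-1])),
        qRg_window=(float(q[0] * Rg), float(q[-1] * Rg)),
        r2=float(r2), n_points=int(m.sum()),
        n_truncated_low=n_truncated_low,
    )


def auto_guinier_range(
    profile: Profile,
    qrg_limit: float = QRG_LIMIT_GLOBULAR,
    mask_low: int = 0,
    rg_tol: float = 1e-3,
    max_iter: int = 50,
) -> Tuple[Tuple[float, float], GuinierResult]:
    """Self-consistent Guinier window: iterate the fit, each time truncating
    the window at the largest q with q*Rg <= qrg_limit, until Rg is stable
    to ``rg_tol`` (0.1%).

    ``mask_low`` excludes that many leading points (user-declared truncation,
    e.g. for a low-q aggregate upturn); the count is surfaced on the result
    as ``n_truncated_low`` so that reports can state it.

    Returns ``(q_range, GuinierResult)``.
    """
    q = profile.q
    if mask_low < 0 or mask_low > len(q) - 3:
        raise ValueError("mask_low leaves fewer than 3 points")
    qmin = q[mask_low]
    # initial window: first 10 usable points (or all, if fewer)
    hi0 = q[min(mask_low + 9, len(q) - 1)]
    result = guinier_fit(profile, (qmin, hi0), n_truncated_low=mask_low)
    seen = set()
    for _ in range(max_iter):
        qmax_target = qrg_limit / result.Rg
        usable = q[(q >= qmin) & (q <= qmax_target)]
        if len(usable) < 3:
            raise GuinierError("self-consistent window has fewer than 3 points")
        new = guinier_fit(profile, (qmin, usable[-1]), n_truncated_low=mask_low)
        if abs(new.Rg - result.Rg) <= rg_tol * result.Rg:
            return (qmin, usable[-1]), new
        # the discrete cutoff can cycle between adjacent windows whose Rg
        # values straddle the tolerance; revisiting a window ends the cycle
        if len(usable) in seen:
            return (qmin, usable[-1]), new
        seen.add(len(usable))
        result = new
    raise GuinierError(f"no self-consistent Guinier window after {max_iter} iterations")
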