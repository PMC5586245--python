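"""Kratky-family transforms and qualitative flexibility diagnostics.

The dimensionless Kratky plot, (q Rg)^2 I(q)/I(0) versus q Rg, separates
degrees of folding on a shape- and size-normalized axis: folded globular
particles show a bell with a maximum of about 1.1 near q Rg = 1.75 (for the
pure Guinier law the maximum is exactly 3/e at q Rg = sqrt(3)), elongation
shifts the peak up and right, and chain-like flexibility raises the high-qRg
tail (a Gaussian coil plateaus at 2).  The plain Kratky (q^2 I vs q) and
Porod-Debye (q^4 I vs q^4) transforms carry the same information in
non-normalized form; a Porod-Debye plateau indicates a well-defined particle
boundary (q^-4 decay).

Flags produced here are advisory strings for the report, never hard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .profiles import Profile

__all__ = ["TransformCurve", "transform", "flexibility_flags", "DIMLESS_KRATKY_PEAK_GUINIER"]

# exact peak of x^2 exp(-x^2/3): at x = sqrt(3), value 3/e
DIMLESS_KRATKY_PEAK_GUINIER = (np.sqrt(3.0), 3.0 / np.e)

_KINDS = ("kratky", "dimensionless_kratky", "porod_debye", "log_log")


@dataclass
class TransformCurve:
    x: np.ndarray
    y: np.ndarray
    kind: str
    peak: Optional[Tuple[float, float]] = None     # (x*, y*) for dimensionless Kratky
    plateau: Optional[float] = None                # high-q^4 plateau for Porod-Debye
    secondary_oscillation: bool = False


def _quadratic_peak(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Global maximum refined by a parabola through the three bracketing
    points; falls back to the discrete maximum at the edges."""
    j = int(np.argmax(y))
    if j == 0 or j == len(y) - 1:
        return float(x[j]), float(y[j])
    x0, x1, x2 = x[j - 1], x[j], x[j + 1]
    y0, y1, y2 = y[j - 1], y[j], y[j + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 ** 2 * (y0 - y1) + x1 ** 2 * (y2 - y0) + x0 ** 2 * (y1 - y2)) / denom
    if a >= 0:
        return float(x1), float(y1)
    xs = -b / (2 * a)
    c = y1 - a * x1 ** 2 - b * x1
    return float(xs), float(a * xs ** 2 + b * xs + c)


def transform(profile: Profile, kind: str,
              Rg: Optional[float] = None, I0: Optional[float] = None) -> TransformCurve:
    """Compute one of the standard flexibility transforms.

    ``dimensionless_kratky`` requires Rg and I0 (typically from the Guinier
    or P(r) analysis); the peak is located by quadratic interpolation through
    the three points bracketing the discrete maximum.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown transform kind {kind!r}")
    q, i = profile.q, profile.intensity
    if kind == "kratky":
        x, y = q, q ** 2 * i
    elif kind == "dimensionless_kratky":
        if Rg is None or I0 is None or Rg <= 0 or I0 <= 0:
            raise ValueError("dimensionless Kratky requires positive Rg and I0")
        x = q * Rg
        y = x ** 2 * i / I0
    elif kind == "porod_debye":
        x, y = q ** 4, q ** 4 * i
    else:  # log_log
        ok = i > 0
        x, y = np.log10(q[ok]), np.log10(i[ok])
    finite = np.isfinite(x) & np.isfinite(y)
    x, y = x[finite], y[finite]
    curve = TransformCurve(x=x, y=y, kind=kind)
    if kind == "dimensionless_kratky":
        xs, ys = _quadratic_peak(x, y)
        interior = 0 < np.argmax(y) < len(y) - 1
        curve.peak = (xs, ys) if interior else None
        if curve.peak:
            # shallow secondary extremum beyond the main peak (resolved domains)
            beyond = y[x > xs + 0.5]
            if len(beyond) > 4:
                d = np.diff(beyond)
                curve.secondary_oscillation = bool(np.any(d[:-1] * d[1:] < 0))
    if kind == "porod_debye":
        # plateau: mean of the last quarter, accepted only if the tail is
        # both flat (scatter < 20% of the level) and trend-free (linear
        # drift across the window < 20% of the level) — a Gaussian coil's
        # q^4 I rises steadily yet can have modest scatter, so the trend
        # criterion is essential
        tail = y[-max(len(y) // 4, 3):]
        xt = x[-len(tail):]
        level = float(np.mean(tail))
        if level > 0 and np.std(tail) < 0.2 * level:
            slope = float(np.polyfit(xt, tail, 1)[0])
            if abs(slope * (xt[-1] - xt[0])) < 0.2 * level:
                curve.plateau = level
    return curve


def flexibility_flags(
    curve: TransformCurve,
    globular_x_window: Tuple[float, float] = (1.5, 2.2),
    globular_y_window: Tuple[float, float] = (0.9, 1.3),
    tail_start: float = 6.0,
) -> dict:
    """Advisory shape/flexibility flags from a dimensionless Kratky curve.

    * ``globular``: interior peak with x* in [1.5, 2.2] and y* in [0.9, 1.3]
      (the folded-protein bell, ~1.1 at qRg ~ 1.75);
    * ``flexible_tail``: mean positive slope beyond q Rg = 6, the rise that
      signals chain-like flexibility;
    * ``secondary_oscillation``: recorded, not thresholded (multi-domain
      particles show a shallow oscillation past the bell).
    """
    if curve.kind != "dimensionless_kratky":
        raise ValueError("flexibility flags are defined on the dimensionless Kratky curve")
    flags = {"globular": False, "flexible_tail": False,
             "secondary_oscillation": curve.secondary_oscillation}
    if curve.peak is not None:
        xs, ys = curve.peak
        flags["globular"] = (globular_x_window[0] <= xs <= globular_x_window[1]
                             and globular_y_window[0] <= ys <= globular_y_window[1])
    tail = curve.x >= tail_start
    if tail.sum() >= 3:
        slope = np.polyfit(curve.x[tail], curve.y[tail], 1)[0]
        flags["flexible_tail"] = bool(slope > 0)
    return flags
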