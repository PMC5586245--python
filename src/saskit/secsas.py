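"""SEC-SAS frame processing: per-frame traces, buffer/sample frame selection,
averaging and subtraction.

With scattering collected continuously on a size-exclusion eluate, the batch
concentration series is replaced by frame selection: buffer frames are taken
from a window away from the elution peak, sample frames from a contiguous
window around the I(0) maximum where the per-frame Rg is stable.  Frame
compatibility is judged two ways at once: Rg agreement within combined
standard errors, and the longest-run (correlation-map) test applied to every
frame pair, with a Bonferroni-adjusted significance threshold because many
pairs are tested.  Selected frames are averaged (inverse-variance style
uncertainty reduction ~ 1/sqrt(N)) and subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fitting import cormap_test
from .guinier import GuinierError, auto_guinier_range
from .profiles import FrameSeries, Profile, subtract_solvent

__all__ = [
    "FrameSelection", "frame_traces", "select_frames", "average_frames",
    "concentration_trace", "estimate_uv_delay",
]


class SelectionError(RuntimeError):
    pass


@dataclass
class FrameSelection:
    mode: str
    indices: list
    averaged: Profile
    criteria_log: dict


def frame_traces(series: FrameSeries, solvent_estimate: Profile,
                 qrg_limit: float = 1.3) -> pd.DataFrame:
    """Per-frame I(0) and Rg via solvent subtraction + auto-Guinier fit.

    Frames where the fit fails (no decay, negative intensities: e.g. pure
    baseline frames) appear as NaN gaps, not errors.
    """
    rows = []
    for idx, frame in enumerate(series.frames):
        sub, _ = subtract_solvent(frame, solvent_estimate)
        try:
            _, res = auto_guinier_range(sub, qrg_limit=qrg_limit)
            rows.append({"frame": idx, "time": series.times[idx],
                         "I0": res.I0, "I0_err": res.I0_err,
                         "Rg": res.Rg, "Rg_err": res.Rg_err, "r2": res.r2})
        except (GuinierError, ValueError):
            rows.append({"frame": idx, "time": series.times[idx],
                         "I0": np.nan, "I0_err": np.nan,
                         "Rg": np.nan, "Rg_err": np.nan, "r2": np.nan})
    return pd.DataFrame(rows).set_index("frame")


def average_frames(series: FrameSeries, indices: Sequence[int]) -> Profile:
    """Mean intensity of the chosen frames with sigma = rms(sigma)/sqrt(N)
    (frames are independent measurements of the same curve)."""
    idx = list(indices)
    if not idx:
        raise ValueError("no frames to average")
    I = np.array([series.frames[i].intensity for i in idx])
    S = np.array([series.frames[i].sigma for i in idx])
    n = len(idx)
    f0 = series.frames[idx[0]]
    return Profile(
        q=series.q, intensity=I.mean(axis=0),
        sigma=np.sqrt((S ** 2).mean(axis=0) / n),
        scale=f0.scale, calibration=f0.calibration,
        meta={"averaged_frames": idx},
    )


def _pairwise_cormap_ok(series: FrameSeries, idx: Sequence[int], alpha: float,
                        scale: bool = False):
    """All-pairs longest-run compatibility with Bonferroni adjustment:
    each pair must have p >= alpha / n_pairs.

    With ``scale`` the second curve of each pair is multiplied by the
    weighted-least-squares optimal factor first, making the test sensitive to
    shape only.  Sample-mode selection uses this (concentration varies across
    an elution peak while the particle shape must not); buffer-mode selection
    compares raw frames so that baseline level drift is still detected.
    """
    idx = list(idx)
    n_pairs = len(idx) * (len(idx) - 1) // 2
    if n_pairs == 0:
        return True, 1.0
    thresh = alpha / n_pairs
    pmin = 1.0
    for a in range(len(idx)):
        ia = series.frames[idx[a]].intensity
        wa = 1.0 / series.frames[idx[a]].sigma ** 2
        for b in range(a + 1, len(idx)):
            ib = series.frames[idx[b]].intensity
            if scale:
                c = float(np.sum(wa * ia * ib) / np.sum(wa * ib ** 2))
                ib = c * ib
            p = cormap_test(ia, ib).p_value
            pmin = min(pmin, p)
            if p < thresh:
                return False, pmin
    return True, pmin


def select_frames(
    series: FrameSeries,
    traces: pd.DataFrame,
    mode: str,
    alpha: float = 0.01,
    buffer_side: str = "pre",
    min_frames: int = 5,
    max_frames: int = 50,
    peak_frame: Optional[int] = None,
    rg_tol_frac: float = 0.01,
    buffer: Optional[Profile] = None,
) -> FrameSelection:
    """Choose buffer or sample frames.

    buffer mode
        Longest window of up to ``max_frames`` frames on the chosen side of
        the elution peak (``buffer_side`` = "pre" or "post"; never
        auto-switched) whose frames are pairwise compatible under the
        longest-run test at the Bonferroni-adjusted level.
    sample mode
        Contiguous window grown symmetrically around the I(0) maximum while
        (a) every frame's Rg stays within its combined standard error of the
        window mean and (b) the pairwise longest-run test passes.  The
        per-frame automatic Guinier window length changes discretely from
        frame to frame, which for compact particles moves the fitted Rg by
        of order 1% — a systematic jitter the statistical errors do not
        cover — so ``rg_tol_frac`` (fraction of the window-mean Rg) is added
        in quadrature to the combined standard error.  Pass the averaged
        buffer profile as ``buffer``: pairwise compatibility is then judged
        on buffer-subtracted frames, where an optimal scale factor removes
        concentration differences exactly — on raw frames the constant
        solvent background makes concentration steps across the peak look
        like shape changes.
    """
    if mode not in ("buffer", "sample"):
        raise ValueError("mode must be 'buffer' or 'sample'")
    i0 = traces["I0"].to_numpy()
    if peak_frame is None:
        if np.all(np.isnan(i0)):
            raise SelectionError("no usable I0 trace to locate the elution peak")
        peak_frame = int(np.nanargmax(i0))

    if mode == "buffer":
        if buffer_side == "pre":
            candidates = list(range(0, peak_frame))
        elif buffer_side == "post":
            candidates = list(range(peak_frame + 1, len(series)))
        else:
            raise ValueError("buffer_side must be 'pre' or 'post'")
        # walk outward from the end farthest from the peak
        if buffer_side == "pre":
            candidates = candidates[:max_frames]
        else:
            candidates = candidates[-max_frames:]
        # shrink from the peak-adjacent side until pairwise compatible
        window = list(candidates)
        while len(window) >= min_frames:
            ok, pmin = _pairwise_cormap_ok(series, window, alpha)
            if ok:
                avg = average_frames(series, window)
                return FrameSelection(
                    mode="buffer", indices=window, averaged=avg,
                    criteria_log={"alpha": alpha, "side": buffer_side,
                                  "min_pairwise_p": pmin, "peak_frame": peak_frame},
                )
            window = window[:-1] if buffer_side == "pre" else window[1:]
        raise SelectionError(
            f"no pairwise-compatible {buffer_side}-peak buffer window of >= {min_frames} frames; "
            f"inspect the frame traces for drift")

    # sample mode
    rg = traces["Rg"].to_numpy()
    rg_err = traces["Rg_err"].to_numpy()
    if buffer is not None:
        cmp_series = FrameSeries(
            frames=[subtract_solvent(f, buffer)[0] for f in series.frames],
            times=series.times)
    else:
        cmp_series = series
    window = [peak_frame]

    def rg_stable(win):
        vals, errs = rg[win], rg_err[win]
        if np.any(np.isnan(vals)):
            return False
        mean = np.average(vals, weights=1.0 / np.clip(errs, 1e-12, None) ** 2)
        scatter = np.sqrt(errs ** 2 + (np.sum(errs ** -2) ** -1)
                          + (rg_tol_frac * mean) ** 2)
        return bool(np.all(np.abs(vals - mean) <= scatter))

    improved = True
    while improved and len(window) < max_frames:
        improved = False
        for cand in (window[0] - 1, window[-1] + 1):
            if cand < 0 or cand >= len(series):
                continue
            trial = sorted(set(window + [cand]))
            if not rg_stable(trial):
                continue
            ok, _ = _pairwise_cormap_ok(cmp_series, trial, alpha, scale=True)
            if ok:
                window = trial
                improved = True
    if len(window) < min_frames:
        raise SelectionError(
            f"stable sample window around frame {peak_frame} has only {len(window)} frames "
            f"(minimum {min_frames}); Rg trace: {rg[max(0, peak_frame-5):peak_frame+6]}")
    ok, pmin = _pairwise_cormap_ok(cmp_series, window, alpha, scale=True)
    avg = average_frames(series, window)
    return FrameSelection(
        mode="sample", indices=window, averaged=avg,
        criteria_log={"alpha": alpha, "min_pairwise_p": pmin, "peak_frame": peak_frame,
                      "rg_window_mean": float(np.nanmean(rg[window]))},
    )


def concentration_trace(
    a280: np.ndarray,
    path_cm: float,
    epsilon: float,
    delay: float = 0.0,
    frame_times: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Concentration (mg/ml) from a UV A280 trace.

    C = A280 / (path_cm * epsilon) with epsilon the 0.1% (w/v) extinction
    coefficient for a 1 cm path (a 0.31 cm cell therefore multiplies the
    absorbance by 3.22 before dividing by epsilon).  ``delay`` shifts the UV
    time base forward onto the SAS frame clock; with ``frame_times`` given,
    the trace is interpolated onto the frames and returned as C(frame).
    """
    a280 = np.asarray(a280, dtype=float)
    if path_cm <= 0 or epsilon <= 0:
        raise ValueError("path length and extinction coefficient must be positive")
    t = a280[:, 0] + delay
    c = a280[:, 1] / (path_cm * epsilon)
    if frame_times is None:
        return np.column_stack([t, c])
    return np.interp(np.asarray(frame_times, dtype=float), t, c)


def estimate_uv_delay(
    series: FrameSeries,
    traces: pd.DataFrame,
    delay_grid: Optional[np.ndarray] = None,
) -> float:
    """Estimate the UV-to-SAS time offset by maximizing the correlation of
    the interpolated A280 trace with the per-frame I(0) trace."""
    if series.a280 is None:
        raise ValueError("series has no UV trace")
    i0 = traces["I0"].to_numpy()
    ok = np.isfinite(i0)
    if ok.sum() < 5:
        raise ValueError("too few usable I0 values to align the UV trace")
    if delay_grid is None:
        dt = np.median(np.diff(series.times))
        delay_grid = np.arange(-20, 21) * dt
    best, best_corr = 0.0, -np.inf
    for d in delay_grid:
        a = np.interp(series.times[ok], series.a280[:, 0] + d, series.a280[:, 1])
        if np.std(a) == 0:
            continue
        corr = np.corrcoef(a, i0[ok])[0, 1]
        if corr > best_corr:
            best, best_corr = float(d), corr
    return best
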