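"""One-dimensional scattering profiles: data model, ASCII I/O, scaling and
solvent subtraction.

A reduced solution scattering measurement is a table of momentum transfer
``q = 4 pi sin(theta) / lambda`` (in inverse Angstrom), intensity ``I(q)``
(in 1/cm when calibrated to an absolute standard such as pure water, otherwise
on an arbitrary scale) and the one-standard-error uncertainty ``sigma(q)``.
All downstream analyses in this package assume this container.

Conventions enforced here and relied on elsewhere:

* q is strictly increasing and positive, in 1/Angstrom (files in 1/nm are
  accepted through an explicit ``units="nm"`` flag that divides q by 10);
* sigma is always one standard error -- reduction pipelines that emit 2-sigma
  errors are handled by the ``sigma_is_2x`` dialect at read time;
* no silent regridding: pointwise operations between two profiles require
  identical q-grids and raise otherwise, because the fit statistics assume
  pointwise correspondence;
* rows dropped during reading (non-finite values) are counted and reported,
  never silently discarded.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Profile",
    "FrameSeries",
    "SubtractionReport",
    "GridMismatchError",
    "ProfileFormatError",
    "read_profile",
    "write_profile",
    "rescale",
    "subtract_solvent",
]


class ProfileFormatError(ValueError):
    """Raised when a profile file cannot be parsed as (q, I, sigma) columns."""


class GridMismatchError(ValueError):
    """Raised when two profiles expected to share a q-grid do not."""


@dataclass(frozen=True)
class Profile:
    """A reduced 1D scattering curve with 1-standard-error uncertainties.

    Parameters
    ----------
    q : array
        Momentum transfer in 1/Angstrom, strictly increasing and positive.
    intensity : array
        I(q); 1/cm when ``scale == "absolute"``, otherwise arbitrary units.
    sigma : array
        One standard error on the intensity, same units.
    scale : {"absolute", "arbitrary"}
    calibration : str, optional
        Provenance of the absolute scale (e.g. "1 mm pure H2O"); required
        when scale is absolute.
    meta : dict
        Optional acquisition metadata (wavelength [A], dlambda_over_lambda,
        exposure [s], temperature [C], path_length [mm], instrument, ...).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    scale: str = "arbitrary"
    calibration: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "sigma", s)
        if not (q.ndim == 1 and q.shape == i.shape == s.shape):
            raise ValueError("q, intensity and sigma must be 1-D arrays of equal length")
        if len(q) < 3:
            raise ValueError("a profile needs at least 3 points")
        if not np.all(q > 0):
            raise ValueError("q must be positive")
        if not np.all(np.diff(q) > 0):
            raise ValueError("q must be strictly increasing")
        finite = np.isfinite(i)
        if np.any(s[finite] <= 0):
            raise ValueError("sigma must be > 0 wherever intensity is finite")
        if self.scale not in ("absolute", "arbitrary"):
            raise ValueError("scale must be 'absolute' or 'arbitrary'")
        if self.scale == "absolute" and not self.calibration:
            raise ValueError("absolute scale requires a calibration provenance string")

    def __len__(self) -> int:
        return len(self.q)

    def same_grid(self, other: "Profile", rtol: float = 1e-8) -> bool:
        return len(self) == len(other) and np.allclose(self.q, other.q, rtol=rtol, atol=0)

    def crop(self, qmin: float = 0.0, qmax: float = np.inf) -> "Profile":
        """Return the sub-profile with qmin <= q <= qmax."""
        m = (self.q >= qmin) & (self.q <= qmax)
        if m.sum() < 3:
            raise ValueError("cropped profile would have fewer than 3 points")
        return replace(self, q=self.q[m], intensity=self.intensity[m], sigma=self.sigma[m])


@dataclass
class FrameSeries:
    """Time-ordered scattering frames on one shared q-grid.

    ``a280`` is an optional UV absorbance trace on its own time base;
    ``alignment`` is the time offset (s) between the UV and SAS measurement
    points (UV leads SAS by ``alignment`` seconds).
    """

    frames: list
    times: np.ndarray
    a280: Optional[np.ndarray] = None  # shape (n, 2): time [s], absorbance
    alignment: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != len(self.times):
            raise ValueError("one timestamp per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        q0 = self.frames[0].q
        for f in self.frames[1:]:
            if not (len(f.q) == len(q0) and np.allclose(f.q, q0)):
                raise GridMismatchError("all frames must share one q-grid")
        if self.a280 is not None:
            self.a280 = np.asarray(self.a280, dtype=float)
            if self.a280.ndim != 2 or self.a280.shape[1] != 2:
                raise ValueError("a280 must be an (n, 2) array of (time, absorbance)")

    @property
    def q(self) -> np.ndarray:
        return self.frames[0].q

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class SubtractionReport:
    """Record of a solvent subtraction: the ad hoc constant and its size
    relative to the mean solvent level.  ``flagged`` is True when the
    constant exceeds 1% of the solvent scattering level, the point at which
    the guidelines call the correction unduly large."""

    constant: float
    mean_solvent_intensity: float
    ratio_to_solvent: float
    flagged: bool


def _parse_columns(text: str):
    rows = []
    n_bad = 0
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.replace(",", " ").split()
        try:
            vals = [float(p) for p in parts[:3]]
        except ValueError:
            # tolerate stray non-numeric trailer lines (common in beamline output)
            n_bad += 1
            continue
        if len(vals) < 3:
            raise ProfileFormatError("profile files need at least 3 numeric columns (q, I, sigma)")
        rows.append(vals)
    if not rows:
        raise ProfileFormatError("no numeric data rows found")
    return np.array(rows, dtype=float), n_bad


def _parse_header_meta(text: str) -> dict:
    meta = {}
    for line in text.splitlines():
        s = line.strip()
        if not s.startswith("#"):
            continue
        body = s.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            key = key.strip()
            val = val.strip()
            if key:
                try:
                    meta[key] = float(val)
                except ValueError:
                    meta[key] = val
    return meta


def read_profile(
    path,
    dialect: str = "plain3col",
    units: str = "angstrom",
    scale: str = "arbitrary",
    calibration: Optional[str] = None,
) -> Profile:
    """Read a 3-column ASCII profile (q, I, sigma).

    Parameters
    ----------
    dialect : {"plain3col", "sigma_is_2x"}
        ``sigma_is_2x`` halves the third column, for reduction software that
        reports errors as twice the standard error.
    units : {"angstrom", "nm"}
        q unit of the file; 1/nm values are divided by 10.
    """
    if dialect not in ("plain3col", "sigma_is_2x"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if units not in ("angstrom", "nm"):
        raise ValueError(f"unknown q units {units!r}")
    with open(path, "r") as fh:
        text = fh.read()
    data, _ = _parse_columns(text)
    meta = _parse_header_meta(text)
    q, i, s = data[:, 0], data[:, 1], data[:, 2]
    finite = np.isfinite(q) & np.isfinite(i) & np.isfinite(s)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("read_profile(%s): dropped %d non-finite rows", path, n_dropped)
    q, i, s = q[finite], i[finite], s[finite]
    if units == "nm":
        q = q / 10.0
    if dialect == "sigma_is_2x":
        s = s / 2.0
    if not np.all(np.diff(q) > 0):
        raise ValueError(f"{path}: q column is not strictly increasing")
    meta["n_dropped_rows"] = n_dropped
    meta.setdefault("source_path", str(path))
    return Profile(q=q, intensity=i, sigma=s, scale=scale, calibration=calibration, meta=meta)


def write_profile(profile: Profile, path) -> None:
    """Write the 3-column ASCII format with a '#'-prefixed key: value header.

    Six significant digits; a written file reads back bit-stably at that
    precision.
    """
    buf = io.StringIO()
    buf.write("# saskit profile\n")
    buf.write(f"# scale: {profile.scale}\n")
    if profile.calibration:
        buf.write(f"# calibration: {profile.calibration}\n")
    for key, val in profile.meta.items():
        if key in ("source_path",):
            continue
        buf.write(f"# {key}: {val}\n")
    buf.write("# columns: q[1/A] I sigma\n")
    for q, i, s in zip(profile.q, profile.intensity, profile.sigma):
        buf.write(f"{q:.6e} {i:.6e} {s:.6e}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def rescale(profile: Profile, factor: float, provenance: str = "") -> Profile:
    """Multiply intensity and sigma by ``factor``.

    When ``provenance`` names a calibration standard (mentions water, H2O or
    glassy carbon) the result is marked absolute-scaled with that provenance.
    """
    if not factor > 0:
        raise ValueError("rescale factor must be positive")
    i = profile.intensity * factor
    s = profile.sigma * factor
    meta = dict(profile.meta)
    if provenance:
        meta.setdefault("rescale_history", [])
        meta["rescale_history"] = list(meta["rescale_history"]) + [(factor, provenance)]
    names_standard = any(
        tok in provenance.lower() for tok in ("h2o", "water", "glassy carbon", "srm 3600")
    )
    if names_standard:
        return Profile(q=profile.q, intensity=i, sigma=s, scale="absolute",
                       calibration=provenance, meta=meta)
    return replace(profile, intensity=i, sigma=s, meta=meta)


def subtract_solvent(
    sample: Profile,
    solvent: Profile,
    constant: float = 0.0,
    flag_fraction: float = 0.01,
):
    """Pointwise solvent subtraction with error propagation.

    Returns ``(Profile, SubtractionReport)`` where the profile carries
    ``I = I_sample - I_solvent - constant`` and
    ``sigma = sqrt(sigma_sample^2 + sigma_solvent^2)``.  The report records
    the ad hoc constant and flags it when its magnitude exceeds
    ``flag_fraction`` (default 1%) of the mean solvent intensity.
    """
    if not sample.same_grid(solvent):
        raise GridMismatchError(
            "sample and solvent q-grids differ; regrid explicitly before subtracting"
        )
    i = sample.intensity - solvent.intensity - constant
    s = np.sqrt(sample.sigma ** 2 + solvent.sigma ** 2)
    mean_solvent = float(np.mean(np.abs(solvent.intensity)))
    ratio = abs(constant) / mean_solvent if mean_solvent > 0 else np.inf if constant else 0.0
    report = SubtractionReport(
        constant=float(constant),
        mean_solvent_intensity=mean_solvent,
        ratio_to_solvent=float(ratio),
        flagged=bool(ratio > flag_fraction),
    )
    meta = dict(sample.meta)
    meta["subtraction_constant"] = float(constant)
    out = Profile(
        q=sample.q, intensity=i, sigma=s,
        scale=sample.scale if sample.scale == solvent.scale else "arbitrary",
        calibration=sample.calibration if sample.scale == "absolute" else None,
        meta=meta,
    )
    return out, report
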