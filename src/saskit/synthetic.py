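"""Synthetic scattering data with exact ground truth.

Analytic, orientationally averaged form factors for a handful of reference
bodies (uniform sphere, ellipsoid of revolution, two-sphere dumbbell, Gaussian
coil, pure Guinier law), with optional realistic corruptions:

* Percus-Yevick hard-sphere structure factor (interparticle interference),
* a constant solvent-mismatch offset,
* an admixed aggregate component (mass fraction with a size multiplier),
* Gaussian resolution smearing,
* counting noise: sigma(q) = I(q)/sqrt(counts(q)) with counts scaled so the
  requested mean count is reached at q_min; the perturbation is Gaussian with
  that sigma (an optional flag draws genuinely Poisson counts instead).

Every generated profile comes with a truth record (exact Rg, d_max, volume,
I(0)) so recovery can be asserted quantitatively, and the same seed + spec
always reproduces the same bytes.

A small SEC elution simulator builds frame series from these components with
Gaussian concentration profiles, a solvent baseline (optionally drifting) and
a UV A280 trace offset by a configurable delay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .profiles import FrameSeries, Profile

__all__ = [
    "SyntheticSpec", "TruthRecord", "generate",
    "sphere_intensity", "ellipsoid_intensity", "dumbbell_intensity",
    "debye_coil_intensity", "guinier_intensity", "sphere_pr",
    "hard_sphere_structure_factor",
    "ElutionComponent", "simulate_sec_run",
]

AVOGADRO = 6.02214076e23


# ----------------------------------------------------------------------------
# form factors (normalized so the shape factor is 1 at q = 0)

def _sphere_amplitude(x: np.ndarray) -> np.ndarray:
    """3 (sin x - x cos x) / x^3, -> 1 as x -> 0."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-8
    xs = x[nz]
    out[nz] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs ** 3
    return out


def sphere_intensity(q: np.ndarray, radius: float) -> np.ndarray:
    """Normalized intensity of a uniform sphere of the given radius."""
    return _sphere_amplitude(np.asarray(q) * radius) ** 2


def ellipsoid_intensity(q: np.ndarray, a: float, c: float, n_quad: int = 64) -> np.ndarray:
    """Ellipsoid of revolution with equatorial semi-axis ``a`` and polar
    semi-axis ``c``; orientational average by Gauss-Legendre quadrature in
    cos(angle)."""
    u, w = np.polynomial.legendre.leggauss(n_quad)
    u = 0.5 * (u + 1.0)   # map to [0, 1]
    w = 0.5 * w
    r_eff = np.sqrt(a ** 2 * (1.0 - u ** 2) + c ** 2 * u ** 2)
    amp2 = _sphere_amplitude(np.outer(q, r_eff)) ** 2
    return amp2 @ w / np.sum(w)


def dumbbell_intensity(q: np.ndarray, radius: float, separation: float) -> np.ndarray:
    """Two identical uniform spheres with centers ``separation`` apart
    (two-center Debye formula)."""
    q = np.asarray(q, dtype=float)
    f2 = _sphere_amplitude(q * radius) ** 2
    x = q * separation
    sinc = np.ones_like(x)
    nz = x > 1e-12
    sinc[nz] = np.sin(x[nz]) / x[nz]
    return f2 * (1.0 + sinc) / 2.0


def debye_coil_intensity(q: np.ndarray, rg: float) -> np.ndarray:
    """Debye function for a Gaussian chain: 2 (exp(-x) + x - 1) / x^2,
    x = (q Rg)^2."""
    x = (np.asarray(q, dtype=float) * rg) ** 2
    out = np.ones_like(x)
    nz = x > 1e-10
    xs = x[nz]
    out[nz] = 2.0 * (np.exp(-xs) + xs - 1.0) / xs ** 2
    return out


def guinier_intensity(q: np.ndarray, rg: float) -> np.ndarray:
    """Pure Guinier law exp(-q^2 Rg^2 / 3) over the whole grid."""
    return np.exp(-(np.asarray(q) * rg) ** 2 / 3.0)


def sphere_pr(r: np.ndarray, radius: float) -> np.ndarray:
    """Closed-form distance distribution of a uniform sphere, normalized to
    unit area: p(r) = 12 x^2 (1 - 1.5 x + 0.5 x^3) / R with x = r / 2R
    (integral over r in [0, 2R] of x^2 (1 - 1.5 x + 0.5 x^3) dx is R/12)."""
    r = np.asarray(r, dtype=float)
    x = r / (2.0 * radius)
    p = np.where((x >= 0) & (x <= 1), 12.0 * x ** 2 * (1 - 1.5 * x + 0.5 * x ** 3), 0.0)
    return p / radius


def hard_sphere_structure_factor(q: np.ndarray, radius: float, volume_fraction: float) -> np.ndarray:
    """Percus-Yevick structure factor of hard spheres (interaction radius
    ``radius``, packing fraction ``volume_fraction``)."""
    eta = float(volume_fraction)
    if not 0 <= eta < 1:
        raise ValueError("volume fraction must be in [0, 1)")
    if eta == 0:
        return np.ones_like(np.asarray(q, dtype=float))
    A = 2.0 * radius * np.asarray(q, dtype=float)
    alpha = (1 + 2 * eta) ** 2 / (1 - eta) ** 4
    beta = -6 * eta * (1 + eta / 2) ** 2 / (1 - eta) ** 4
    gamma = eta * alpha / 2
    A = np.where(A < 1e-6, 1e-6, A)
    sinA, cosA = np.sin(A), np.cos(A)
    G = (
        alpha * (sinA - A * cosA) / A ** 2
        + beta * (2 * A * sinA + (2 - A ** 2) * cosA - 2) / A ** 3
        + gamma * (-(A ** 4) * cosA + 4 * ((3 * A ** 2 - 6) * cosA + (A ** 3 - 6 * A) * sinA + 6)) / A ** 5
    )
    return 1.0 / (1.0 + 24 * eta * G / A)


_SHAPES = ("sphere", "ellipsoid_of_revolution", "two_sphere_dumbbell", "debye_coil", "guinier_law")


@dataclass(frozen=True)
class TruthRecord:
    """Exact ground truth of a generated profile."""

    Rg: float
    dmax: Optional[float]
    volume: Optional[float]   # A^3, uniform-body volume where defined
    I0: float


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic profile.

    geometry keys by shape: sphere {radius}; ellipsoid_of_revolution {a, c};
    two_sphere_dumbbell {radius, separation}; debye_coil {rg};
    guinier_law {rg}.
    """

    shape: str = "sphere"
    geometry: dict = field(default_factory=lambda: {"radius": 30.0})
    I0_abs: float = 1.0                  # forward intensity, 1/cm on absolute scale
    q_grid: Optional[np.ndarray] = None  # default 0.005..0.5, 400 points
    counts_at_qmin: float = 0.0          # 0 disables noise
    seed: int = 0
    poisson: bool = False                # draw true Poisson counts instead of Gaussian
    structure_factor: Optional[dict] = None   # {"volume_fraction": .., "radius": ..}
    solvent_mismatch: float = 0.0        # additive constant (same units as I)
    aggregate: Optional[dict] = None     # {"mass_fraction": .., "size_multiplier": ..}
    smearing_sigma_q: Optional[np.ndarray] = None  # per-q Gaussian kernel width

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.q_grid is None:
            self.q_grid = np.linspace(0.005, 0.5, 400)
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        for key, val in self.geometry.items():
            if val <= 0:
                raise ValueError(f"geometry {key} must be positive")


def _shape_truth(spec: SyntheticSpec):
    g = spec.geometry
    if spec.shape == "sphere":
        R = g["radius"]
        form = lambda q: sphere_intensity(q, R)
        return form, math.sqrt(3.0 / 5.0) * R, 2 * R, 4.0 / 3.0 * math.pi * R ** 3
    if spec.shape == "ellipsoid_of_revolution":
        a, c = g["a"], g["c"]
        form = lambda q: ellipsoid_intensity(q, a, c)
        rg = math.sqrt((2 * a ** 2 + c ** 2) / 5.0)
        return form, rg, 2 * max(a, c), 4.0 / 3.0 * math.pi * a * a * c
    if spec.shape == "two_sphere_dumbbell":
        R, D = g["radius"], g["separation"]
        form = lambda q: dumbbell_intensity(q, R, D)
        rg = math.sqrt(0.6 * R ** 2 + D ** 2 / 4.0)  # parallel-axis theorem
        return form, rg, 2 * R + D, 2 * (4.0 / 3.0) * math.pi * R ** 3
    if spec.shape == "debye_coil":
        rg = g["rg"]
        return (lambda q: debye_coil_intensity(q, rg)), rg, None, None
    rg = g["rg"]
    return (lambda q: guinier_intensity(q, rg)), rg, None, None


def generate(spec: SyntheticSpec):
    """Generate one profile.  Returns ``(Profile, TruthRecord)``.

    The truth record reflects the underlying monodisperse particle; the
    corruptions (structure factor, aggregate, mismatch) deliberately make the
    *profile* deviate from it, which is the point of using them as test
    fixtures for the diagnostics.
    """
    q = spec.q_grid
    form, rg, dmax, volume = _shape_truth(spec)
    intensity = spec.I0_abs * form(q)
    if spec.aggregate:
        w = spec.aggregate["mass_fraction"]
        mult = spec.aggregate["size_multiplier"]
        if not 0 <= w < 1:
            raise ValueError("aggregate mass fraction must be in [0, 1)")
        if spec.shape != "sphere":
            raise ValueError("aggregate corruption implemented for spheres")
        R = spec.geometry["radius"]
        # at fixed mass concentration, I(0) per species scales with its mass
        agg = spec.I0_abs * mult ** 3 * sphere_intensity(q, mult * R)
        intensity = (1 - w) * intensity + w * agg
    if spec.structure_factor:
        sf = hard_sphere_structure_factor(
            q, spec.structure_factor["radius"], spec.structure_factor["volume_fraction"]
        )
        intensity = intensity * sf
    if spec.smearing_sigma_q is not None:
        from .fitting import smear_model
        intensity = smear_model(q, intensity, sigma_q=spec.smearing_sigma_q)
    intensity = intensity + spec.solvent_mismatch

    if spec.counts_at_qmin > 0:
        ref = intensity[0] if intensity[0] > 0 else np.max(intensity)
        counts = spec.counts_at_qmin * np.clip(intensity, 1e-12 * ref, None) / ref
        sigma = np.abs(intensity) / np.sqrt(counts)
        rng = np.random.default_rng(spec.seed)
        if spec.poisson:
            scale = counts / np.clip(np.abs(intensity), 1e-300, None)
            noisy = rng.poisson(np.clip(counts, 0, None)) / scale
        else:
            noisy = intensity + rng.normal(0.0, sigma)
        intensity = noisy
    else:
        # noise-free: nominal 1% errors keep sigma columns valid
        floor = 1e-6 * max(abs(spec.I0_abs), float(np.max(np.abs(intensity))))
        sigma = np.maximum(0.01 * np.abs(intensity), floor)

    profile = Profile(
        q=q, intensity=intensity, sigma=sigma,
        scale="absolute", calibration="synthetic: exact absolute scale",
        meta={"synthetic_shape": spec.shape, "seed": spec.seed},
    )
    truth = TruthRecord(Rg=rg, dmax=dmax, volume=volume, I0=spec.I0_abs)
    return profile, truth


# ----------------------------------------------------------------------------
# SEC run simulation

@dataclass
class ElutionComponent:
    """One eluting species: a particle spec plus a Gaussian elution profile
    (center and width in seconds, peak concentration in mg/ml) and an
    extinction coefficient for the UV trace (A280 for 0.1% w/v, 1 cm)."""

    spec: SyntheticSpec
    center: float
    width: float
    peak_concentration: float
    epsilon: float = 1.0
    i0_per_mg_ml: float = 0.02   # forward intensity per unit concentration, 1/cm per mg/ml

    def concentration(self, t: np.ndarray) -> np.ndarray:
        return self.peak_concentration * np.exp(-0.5 * ((np.asarray(t) - self.center) / self.width) ** 2)


def simulate_sec_run(
    components: Sequence[ElutionComponent],
    times: np.ndarray,
    q_grid: np.ndarray,
    baseline_level: float = 0.02,
    baseline_drift: float = 0.0,        # fractional drift of the baseline per second
    counts_at_qmin: float = 1e4,
    uv_path_cm: float = 0.31,
    uv_delay: float = 0.0,              # UV measured this many seconds before SAS
    seed: int = 0,
):
    """Simulate a SEC-SAS run.

    Returns ``(FrameSeries, truth)`` where truth holds the per-frame
    concentration of each component, the baseline profile and the component
    truth records.  Frames carry total (unsubtracted) intensity: baseline plus
    concentration-scaled component form factors, with counting noise.
    """
    times = np.asarray(times, dtype=float)
    q = np.asarray(q_grid, dtype=float)
    rng = np.random.default_rng(seed)
    base = baseline_level * (1.0 + 0.5 * (q / q[-1]))   # gently sloping solvent curve
    comp_curves = []
    for comp in components:
        form, *_ = _shape_truth(comp.spec)
        comp_curves.append(comp.i0_per_mg_ml * form(q))
    frames = []
    conc = np.zeros((len(components), len(times)))
    for j, t in enumerate(times):
        drift = 1.0 + baseline_drift * (t - times[0])
        ideal = base * drift
        for k, comp in enumerate(components):
            c = float(comp.concentration(np.array([t]))[0])
            conc[k, j] = c
            ideal = ideal + c * comp_curves[k]
        counts = counts_at_qmin * ideal / ideal[0]
        sigma = ideal / np.sqrt(counts)
        noisy = ideal + rng.normal(0.0, sigma)
        frames.append(Profile(q=q, intensity=noisy, sigma=sigma,
                              scale="absolute", calibration="synthetic: exact absolute scale"))
    # UV trace: A280 = sum_k C_k * eps_k * path; measured uv_delay s earlier
    uv_times = times - uv_delay
    a280_vals = np.zeros_like(times)
    for k, comp in enumerate(components):
        a280_vals += comp.concentration(times) * comp.epsilon * uv_path_cm
    a280 = np.column_stack([uv_times, a280_vals])
    series = FrameSeries(frames=frames, times=times, a280=a280, alignment=uv_delay)
    truth = {
        "concentration": conc,
        "baseline": base,
        "baseline_drift": baseline_drift,
        "components": [_shape_truth(c.spec)[1:] for c in components],  # (Rg, dmax, V)
        "uv_delay": uv_delay,
        "uv_path_cm": uv_path_cm,
    }
    return series, truth
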