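"""Composition-based scattering contrast and neutron contrast-variation
analysis.

From a sequence this module tallies elemental composition (with deuteration
and labile-hydrogen bookkeeping), and derives:

* molecular mass and partial specific volume (residue-volume tables),
* X-ray and neutron scattering-length densities of particle and solvent,
  hence the mean contrast delta_rho = rho_particle - rho_solvent and the mass
  contrast delta_rho_M = delta_rho * vbar used in the I(0)-to-mass relation,
* the A280 extinction coefficient (Gill & von Hippel composition rule).

For a neutron contrast series (measurements at several solvent 2H2O
fractions) it implements the match-point fit (signed sqrt(I(0)/C) versus
solvent density), the Stuhrmann plot Rg^2 = Rm^2 + alpha/delta_rho -
beta/delta_rho^2, the two-component parallel-axis decomposition, and per-q
extraction of the component scattering functions I11, I12, I22.

Units: scattering-length densities in cm^-2 (often quoted as 10^10 cm^-2),
volumes in A^3, vbar in cm^3/g, masses in Da.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .profiles import Profile
from .guinier import GuinierResult

__all__ = [
    "Composition", "ContrastContext", "ContrastPoint", "ContrastSeries",
    "composition_from_sequence", "contrast_context", "solvent_sld",
    "extinction_coefficient", "match_point", "stuhrmann",
    "parallel_axis", "decompose_two_components", "extract_components",
    "R0_ELECTRON_CM", "WATER_MOLAR_VOLUME",
]

R0_ELECTRON_CM = 2.8179e-13   # Thomson scattering length of the electron, cm
AVOGADRO = 6.02214076e23
WATER_MOLAR_VOLUME = 18.07    # cm^3/mol at ~22 C
D_MINUS_H_MASS = 1.00628      # 2H - 1H mass difference, Da

_N_TERMINAL_EXTRA_LABILE = {"protein": 3, "dna": 2, "rna": 2}


def _load(name: str) -> dict:
    with resources.files("saskit.data").joinpath(name).open() as fh:
        return json.load(fh)


_ELEMENTS = {k: v for k, v in _load("elements.json").items() if not k.startswith("_")}
_AA = {k: v for k, v in _load("amino_acids.json").items() if not k.startswith("_")}
_NUC = _load("nucleotides.json")
_SOLUTES = {k: v for k, v in _load("solutes.json").items() if not k.startswith("_")}


@dataclass
class Composition:
    """Elemental composition of a particle (all copies included).

    ``atoms`` counts every element including H; ``labile_H`` of those
    hydrogens are solvent-exchangeable, and ``deuterated_H`` of the
    non-exchangeable ones carry 2H from biosynthetic deuteration.
    """

    atoms: Dict[str, float]
    labile_H: float
    deuterated_H: float
    volume: float            # A^3, from residue-volume tables
    n_copies: int = 1
    kind: str = "protein"
    sequence: Optional[str] = None

    @property
    def mass(self) -> float:
        """Average (not monoisotopic) molecular mass in Da, including the
        extra neutron mass of biosynthetically deuterated hydrogens."""
        m = sum(n * _ELEMENTS[el]["mass"] for el, n in self.atoms.items())
        return m + self.deuterated_H * D_MINUS_H_MASS

    @property
    def electrons(self) -> float:
        return sum(n * _ELEMENTS[el]["electrons"] for el, n in self.atoms.items())

    @property
    def vbar(self) -> float:
        """Partial specific volume, cm^3/g."""
        return self.volume * AVOGADRO * 1e-24 / self.mass

    def neutron_b(self, f_d2o: float = 0.0, exchange_completeness: float = 0.9) -> float:
        """Total coherent scattering length (cm) at a given solvent 2H2O
        fraction.  Labile hydrogens exchange with the solvent in proportion
        to f_d2o times the exchange completeness."""
        bH = _ELEMENTS["H"]["b_coh"]
        bD = _ELEMENTS["D"]["b_coh"]
        total = sum(n * _ELEMENTS[el]["b_coh"] for el, n in self.atoms.items())
        total += self.deuterated_H * (bD - bH)
        total += self.labile_H * exchange_completeness * f_d2o * (bD - bH)
        return total * 1e-13  # fm -> cm


def _merge(atoms: Dict[str, float], formula: Dict[str, float], mult: float = 1.0):
    for el, n in formula.items():
        atoms[el] = atoms.get(el, 0.0) + mult * n


def composition_from_sequence(
    sequence: str,
    kind: str = "protein",
    n_copies: int = 1,
    deuteration: float = 0.0,
    ligands: Optional[Sequence[Tuple[Dict[str, float], float, int]]] = None,
) -> Composition:
    """Tally elemental composition from a one-letter sequence.

    Parameters
    ----------
    kind : {"protein", "dna", "rna"}
    n_copies : int
        Oligomeric multiplier (a homotetramer is the monomer sequence with
        n_copies = 4).
    deuteration : float in [0, 1]
        Fraction of non-exchangeable hydrogens biosynthetically replaced by
        2H.
    ligands : sequence of (formula, volume_A3, count), optional
        Extra formula units per *whole particle* (cofactors, tags already in
        sequence form should simply be appended to the sequence).
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty sequence")
    if not 0 <= deuteration <= 1:
        raise ValueError("deuteration fraction must be in [0, 1]")
    if kind == "protein":
        table = _AA
    elif kind in ("dna", "rna"):
        table = _NUC[kind]
    else:
        raise ValueError(f"unknown molecule kind {kind!r}")
    atoms: Dict[str, float] = {}
    labile = 0.0
    volume = 0.0
    for ch in sequence:
        try:
            res = table[ch]
        except KeyError:
            raise ValueError(f"unknown residue letter {ch!r} for kind {kind!r}") from None
        _merge(atoms, res["formula"])
        labile += res["exch_H"]
        volume += res["volume"]
    # chain termini: one water plus its labile hydrogens
    _merge(atoms, {"H": 2, "O": 1})
    labile += _N_TERMINAL_EXTRA_LABILE[kind]
    volume += WATER_MOLAR_VOLUME / AVOGADRO * 1e24
    # scale to n_copies
    atoms = {el: n * n_copies for el, n in atoms.items()}
    labile *= n_copies
    volume *= n_copies
    if ligands:
        for formula, vol, count in ligands:
            _merge(atoms, formula, mult=count)
            volume += vol * count
    nonexch_H = atoms.get("H", 0.0) - labile
    deuterated = deuteration * nonexch_H
    return Composition(atoms=atoms, labile_H=labile, deuterated_H=deuterated,
                       volume=volume, n_copies=n_copies, kind=kind, sequence=sequence)


# ----------------------------------------------------------------------------
# solvent and context

def solvent_sld(
    solutes: Optional[Dict[str, float]] = None,
    probe: str = "xray",
    f_d2o: float = 0.0,
) -> float:
    """Scattering-length density of an aqueous solvent, cm^-2.

    ``solutes`` maps chemical names (built-in table) or explicit formulas to
    molar concentrations; each solute displaces water by its partial molar
    volume.  For neutrons, ``f_d2o`` is the 2H2O mole fraction of the water.
    """
    solutes = solutes or {}
    # per liter: start from pure water occupying the whole volume
    displaced = 0.0   # cm^3 of water displaced per liter
    b_solutes = 0.0   # scattering length (cm) per liter, or electrons for X-ray
    for name, molar in solutes.items():
        if name in _SOLUTES:
            entry = _SOLUTES[name]
        elif isinstance(name, str):
            raise ValueError(f"unknown solute {name!r}; supply via built-in table names")
        formula = entry["formula"]
        displaced += molar * entry.get("molar_volume", 0.0)
        if probe == "xray":
            ne = sum(n * _ELEMENTS[el]["electrons"] for el, n in formula.items())
            b_solutes += molar * AVOGADRO * ne * R0_ELECTRON_CM
        else:
            b = sum(n * _ELEMENTS[el]["b_coh"] for el, n in formula.items()) * 1e-13
            b_solutes += molar * AVOGADRO * b
    water_cm3 = 1000.0 - displaced
    moles_water = water_cm3 / WATER_MOLAR_VOLUME
    if probe == "xray":
        b_water = moles_water * AVOGADRO * 10 * R0_ELECTRON_CM
    elif probe == "neutron":
        bH = _ELEMENTS["H"]["b_coh"] * (1 - f_d2o) + _ELEMENTS["D"]["b_coh"] * f_d2o
        b_per_molecule = (2 * bH + _ELEMENTS["O"]["b_coh"]) * 1e-13
        b_water = moles_water * AVOGADRO * b_per_molecule
    else:
        raise ValueError("probe must be 'xray' or 'neutron'")
    return (b_water + b_solutes) / 1000.0  # per cm^3 of solvent


@dataclass(frozen=True)
class ContrastContext:
    """Scattering-length densities and derived contrast of one particle in
    one solvent, for one probe."""

    rho_particle: float   # cm^-2
    rho_solvent: float    # cm^-2
    vbar: float           # cm^3/g
    probe: str
    f_d2o: float = 0.0
    exchange_completeness: float = 0.9

    @property
    def delta_rho(self) -> float:
        return self.rho_particle - self.rho_solvent

    @property
    def delta_rho_M(self) -> float:
        """Mass contrast, cm^2/g: delta_rho * vbar (identity by construction)."""
        return self.delta_rho * self.vbar


def contrast_context(
    comp: Composition,
    solutes: Optional[Dict[str, float]] = None,
    probe: str = "xray",
    f_d2o: float = 0.0,
    exchange_completeness: float = 0.9,
    vbar: Optional[float] = None,
) -> ContrastContext:
    """Build the contrast context for a particle in a given solvent.

    ``vbar`` can be supplied to override the residue-table estimate (e.g.
    when matching a published value); the particle volume used for
    rho_particle is then M * vbar / N_A.
    """
    if vbar is None:
        vbar = comp.vbar
    vol_cm3 = comp.mass * vbar / AVOGADRO          # particle dry volume, cm^3
    if probe == "xray":
        b = comp.electrons * R0_ELECTRON_CM
    elif probe == "neutron":
        b = comp.neutron_b(f_d2o=f_d2o, exchange_completeness=exchange_completeness)
    else:
        raise ValueError("probe must be 'xray' or 'neutron'")
    rho_p = b / vol_cm3
    rho_s = solvent_sld(solutes, probe=probe, f_d2o=f_d2o)
    return ContrastContext(rho_particle=rho_p, rho_solvent=rho_s, vbar=vbar,
                           probe=probe, f_d2o=f_d2o,
                           exchange_completeness=exchange_completeness)


def extinction_coefficient(sequence: str, cystines: str = "all") -> float:
    """A280 extinction coefficient for a 0.1% (w/v = 1 g/l) solution, 1 cm
    path, from the Gill & von Hippel composition rule:
    eps_M = 5500 nW + 1490 nY + 125 n_cystine (M^-1 cm^-1), divided by the
    mass.  ``cystines``: "all" assumes every pair of Cys forms a disulfide,
    "none" assumes all reduced."""
    seq = sequence.strip().upper()
    n_w = seq.count("W")
    n_y = seq.count("Y")
    n_c = seq.count("C")
    n_ss = n_c // 2 if cystines == "all" else 0
    eps_molar = 5500 * n_w + 1490 * n_y + 125 * n_ss
    mass = composition_from_sequence(seq, kind="protein").mass
    return eps_molar / mass


# ----------------------------------------------------------------------------
# contrast series analyses

@dataclass
class ContrastPoint:
    """One contrast point of a SANS series."""

    f_d2o: float
    profile: Optional[Profile]
    concentration: float          # mg/ml
    guinier: GuinierResult
    context: ContrastContext


@dataclass
class ContrastSeries:
    points: list

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValueError("a contrast series needs at least 2 points")

    def __len__(self):
        return len(self.points)

    def __iter__(self):
        return iter(self.points)


def match_point(series: ContrastSeries) -> dict:
    """Solvent match point from the linear fit of signed sqrt(I(0)/C) versus
    solvent scattering-length density.

    The sign of each square root follows the sign of the calculated contrast
    at that point (the measured I(0) loses the sign).  Returns the match
    point both as a solvent density and as an f_d2o value, with the fit
    standard error, flagging extrapolation when the root lies outside the
    measured f_d2o range.
    """
    x = np.array([p.context.rho_solvent for p in series])
    f = np.array([p.f_d2o for p in series])
    y = np.array([math.copysign(math.sqrt(p.guinier.I0 / p.concentration),
                                p.context.delta_rho) for p in series])
    yerr = np.array([0.5 * p.guinier.I0_err / math.sqrt(p.guinier.I0 * p.concentration)
                     for p in series])
    w = 1.0 / np.where(yerr > 0, yerr, np.median(yerr[yerr > 0]) if np.any(yerr > 0) else 1.0) ** 2
    W = np.sum(w); xm = np.sum(w * x) / W; ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    b = np.sum(w * (x - xm) * (y - ym)) / sxx
    a = ym - b * xm
    if b == 0:
        raise ValueError("flat contrast series: no match point")
    rho_match = -a / b
    # error of the root by the delta method
    var_b = 1.0 / sxx
    var_a = 1.0 / W + xm ** 2 / sxx
    cov_ab = -xm / sxx
    var_root = (var_a / b ** 2 + a ** 2 * var_b / b ** 4 - 2 * a * cov_ab / b ** 3)
    # map back to f_d2o via the (locally linear) rho_solvent(f) relation
    coeffs = np.polyfit(f, x, 1)
    f_match = (rho_match - coeffs[1]) / coeffs[0]
    same_sign = np.all(y > 0) or np.all(y < 0)
    extrapolated = bool(f_match < f.min() or f_match > f.max() or same_sign)
    return {
        "rho_match": float(rho_match),
        "rho_match_err": float(math.sqrt(max(var_root, 0.0))),
        "f_d2o_match": float(f_match),
        "slope": float(b), "intercept": float(a),
        "extrapolated": extrapolated,
    }


def stuhrmann(series: ContrastSeries, pin_beta: bool = False) -> dict:
    """Weighted fit of Rg^2 = Rm^2 + alpha/delta_rho - beta/delta_rho^2.

    Rm is the radius of gyration at infinite contrast; alpha reports the
    radial distribution of internal density inhomogeneity and beta the
    displacement between the centre of scattering and the centre of shape.
    ``pin_beta`` drops the quadratic term (two-parameter mode, minimum 2
    points; full mode needs 3)."""
    pts = list(series)
    need = 2 if pin_beta else 3
    if len(pts) < need:
        raise ValueError(f"Stuhrmann fit needs at least {need} contrast points")
    inv = np.array([1.0 / p.context.delta_rho for p in pts])
    y = np.array([p.guinier.Rg ** 2 for p in pts])
    yerr = np.array([2 * p.guinier.Rg * p.guinier.Rg_err for p in pts])
    w = np.where(yerr > 0, 1.0 / yerr ** 2, 1.0)
    cols = [np.ones_like(inv), inv] if pin_beta else [np.ones_like(inv), inv, -inv ** 2]
    A = np.column_stack(cols)
    Aw = A * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    # column scaling: 1, 1/delta_rho and 1/delta_rho^2 differ by ~10 orders
    # of magnitude each, so the raw normal equations are hopelessly
    # ill-conditioned
    col_scale = np.linalg.norm(Aw, axis=0)
    As = Aw / col_scale
    coef, *_ = np.linalg.lstsq(As, yw, rcond=None)
    coef = coef / col_scale
    cov = np.linalg.inv(As.T @ As) / np.outer(col_scale, col_scale)
    out = {
        "Rm2": float(coef[0]), "Rm2_err": float(math.sqrt(cov[0, 0])),
        "alpha": float(coef[1]), "alpha_err": float(math.sqrt(cov[1, 1])),
        "beta": float(coef[2]) if not pin_beta else 0.0,
        "beta_err": float(math.sqrt(cov[2, 2])) if not pin_beta else 0.0,
        "residuals": (y - A @ coef).tolist(),
    }
    return out


def parallel_axis(R1: float, R2: float, f1: float, D: float) -> float:
    """Whole-particle Rg from two components:
    Rg^2 = f1 R1^2 + f2 R2^2 + f1 f2 D^2 with f2 = 1 - f1, where f1 is the
    contrast-weighted scattering fraction of component 1 and D the distance
    between the component centres of scattering."""
    f2 = 1.0 - f1
    return math.sqrt(f1 * R1 ** 2 + f2 * R2 ** 2 + f1 * f2 * D ** 2)


def decompose_two_components(
    rg_values: Sequence[float],
    f1_values: Sequence[float],
    rg_errors: Optional[Sequence[float]] = None,
) -> dict:
    """Invert the parallel-axis relation across a contrast series.

    Given whole-particle Rg and the contrast-weighted fraction f1 of
    component 1 at each contrast point, solve the linear system
    Rg^2 = f1 R1^2 + (1-f1) R2^2 + f1(1-f1) D^2 for (R1^2, R2^2, D^2) by
    weighted least squares.  Needs >= 3 points with distinct f1.
    """
    f1 = np.asarray(f1_values, dtype=float)
    rg = np.asarray(rg_values, dtype=float)
    if len(f1) < 3:
        raise ValueError("parallel-axis decomposition needs at least 3 contrast points")
    y = rg ** 2
    if rg_errors is not None:
        yerr = 2 * rg * np.asarray(rg_errors, dtype=float)
        w = np.where(yerr > 0, 1.0 / yerr ** 2, 1.0)
    else:
        w = np.ones_like(y)
    A = np.column_stack([f1, 1.0 - f1, f1 * (1.0 - f1)])
    Aw = A * np.sqrt(w)[:, None]
    coef, *_ = np.linalg.lstsq(Aw, y * np.sqrt(w), rcond=None)
    r1sq, r2sq, dsq = coef
    return {
        "R1": float(math.sqrt(max(r1sq, 0.0))),
        "R2": float(math.sqrt(max(r2sq, 0.0))),
        "D": float(math.sqrt(max(dsq, 0.0))),
    }


def extract_components(
    profiles: Sequence[Profile],
    contrasts: Sequence[Tuple[float, float]],
    condition_limit: float = 1e6,
):
    """Per-q decomposition of a contrast series into component scattering
    functions.

    Each measured curve obeys
    I_k(q) = d1_k^2 I11(q) + d1_k d2_k I12(q) + d2_k^2 I22(q)
    where (d1_k, d2_k) are the component contrasts at point k.  Solves the
    per-q weighted least squares for (I11, I12, I22) with error propagation,
    and reports the design condition number.

    Returns ``(I11, I12, I22, errors, info)`` with errors an (3, nq) array.
    """
    if len(profiles) < 3:
        raise ValueError("component extraction needs at least 3 contrast points")
    if len(profiles) != len(contrasts):
        raise ValueError("one (delta_rho1, delta_rho2) pair per profile required")
    q0 = profiles[0].q
    for p in profiles[1:]:
        if not p.same_grid(profiles[0]):
            raise ValueError("all contrast-series profiles must share one q-grid")
    d = np.asarray(contrasts, dtype=float)
    X = np.column_stack([d[:, 0] ** 2, d[:, 0] * d[:, 1], d[:, 1] ** 2])
    svals = np.linalg.svd(X, compute_uv=False)
    cond = float(svals[0] / svals[-1]) if svals[-1] > 0 else np.inf
    if not np.isfinite(cond) or cond > condition_limit:
        # name the deficient direction in the raised error
        _, _, vt = np.linalg.svd(X)
        null = vt[-1]
        labels = ["I11", "I12", "I22"]
        combo = " + ".join(f"{c:+.2f} {l}" for c, l in zip(null, labels))
        raise ValueError(f"rank-deficient contrast design; undetermined direction: {combo}")
    nq = len(q0)
    I = np.array([p.intensity for p in profiles])        # (K, nq)
    S = np.array([p.sigma for p in profiles])
    out = np.zeros((3, nq))
    err = np.zeros((3, nq))
    for j in range(nq):
        w = 1.0 / S[:, j] ** 2
        Xw = X * np.sqrt(w)[:, None]
        yw = I[:, j] * np.sqrt(w)
        coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        cov = np.linalg.inv(Xw.T @ Xw)
        out[:, j] = coef
        err[:, j] = np.sqrt(np.diag(cov))
    # warn (not fail) on duplicated contrast points
    dup = len(np.unique(np.round(d, 12), axis=0)) < len(d)
    info = {"condition_number": cond, "duplicate_contrast_warning": bool(dup), "q": q0}
    return out[0], out[1], out[2], err, info
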