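import numpy as np
import pytest
from Bio.SeqUtils import molecular_weight

from saskit.contrast import (
    ContrastContext, ContrastPoint, ContrastSeries,
    composition_from_sequence, contrast_context, decompose_two_components,
    extinction_coefficient, extract_components, match_point, parallel_axis,
    solvent_sld, stuhrmann,
)
from saskit.guinier import GuinierResult
from saskit.profiles import Profile

R0 = 2.8179e-13
NA = 6.02214076e23


# ---------------------------------------------------------------- composition

def test_glycine_mass():
    comp = composition_from_sequence("G")
    assert comp.mass == pytest.approx(75.067, abs=0.01)   # glycine + water


@pytest.mark.parametrize("seq", [
    "G",
    "ACDEFGHIKLMNPQRSTVWY",
    "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALP",
])
def test_mass_against_biopython(seq):
    """Independent average-mass oracle."""
    mine = composition_from_sequence(seq).mass
    ref = molecular_weight(seq, seq_type="protein", monoisotopic=False)
    assert mine == pytest.approx(ref, rel=1e-4)


def test_oligomer_mass_multiplies():
    m1 = composition_from_sequence("ACDEFGHIK").mass
    m4 = composition_from_sequence("ACDEFGHIK", n_copies=4).mass
    assert m4 == pytest.approx(4 * m1, rel=1e-12)


def test_deuteration_mass_arithmetic():
    c0 = composition_from_sequence("ACDEFGHIK", deuteration=0.0)
    c1 = composition_from_sequence("ACDEFGHIK", deuteration=1.0)
    nonexch = c0.atoms["H"] - c0.labile_H
    assert c1.mass - c0.mass == pytest.approx(nonexch * 1.00628, rel=1e-9)


def test_vbar_in_protein_range():
    vbar = composition_from_sequence("ACDEFGHIKLMNPQRSTVWY" * 5).vbar
    assert 0.68 < vbar < 0.78


def test_unknown_residue_raises():
    with pytest.raises(ValueError):
        composition_from_sequence("ACX")
    with pytest.raises(ValueError):
        composition_from_sequence("")


def test_ligands_add_to_composition():
    base = composition_from_sequence("ACDEF")
    with_zn = composition_from_sequence("ACDEF", ligands=[({"Zn": 1}, 10.0, 2)])
    assert with_zn.atoms["Zn"] == 2
    assert with_zn.volume == pytest.approx(base.volume + 20.0)


# ------------------------------------------------------------------- solvents

def test_water_xray_sld():
    """Pure water: 10 electrons per 18.07 cm^3/mol."""
    ref = 10 * R0 * NA / 18.07
    assert solvent_sld() == pytest.approx(ref, rel=1e-9)
    assert ref == pytest.approx(9.39e10, rel=0.005)


def test_water_neutron_sld_endpoints():
    assert solvent_sld(probe="neutron", f_d2o=0.0) == pytest.approx(-0.56e10, rel=0.02)
    assert solvent_sld(probe="neutron", f_d2o=1.0) == pytest.approx(6.36e10, rel=0.02)


def test_salt_raises_xray_sld():
    plain = solvent_sld()
    salty = solvent_sld({"NaCl": 1.0})
    assert salty > plain


def test_unknown_solute_raises():
    with pytest.raises(ValueError):
        solvent_sld({"unobtainium": 0.1})


def test_protein_xray_contrast_in_typical_band():
    comp = composition_from_sequence("ACDEFGHIKLMNPQRSTVWY" * 10)
    ctx = contrast_context(comp)
    assert ctx.probe == "xray"
    assert 2.4e10 < ctx.delta_rho < 3.6e10      # typical protein vs water
    assert ctx.delta_rho_M == pytest.approx(ctx.delta_rho * ctx.vbar)


def test_vbar_override():
    comp = composition_from_sequence("ACDEFGHIKLMNPQRSTVWY" * 10)
    ctx = contrast_context(comp, vbar=0.732)
    assert ctx.vbar == 0.732


def test_exchange_moves_neutron_contrast():
    comp = composition_from_sequence("ACDEFGHIKLMNPQRSTVWY" * 10)
    b0 = comp.neutron_b(f_d2o=0.0)
    b1 = comp.neutron_b(f_d2o=1.0, exchange_completeness=0.9)
    bD, bH = 6.671e-13, -3.739e-13
    assert b1 - b0 == pytest.approx(comp.labile_H * 0.9 * (bD - bH), rel=1e-3)


# ----------------------------------------------------------------- extinction

def test_extinction_coefficient_rule():
    m = composition_from_sequence("GY").mass
    assert extinction_coefficient("GY") == pytest.approx(1490 / m, rel=1e-12)
    m2 = composition_from_sequence("WCC").mass
    assert extinction_coefficient("WCC") == pytest.approx((5500 + 125) / m2, rel=1e-12)
    assert extinction_coefficient("WCC", cystines="none") == pytest.approx(5500 / m2, rel=1e-12)


# ------------------------------------------------------------ contrast series

def _fake_point(f, rho_p, rho_s, I0, rg=20.0, conc=1.0):
    ctx = ContrastContext(rho_particle=rho_p, rho_solvent=rho_s,
                          vbar=0.73, probe="neutron", f_d2o=f)
    g = GuinierResult(Rg=rg, Rg_err=0.05, I0=I0, I0_err=0.01 * abs(I0) + 1e-9,
                      q_range=(0.01, 0.06), qRg_window=(0.2, 1.2),
                      r2=1.0, n_points=20)
    return ContrastPoint(f_d2o=f, profile=None, concentration=conc,
                         guinier=g, context=ctx)


def _series(fvals, rho_p0=2.0e10, rho_p1=3.0e10):
    def rho_part(f):
        return rho_p0 + (rho_p1 - rho_p0) * f

    def rho_solv(f):
        return -0.56e10 + (6.36e10 + 0.56e10) * f

    pts = []
    for f in fvals:
        dr = rho_part(f) - rho_solv(f)
        I0 = (dr * 1e-10) ** 2 * 2.5
        pts.append(_fake_point(f, rho_part(f), rho_solv(f), I0))
    f_true = (rho_p0 + 0.56e10) / ((6.36e10 + 0.56e10) - (rho_p1 - rho_p0))
    return ContrastSeries(pts), f_true


def test_match_point_forward_model():
    series, f_true = _series([0.0, 0.2, 0.42, 0.8, 1.0])
    mp = match_point(series)
    assert mp["f_d2o_match"] == pytest.approx(f_true, abs=1e-6)
    assert not mp["extrapolated"]


def test_match_point_flags_extrapolation():
    series, _ = _series([0.0, 0.05, 0.1])   # all far below the root
    mp = match_point(series)
    assert mp["extrapolated"]


def test_stuhrmann_exact_round_trip():
    """Three exact points determine (Rm^2, alpha, beta) exactly."""
    rm2, alpha, beta = 400.0, 8.0e11, 1.0e21
    pts = []
    for f, dr in [(0.0, 3.0e10), (0.2, 2.0e10), (0.9, -1.5e10)]:
        rg2 = rm2 + alpha / dr - beta / dr ** 2
        pts.append(_fake_point(f, dr, 0.0, I0=1.0, rg=np.sqrt(rg2)))
    out = stuhrmann(ContrastSeries(pts))
    assert out["Rm2"] == pytest.approx(rm2, rel=1e-6)
    assert out["alpha"] == pytest.approx(alpha, rel=1e-6)
    assert out["beta"] == pytest.approx(beta, rel=1e-6)


def test_stuhrmann_pinned_beta():
    rm2, alpha = 400.0, 8.0e11
    pts = []
    for f, dr in [(0.0, 3.0e10), (0.9, -1.5e10)]:
        rg2 = rm2 + alpha / dr
        pts.append(_fake_point(f, dr, 0.0, I0=1.0, rg=np.sqrt(rg2)))
    out = stuhrmann(ContrastSeries(pts), pin_beta=True)
    assert out["Rm2"] == pytest.approx(rm2, rel=1e-6)
    assert out["beta"] == 0.0
    with pytest.raises(ValueError):
        stuhrmann(ContrastSeries(pts))   # full fit needs 3 points


def test_parallel_axis_round_trip():
    R1, R2, D = 18.0, 26.0, 45.0
    f1s = [0.2, 0.4, 0.6, 0.8]
    rgs = [parallel_axis(R1, R2, f1, D) for f1 in f1s]
    out = decompose_two_components(rgs, f1s)
    assert out["R1"] == pytest.approx(R1, rel=1e-6)
    assert out["R2"] == pytest.approx(R2, rel=1e-6)
    assert out["D"] == pytest.approx(D, rel=1e-6)


def test_extract_components_recovery():
    q = np.linspace(0.01, 0.3, 120)
    I11 = np.exp(-q ** 2 * 400)
    I22 = np.exp(-q ** 2 * 100)
    I12 = 0.8 * np.sqrt(I11 * I22)
    contrasts = [(3.0, 5.0), (2.0, -1.0), (-1.0, 4.0), (1.0, 1.0)]
    rng = np.random.default_rng(11)
    profs = []
    for d1, d2 in contrasts:
        ideal = d1 * d1 * I11 + d1 * d2 * I12 + d2 * d2 * I22
        sig = 0.01 * np.abs(ideal) + 1e-4
        profs.append(Profile(q=q, intensity=ideal + rng.normal(0, sig), sigma=sig))
    i11, i12, i22, err, info = extract_components(profs, contrasts)
    for rec, ref, e in ((i11, I11, err[0]), (i12, I12, err[1]), (i22, I22, err[2])):
        z = (rec - ref) / e
        assert np.max(np.abs(z)) < 5.0          # within propagated errors
        assert 0.7 < np.std(z) < 1.3            # and errors are calibrated
    assert info["condition_number"] < 100
    assert not info["duplicate_contrast_warning"]


def test_extract_components_rank_deficiency():
    q = np.linspace(0.01, 0.3, 30)
    p = Profile(q=q, intensity=np.ones(30), sigma=np.full(30, 0.01))
    # all points at identical contrast: rank-1 design
    with pytest.raises(ValueError, match="rank-deficient"):
        extract_components([p, p, p], [(1.0, 1.0)] * 3)


def test_extract_components_duplicate_warning():
    q = np.linspace(0.01, 0.3, 30)
    contrasts = [(3.0, 5.0), (3.0, 5.0), (2.0, -1.0), (-1.0, 4.0)]
    profs = [Profile(q=q, intensity=np.full(30, d1 * d2 + d1 ** 2 + d2 ** 2),
                     sigma=np.full(30, 0.01)) for d1, d2 in contrasts]
    *_, info = extract_components(profs, contrasts)
    assert info["duplicate_contrast_warning"]
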