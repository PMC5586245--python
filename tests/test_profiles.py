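import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saskit.profiles import (
    GridMismatchError, Profile, ProfileFormatError,
    read_profile, rescale, subtract_solvent, write_profile,
)


def make_profile(n=20, scale="arbitrary", calibration=None):
    q = np.linspace(0.01, 0.3, n)
    i = np.exp(-q ** 2 * 300.0)
    return Profile(q=q, intensity=i, sigma=0.01 * i, scale=scale, calibration=calibration)


# ---------------------------------------------------------------- invariants

def test_q_must_increase():
    with pytest.raises(ValueError):
        Profile(q=[0.3, 0.2, 0.1], intensity=[1, 1, 1], sigma=[0.1, 0.1, 0.1])


def test_q_must_be_positive():
    with pytest.raises(ValueError):
        Profile(q=[0.0, 0.1, 0.2], intensity=[1, 1, 1], sigma=[0.1, 0.1, 0.1])


def test_sigma_positive_where_finite():
    with pytest.raises(ValueError):
        Profile(q=[0.1, 0.2, 0.3], intensity=[1, 1, 1], sigma=[0.1, 0.0, 0.1])


def test_minimum_three_points():
    with pytest.raises(ValueError):
        Profile(q=[0.1, 0.2], intensity=[1, 1], sigma=[0.1, 0.1])


def test_absolute_scale_requires_calibration():
    with pytest.raises(ValueError):
        make_profile(scale="absolute")
    p = make_profile(scale="absolute", calibration="1 mm pure H2O")
    assert p.calibration


def test_crop():
    p = make_profile(50)
    c = p.crop(qmin=0.05, qmax=0.2)
    assert c.q[0] >= 0.05 and c.q[-1] <= 0.2
    with pytest.raises(ValueError):
        p.crop(qmin=0.29, qmax=0.30)  # fewer than 3 points


# ---------------------------------------------------------------------- I/O

def test_round_trip(tmp_path):
    p = make_profile(40)
    f = tmp_path / "prof.dat"
    write_profile(p, f)
    r = read_profile(f)
    assert np.allclose(r.q, p.q, rtol=1e-5)
    assert np.allclose(r.intensity, p.intensity, rtol=1e-5)
    assert np.allclose(r.sigma, p.sigma, rtol=1e-5)


def test_write_read_is_idempotent(tmp_path):
    """A written file reads back and rewrites to identical bytes."""
    p = make_profile(40)
    f1, f2 = tmp_path / "a.dat", tmp_path / "b.dat"
    write_profile(p, f1)
    write_profile(read_profile(f1), f2)
    a = "\n".join(l for l in f1.read_text().splitlines() if not l.startswith("#"))
    b = "\n".join(l for l in f2.read_text().splitlines() if not l.startswith("#"))
    assert a == b


def test_sigma_is_2x_dialect(tmp_path):
    f = tmp_path / "p.dat"
    f.write_text("0.01 1.0 0.2\n0.02 0.9 0.2\n0.03 0.8 0.2\n")
    p = read_profile(f, dialect="sigma_is_2x")
    assert np.allclose(p.sigma, 0.1)


def test_nm_units(tmp_path):
    f = tmp_path / "p.dat"
    f.write_text("0.1 1.0 0.1\n0.2 0.9 0.1\n0.3 0.8 0.1\n")
    p = read_profile(f, units="nm")
    assert np.allclose(p.q, [0.01, 0.02, 0.03])


def test_header_meta_and_dropped_rows(tmp_path):
    f = tmp_path / "p.dat"
    f.write_text(
        "# wavelength: 1.24\n# instrument: beamline X\n"
        "0.01 1.0 0.1\n0.02 nan 0.1\n0.03 0.8 0.1\n0.04 0.7 0.1\n"
    )
    p = read_profile(f)
    assert p.meta["wavelength"] == 1.24
    assert p.meta["instrument"] == "beamline X"
    assert p.meta["n_dropped_rows"] == 1
    assert len(p) == 3


def test_unparseable_file(tmp_path):
    f = tmp_path / "junk.dat"
    f.write_text("hello\nworld\n")
    with pytest.raises(ProfileFormatError):
        read_profile(f)


def test_two_column_file_rejected(tmp_path):
    f = tmp_path / "p.dat"
    f.write_text("0.01 1.0\n0.02 0.9\n0.03 0.8\n")
    with pytest.raises(ProfileFormatError):
        read_profile(f)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    n=st.integers(min_value=3, max_value=60),
    seed=st.integers(min_value=0, max_value=2 ** 31 - 1),
)
def test_round_trip_property(tmp_path_factory, n, seed):
    rng = np.random.default_rng(seed)
    q = np.sort(rng.uniform(1e-3, 1.0, n))
    q += np.arange(n) * 1e-6  # ensure strict increase
    i = rng.uniform(-1.0, 10.0, n)
    s = rng.uniform(1e-4, 1.0, n)
    p = Profile(q=q, intensity=i, sigma=s)
    f = tmp_path_factory.mktemp("rt") / "p.dat"
    write_profile(p, f)
    r = read_profile(f)
    assert np.allclose(r.q, p.q, rtol=1e-5)
    assert np.allclose(r.intensity, p.intensity, rtol=1e-5, atol=1e-12)


# ----------------------------------------------------------------- rescaling

def test_rescale_marks_absolute_with_standard():
    p = make_profile()
    r = rescale(p, 2.05, provenance="1 mm pure H2O at 20 C")
    assert r.scale == "absolute"
    assert np.allclose(r.intensity, 2.05 * p.intensity)
    assert np.allclose(r.sigma, 2.05 * p.sigma)


def test_rescale_without_standard_stays_arbitrary():
    p = make_profile()
    r = rescale(p, 3.0, provenance="relative inter-batch factor")
    assert r.scale == "arbitrary"


def test_rescale_rejects_nonpositive():
    with pytest.raises(ValueError):
        rescale(make_profile(), 0.0)


# --------------------------------------------------------------- subtraction

def test_subtraction_values_and_errors():
    s = make_profile()
    b = Profile(q=s.q, intensity=0.5 * s.intensity, sigma=0.02 * s.intensity)
    out, rep = subtract_solvent(s, b, constant=0.0)
    assert np.allclose(out.intensity, s.intensity - b.intensity)
    assert np.allclose(out.sigma, np.sqrt(s.sigma ** 2 + b.sigma ** 2))
    assert not rep.flagged


def test_subtraction_antisymmetry():
    a = make_profile()
    b = Profile(q=a.q, intensity=a.intensity * 0.7, sigma=a.sigma)
    ab, _ = subtract_solvent(a, b)
    ba, _ = subtract_solvent(b, a)
    assert np.allclose(ab.intensity, -ba.intensity)


def test_large_constant_flagged():
    s = make_profile()
    b = Profile(q=s.q, intensity=np.full_like(s.q, 0.1), sigma=np.full_like(s.q, 0.01))
    _, rep = subtract_solvent(s, b, constant=0.05)  # 50% of solvent level
    assert rep.flagged
    _, rep2 = subtract_solvent(s, b, constant=0.0005)  # 0.5%
    assert not rep2.flagged


def test_grid_mismatch_raises():
    a = make_profile(20)
    b = make_profile(21)
    with pytest.raises(GridMismatchError):
        subtract_solvent(a, b)
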