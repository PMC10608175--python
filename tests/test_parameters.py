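import math

import pytest
from hypothesis import given, settings, strategies as st

from memelastic.parameters import (
    ParameterValidationError,
    default_parameter_set,
    derive_higher_moduli,
    spontaneous_stretching,
    tension_kBT_per_nm2_to_mN_per_m,
    tension_mN_per_m_to_kBT_per_nm2,
)


@pytest.mark.parametrize(
    "kt,h,expected",
    [
        # thin (disordered-like) monolayer: printed to one decimal
        (12.0, 1.3, {"kc": -3.4, "kgr": 1.7, "B": -7.8, "C": 3.3}),
        # thick (ordered-like) monolayer
        (12.0, 1.8, {"kc": -6.5, "kgr": 6.3, "B": -10.8, "C": 8.7}),
        # degenerate zero thickness
        (12.0, 0.0, {"kc": 0.0, "kgr": 0.0, "B": 0.0, "C": 0.0}),
    ],
)
def test_derived_moduli_match_closed_forms(kt, h, expected):
    out = derive_higher_moduli(kt, h)
    for name, value in expected.items():
        assert round(out[name], 1) == pytest.approx(value)


def test_derived_moduli_signs_and_homogeneity():
    base = derive_higher_moduli(12.0, 1.1)
    assert base["kc"] < 0 and base["B"] < 0 and base["C"] > 0 and base["kgr"] > 0
    doubled = derive_higher_moduli(12.0, 2.2)
    assert doubled["kc"] == pytest.approx(4 * base["kc"])
    assert doubled["kgr"] == pytest.approx(16 * base["kgr"])
    assert doubled["B"] == pytest.approx(2 * base["B"])
    assert doubled["C"] == pytest.approx(8 * base["C"])


def test_derived_moduli_reject_bad_input():
    with pytest.raises(ParameterValidationError):
        derive_higher_moduli(-1.0, 1.3)
    with pytest.raises(ParameterValidationError):
        derive_higher_moduli(12.0, -0.1)


def test_spontaneous_stretching():
    # 0.1 mN/m at kA = 30 kBT/nm^2 prints as 8e-4
    a0 = spontaneous_stretching(0.1, 30.0, 300.0, "mN/m")
    assert round(a0 * 1e4) == 8
    assert spontaneous_stretching(0.0, 30.0) == 0.0
    assert spontaneous_stretching(0.025, 30.0, sigma_unit="kBT/nm2") == pytest.approx(
        8.3e-4, rel=0.01)
    with pytest.raises(ParameterValidationError):
        spontaneous_stretching(0.1, -30.0)


def test_default_parameter_set():
    p = default_parameter_set()
    assert p.ordered.h == 1.8 and p.ordered.km == 20.0
    assert p.disordered.h == 1.3 and p.disordered.km == 10.0
    assert p.ordered.kt == p.disordered.kt == 12.0
    assert p.ordered.J0 == p.disordered.J0 == 0.0
    assert p.system.sigma == pytest.approx(0.02415, rel=1e-3)
    assert p.system.misregistration_density == 0.016
    # derived moduli filled in automatically
    assert p.ordered.C == pytest.approx(12.0 * 1.8**3 / 8.0)
    assert p.peptide.delta_L == 1.3 and p.peptide.Lp == 3.5


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(min_value=1e-6, max_value=1e3),
       st.floats(min_value=100.0, max_value=400.0))
def test_tension_unit_round_trip(sigma, temperature):
    back = tension_kBT_per_nm2_to_mN_per_m(
        tension_mN_per_m_to_kBT_per_nm2(sigma, temperature), temperature)
    assert back == pytest.approx(sigma, rel=1e-12)


def test_phase_validation():
    from memelastic.parameters import PhaseParameters

    with pytest.raises(ParameterValidationError):
        PhaseParameters(phase_label="ordered", h=-1.0, km=20.0)
    with pytest.raises(ParameterValidationError):
        PhaseParameters(phase_label="rafty", h=1.8, km=20.0)
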