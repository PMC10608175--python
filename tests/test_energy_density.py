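"""Energy density cross-checked against an independent symbolic construction."""

import numpy as np
import pytest
import sympy as sp

from memelastic.elastic_core import (
    energy_density,
    misregistration_energy,
    region_model,
)
from memelastic.parameters import default_parameter_set


def _sympy_monolayer_density(phase, leaflet, vals, sigma):
    """Independent transcription of the monolayer density, built in sympy.

    ``vals`` maps (field, order) -> value for n, H of this leaflet and M.
    """
    h = sp.Rational(str(phase.h))

    def v(f, o):
        return sp.Float(vals.get((f, o), 0.0))

    if leaflet == "upper":
        n, H = "n_u", "H_u"
        T = v(n, 0) - v(H, 1)
        alpha = -(h / 2) * v(n, 1) - (v(H, 0) - v("M", 0)) / h
        dalpha = -(h / 2) * v(n, 2) - (v(H, 1) - v("M", 1)) / h
    else:
        n, H = "n_l", "H_l"
        T = v(n, 0) + v(H, 1)
        alpha = -(h / 2) * v(n, 1) + (v(H, 0) - v("M", 0)) / h
        dalpha = -(h / 2) * v(n, 2) + (v(H, 1) - v("M", 1)) / h

    w = (sp.Rational(str(phase.km)) / 2 * v(n, 1) ** 2
         + phase.kt / sp.Integer(2) * T ** 2
         + phase.kc * T * v(n, 2)
         + phase.kgr / 2 * v(n, 2) ** 2
         + phase.kA / 2 * alpha ** 2
         - phase.kc * dalpha ** 2
         + phase.B * T * dalpha
         + phase.C * dalpha * v(n, 2)
         + sigma / 2 * v(H, 1) ** 2)
    return float(w)


MANUFACTURED = {
    ("n_u", 0): 0.11, ("n_u", 1): -0.05, ("n_u", 2): 0.021,
    ("n_l", 0): -0.07, ("n_l", 1): 0.033, ("n_l", 2): -0.012,
    ("H_u", 0): 0.24, ("H_u", 1): 0.065, ("H_l", 0): -0.18,
    ("H_l", 1): -0.042, ("M", 0): 0.09, ("M", 1): 0.017,
}


@pytest.mark.parametrize("pair", [("ordered", "ordered"),
                                  ("disordered", "disordered"),
                                  ("ordered", "disordered")])
def test_density_matches_symbolic_transcription(params, pair):
    up, low = (params.phase(pair[0]), params.phase(pair[1]))
    model = region_model(up, low, params.system.sigma)
    got = energy_density(MANUFACTURED, model)
    want = (_sympy_monolayer_density(up, "upper", MANUFACTURED, params.system.sigma)
            + _sympy_monolayer_density(low, "lower", MANUFACTURED, params.system.sigma))
    assert got == pytest.approx(want, rel=1e-10)


def test_density_zero_for_undeformed_state(params):
    model = region_model(params.ordered, params.ordered, params.system.sigma)
    assert energy_density({}, model) == 0.0


def test_uniform_tilt_costs_only_tilt_energy(params):
    # constant director over flat surfaces: only the kt/2 t0^2 term survives
    model = region_model(params.disordered, params.disordered, params.system.sigma)
    t0 = 0.2
    got = energy_density({("n_u", 0): t0}, model)
    assert got == pytest.approx(0.5 * params.disordered.kt * t0**2, rel=1e-12)


def test_peptide_region_counts_lower_monolayer_only(params):
    model = region_model(None, params.disordered, params.system.sigma)
    # upper-monolayer entries are ignored under the rigid strip
    got = energy_density({("n_u", 0): 0.5, ("n_l", 0): 0.2}, model)
    assert got == pytest.approx(0.5 * params.disordered.kt * 0.04, rel=1e-12)


def test_misregistration_energy():
    assert misregistration_energy(0.0, 0.016) == 0.0
    assert misregistration_energy(2.3, 0.016) == pytest.approx(0.0368)
    assert misregistration_energy(-2.3, 0.016) == pytest.approx(0.0368)
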