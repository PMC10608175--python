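"""Characteristic roots of the per-region Euler-Lagrange system."""

import numpy as np
import pytest
import sympy as sp

from memelastic.elastic_core import region_model
from memelastic.solver import characteristic_roots, phase_basis


@pytest.fixture(scope="module")
def ld_roots(params):
    return characteristic_roots(params.disordered, params.disordered,
                                params.system.sigma)


def test_root_set_is_sign_symmetric(ld_roots):
    # the functional is invariant under x -> -x, so roots come in +- pairs
    nonzero = ld_roots[np.abs(ld_roots) > 1e-6]
    for lam in nonzero:
        assert np.min(np.abs(nonzero + lam)) < 1e-6 * max(1.0, abs(lam))


def test_total_root_count_matches_system_order(ld_roots):
    # n_u, n_l are fourth order; H_u, H_l, M second order: 4+4+2+2+2 = 14
    assert len(ld_roots) == 14


def test_nanometre_branch_slowest_root_magnitude(params):
    """The membrane-scale deformations decay on about 1 nm.

    The root set splits into a nanometre-scale branch and one quasi-rigid
    tension-bending pair (|Re lambda| ~ 0.05/nm at 0.1 mN/m).  The slowest
    member of the nanometre branch has |lambda| of order 1/nm.
    """
    roots = characteristic_roots(params.disordered, params.disordered,
                                 params.system.sigma)
    fast = roots[np.abs(roots.real) > 0.2]
    assert fast.size > 0
    slowest = fast[np.argmin(np.abs(fast.real))]
    assert 0.5 < abs(slowest) < 1.5
    # and the quasi-rigid pair exists at this tension
    soft = roots[(np.abs(roots) > 1e-6) & (np.abs(roots.real) <= 0.2)]
    assert soft.size == 2


def test_modes_satisfy_euler_lagrange(params):
    """Substituting each exponential mode into the EL system gives ~0.

    The EL operator is rebuilt independently with sympy from the density
    written in terms of symbolic field functions.
    """
    model = region_model(params.disordered, params.disordered, params.system.sigma)
    basis = phase_basis(model)

    x = sp.Symbol("x")
    syms = [sp.Function(name)(x) for name in model.fields]

    def val(i, o):
        return sp.diff(syms[i], x, o)

    fields = model.fields
    total = sp.Integer(0)
    for leaflet, phase in (("upper", model.upper), ("lower", model.lower)):
        h = phase.h
        if leaflet == "upper":
            ni, Hi, ts, asg = fields.index("n_u"), fields.index("H_u"), -1, -1
        else:
            ni, Hi, ts, asg = fields.index("n_l"), fields.index("H_l"), +1, +1
        Mi = fields.index("M")
        T = val(ni, 0) + ts * val(Hi, 1)
        A = -(sp.Rational(str(h)) / 2) * val(ni, 1) + asg * (val(Hi, 0) - val(Mi, 0)) / sp.Rational(str(h))
        dA = sp.diff(A, x)
        total += (phase.km / 2 * val(ni, 1) ** 2 + phase.kt / 2 * T ** 2
                  + phase.kc * T * val(ni, 2) + phase.kgr / 2 * val(ni, 2) ** 2
                  + phase.kA / 2 * A ** 2 - phase.kc * dA ** 2
                  + phase.B * T * dA + phase.C * dA * val(ni, 2)
                  + model.sigma / 2 * val(Hi, 1) ** 2)

    # Euler-Lagrange operator for each field
    el = []
    for f in syms:
        expr = (sp.diff(total, f)
                - sp.diff(sp.diff(total, sp.diff(f, x)), x)
                + sp.diff(sp.diff(total, sp.diff(f, x, 2)), x, 2))
        el.append(sp.expand(expr))

    lam_s = sp.Symbol("lam")
    subs_exp = {val(i, o): lam_s ** o for i in range(len(syms)) for o in range(5)}

    checked = 0
    for mode in basis.decay_plus[:4] + basis.decay_minus[:2]:
        lam = complex(mode.lam)
        vec = mode.coeffs[:, 0]
        scale = 0.0
        for i, expr in enumerate(el):
            resid = sp.Integer(0)
            for j, f in enumerate(syms):
                for o in range(5):
                    coef = expr.coeff(sp.diff(f, x, o)) if o else expr.coeff(f)
                    if coef != 0:
                        term = complex(coef) * lam ** o * complex(vec[j])
                        resid += term
                        scale = max(scale, abs(complex(coef) * lam ** o) * np.max(np.abs(vec)))
            assert abs(complex(resid)) < 1e-7 * max(scale, 1.0)
            checked += 1
    assert checked > 0
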