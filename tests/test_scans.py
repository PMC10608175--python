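"""Scan drivers: profile container, refinement, regression of the shift scan."""

import numpy as np
import pytest

from memelastic.scans import (
    EnergyProfile,
    _parabolic_refine,
    fusion_barrier,
    isolated_boundary_optimum,
    line_tension_vs_shift,
    peptide_domain_profile,
)


def test_profile_requires_increasing_grid():
    with pytest.raises(ValueError):
        EnergyProfile("L", [0.0, 0.0, 1.0], [1, 2, 3], 0.0)
    with pytest.raises(ValueError):
        EnergyProfile("L", [], [], 0.0)


def test_parabolic_refinement_finds_quadratic_vertex():
    f = lambda x: (x - 1.234) ** 2 + 0.5
    xs = [0.9, 1.1, 1.5]
    x, y = _parabolic_refine(f, xs, [f(v) for v in xs], "min")
    assert x == pytest.approx(1.234, abs=1e-6)
    assert y == pytest.approx(0.5, abs=1e-10)
    g = lambda x: -((x + 0.4) ** 2) + 2.0
    xs = [-0.9, -0.5, 0.1]
    x, y = _parabolic_refine(g, xs, [g(v) for v in xs], "max")
    assert x == pytest.approx(-0.4, abs=1e-6)


def test_line_tension_scan_locates_symmetric_minima(fig1_profile):
    minima = fig1_profile.minima()
    assert len(minima) == 2
    pos = sorted(m["position"] for m in minima)
    assert pos[0] == pytest.approx(-pos[1], abs=1e-3)
    vals = [m["value"] for m in minima]
    assert vals[0] == pytest.approx(vals[1], rel=1e-6)
    # the profile is an even function of the shift (the conditioning filter
    # in the mirrored wide-strip bases limits agreement to ~1e-5 there)
    E = fig1_profile.energy
    assert np.allclose(E, E[::-1], rtol=1e-4, atol=1e-5)


def test_isolated_optimum_matches_scan(params, fig1_profile):
    L, E = isolated_boundary_optimum(1, params)
    best = min(fig1_profile.minima(), key=lambda m: abs(m["position"] - L))
    assert L == pytest.approx(best["position"], abs=0.02)
    assert E == pytest.approx(best["value"], abs=1e-4)


def test_peptide_profile_reference_subtraction(params):
    """Far in the disordered phase the profile approaches zero."""
    prof = peptide_domain_profile(2.3, np.arange(8.0, 12.01, 0.5), params)
    # residual at 8-12 nm is the slowly-decaying branch tail, well below the
    # well depth scale
    assert np.all(np.abs(prof.energy) < 0.06)


def test_fusion_barrier_on_synthetic_profiles():
    D = np.linspace(1.0, 15.0, 57)
    # monotone non-increasing toward contact -> no barrier
    down = EnergyProfile("D", D, -np.exp(-D), 0.0)
    _, h = fusion_barrier(down)
    assert h == 0.0
    # a bump on a decaying background
    bump = 0.3 * np.exp(-((D - 4.0) ** 2)) + 1e-4 * np.exp(-D)
    prof = EnergyProfile("D", D, bump, 0.0)
    Dstar, h = fusion_barrier(prof)
    assert h == pytest.approx(0.3, rel=0.02)
    assert Dstar == pytest.approx(4.0, abs=0.2)
    # missing plateau raises unless explicitly tolerated
    bad = EnergyProfile("D", D, np.full_like(D, 0.4), 0.0)
    with pytest.raises(ValueError):
        fusion_barrier(bad)
    _, h = fusion_barrier(bad, require_plateau=False)
    assert h == pytest.approx(0.4)
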