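"""Scenario builders: peptide boundary conditions, layouts, topologies."""

import math

import numpy as np
import pytest

from memelastic.configurations import (
    BoundaryTopology,
    ConfigurationError,
    GeometricInfeasibilityError,
    PeptideStrip,
    build_configuration,
    director_jump,
    domain_pair,
    mixed_director_jump,
    single_boundary,
    single_boundary_with_peptide,
)
from memelastic.solver import solve_equilibrium


def test_director_jump_closed_form():
    assert director_jump(1.3, 1.3) == pytest.approx(math.sqrt(2.0), rel=1e-12)
    assert director_jump(1.3, 1.8) == pytest.approx(1.171, abs=5e-4)
    assert director_jump(1e-9, 1.3) == pytest.approx(0.0, abs=1e-8)
    # monotone decreasing in the monolayer thickness
    assert director_jump(1.3, 1.2) > director_jump(1.3, 1.4)


def test_mixed_director_jump():
    js, jd = director_jump(1.3, 1.3), director_jump(1.3, 1.8)
    assert mixed_director_jump(1.0, js, jd) == js
    assert mixed_director_jump(0.0, js, jd) == jd
    assert mixed_director_jump(0.5, js, jd) == pytest.approx((js + jd) / 2)
    assert mixed_director_jump(0.5, js, jd) == pytest.approx(1.293, abs=2e-3)
    with pytest.raises(ConfigurationError):
        mixed_director_jump(1.2, js, jd)


def test_strip_phase_fraction_is_geometric(params):
    # upper edge at x=0: a strip with 30% of its width right of the edge
    X = 0.3 * params.peptide.delta_L
    cfg = single_boundary_with_peptide(2.3, X, params)
    (strip,) = cfg.strips
    assert strip.delta == pytest.approx(0.3, rel=1e-9)
    js, jd = director_jump(1.3, 1.3), director_jump(1.3, 1.8)
    assert strip.jump == pytest.approx(0.3 * js + 0.7 * jd, rel=1e-9)


def test_strip_fraction_is_continuous_in_position(params):
    deltas = [single_boundary_with_peptide(2.3, X, params).strips[0].delta
              for X in np.linspace(-0.4, 1.7, 22)]
    diffs = np.abs(np.diff(deltas))
    assert np.all(diffs < 0.1 * 1.05 / params.peptide.delta_L + 1e-9)


def test_overlapping_strips_rejected(params):
    strips = [PeptideStrip(X0=0.0), PeptideStrip(X0=0.9)]
    with pytest.raises(GeometricInfeasibilityError):
        build_configuration([], ["disordered"], [], ["disordered"],
                            strips, params)


def test_topology_enumeration_counts():
    assert len(BoundaryTopology.enumerate(0)) == 1
    assert len(BoundaryTopology.enumerate(1)) == 4
    assert len(BoundaryTopology.enumerate(2)) == 3
    with pytest.raises(ConfigurationError):
        BoundaryTopology.enumerate(3)


def test_domain_pair_geometric_infeasibility(params):
    with pytest.raises(GeometricInfeasibilityError):
        domain_pair(4.0, BoundaryTopology(1, 1), 2.3, 2.3, params)


def test_domain_pair_additivity_at_large_separation(params):
    """At D = 40 nm the pair energy is the sum of two isolated boundaries."""
    pair = domain_pair(40.0, BoundaryTopology(1, 1), 2.3, 2.3, params)
    e_pair = solve_equilibrium(pair).energy_per_length
    e_iso = solve_equilibrium(single_boundary(-2.3, params)).energy_per_length
    assert e_pair == pytest.approx(2 * e_iso, abs=1e-4)


def test_leaflet_swap_maps_between_shift_sign_pairs(params):
    """Swapping leaflets maps (+,+) at D to (-,-) at the upper-edge distance.

    D is measured between the lower-monolayer edges, so the leaflet-swapped
    partner of a (+,+) configuration is the (-,-) one whose lower-edge
    distance equals the original upper-edge distance.
    """
    D, L = 7.0, 2.0
    e1 = solve_equilibrium(
        domain_pair(D, BoundaryTopology(1, 1), L, L, params)).energy_per_length
    e2 = solve_equilibrium(
        domain_pair(D - 2 * L, BoundaryTopology(-1, -1), -L, -L,
                    params)).energy_per_length
    assert e2 == pytest.approx(e1, rel=1e-8)


def test_misregistration_width_bookkeeping(params):
    cfg = single_boundary(2.3, params)
    assert cfg.misregistration_width == pytest.approx(2.3)
    cfg = domain_pair(8.0, BoundaryTopology(1, -1), 2.0, -1.5, params)
    assert cfg.misregistration_width == pytest.approx(3.5)


def test_regions_tile_the_line(params):
    cfg = single_boundary_with_peptide(0.9, 2.9, params)
    regs = cfg.regions
    assert math.isinf(regs[0].a) and math.isinf(regs[-1].b)
    for left, right in zip(regs, regs[1:]):
        assert left.b == pytest.approx(right.a, abs=1e-12)
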