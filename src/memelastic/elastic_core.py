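"""Quadratic elastic energy density of a bilayer strip in 1D.

Model
-----
Deformations are functions of a single coordinate ``x`` running
perpendicular to the (straight) phase boundary; all energies are per unit
length along the boundary (the ``y`` direction).  Five scalar fields
describe the bilayer:

- ``n_u``, ``n_l`` : x-projections of the lipid directors of the upper and
  lower monolayers (directors point from tail to head, i.e. outward);
- ``H_u``, ``H_l`` : z-coordinates of the monolayer neutral surfaces;
- ``M``            : z-coordinate of the bilayer mid-surface.

Per monolayer the energy density (per unit area) is the quadratic
tilt-splay functional

    w = km/2 (n')^2 + kt/2 T^2 + kc T n'' + kgr/2 (n'')^2
        + kA/2 (alpha - alpha0)^2 - kc (alpha')^2 + B T alpha' + C alpha' n''
        + sigma/2 (H')^2

(spontaneous curvature zero), where the tilt and the stretching-compression
follow from the geometry and monolayer volumetric incompressibility:

    upper:  T_u = n_u - H_u',   alpha_u = -(h/2) n_u' - (H_u - M - h)/h
    lower:  T_l = n_l + H_l',   alpha_l = -(h/2) n_l' + (H_l - M + h)/h

This module works in *deviation* variables: each field is measured relative
to the flat, tension-relaxed reference state of its region (in which
``alpha = alpha0`` everywhere and the energy density is zero), so the
density is a pure quadratic form ``w = 1/2 z^T Q z`` in the 3F-vector
``z = (y, y', y'')`` of the F active fields and their first two
derivatives.  Region reference offsets (which differ between phases and
drive the deformation at phase boundaries) are handled by the solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from memelastic.parameters import PhaseParameters

__all__ = [
    "FULL_FIELDS",
    "LOWER_FIELDS",
    "RegionModel",
    "region_model",
    "energy_density",
    "misregistration_energy",
    "rest_offset",
]

#: Field names of a region with both monolayers elastic.
FULL_FIELDS = ("n_u", "n_l", "H_u", "H_l", "M")
#: Field names under a rigid peptide strip (upper monolayer excluded).
LOWER_FIELDS = ("n_l", "H_l", "M")


def rest_offset(phase: PhaseParameters) -> float:
    """Distance between the neutral surface and the mid-surface at rest.

    Under lateral tension the monolayer is pre-stretched by ``alpha0`` and,
    by volumetric incompressibility, thinner by the same fraction.
    """
    return phase.h * (1.0 - phase.alpha0)


def _monolayer_terms(phase: PhaseParameters, leaflet: str):
    """Quadratic terms of one monolayer as (coef, form_a, form_b) triples.

    Each form is a dict mapping ``(field, derivative_order)`` to its
    coefficient in the linear combination; ``w = sum coef * (a.z)(b.z)``.
    """
    h = phase.h
    if leaflet == "upper":
        n, H, tilt_sign, alpha_sign = "n_u", "H_u", -1.0, -1.0
    elif leaflet == "lower":
        n, H, tilt_sign, alpha_sign = "n_l", "H_l", +1.0, +1.0
    else:
        raise ValueError(leaflet)

    S = {(n, 1): 1.0}
    P = {(n, 2): 1.0}
    T = {(n, 0): 1.0, (H, 1): tilt_sign}
    # alpha deviation: -(h/2) n' -+ (H - M)/h  (sign per leaflet)
    A = {(n, 1): -h / 2.0, (H, 0): alpha_sign / h, ("M", 0): -alpha_sign / h}
    dA = {(n, 2): -h / 2.0, (H, 1): alpha_sign / h, ("M", 1): -alpha_sign / h}
    G = {(H, 1): 1.0}

    return [
        (phase.km / 2.0, S, S),
        (phase.kt / 2.0, T, T),
        (phase.kc, T, P),
        (phase.kgr / 2.0, P, P),
        (phase.kA / 2.0, A, A),
        (-phase.kc, dA, dA),
        (phase.B, T, dA),
        (phase.C, dA, P),
    ]


@dataclass(frozen=True, eq=False)
class RegionModel:
    """Energy quadratic form of one homogeneous region.

    Attributes
    ----------
    fields : tuple of active field names.
    Q : (3F, 3F) symmetric matrix such that the energy density of the
        deviation fields is ``w = 1/2 z^T Q z`` with
        ``z = (y_1..y_F, y_1'..y_F', y_1''..y_F'')``.
    upper, lower : phase parameters (``upper`` is None under a peptide).
    """

    fields: tuple
    Q: np.ndarray
    upper: PhaseParameters | None
    lower: PhaseParameters
    sigma: float

    @property
    def nfields(self) -> int:
        return len(self.fields)

    def zindex(self, field: str, order: int) -> int:
        return order * self.nfields + self.fields.index(field)

    def rest_vector(self) -> np.ndarray:
        """Absolute field values of the region's flat reference state.

        Ordered like ``fields``; the mid-surface rest position is z = 0.
        """
        rest = {"M": 0.0, "n_u": 0.0, "n_l": 0.0}
        if self.upper is not None:
            rest["H_u"] = rest_offset(self.upper)
        rest["H_l"] = -rest_offset(self.lower)
        return np.array([rest[f] for f in self.fields])


@lru_cache(maxsize=64)
def _region_model_cached(upper_key, lower_key, sigma, upper: PhaseParameters,
                         lower: PhaseParameters) -> RegionModel:
    fields = FULL_FIELDS if upper is not None else LOWER_FIELDS
    nf = len(fields)
    Q = np.zeros((3 * nf, 3 * nf))

    def row(form: dict) -> np.ndarray:
        r = np.zeros(3 * nf)
        for (fname, order), coef in form.items():
            r[order * nf + fields.index(fname)] += coef
        return r

    terms = []
    if upper is not None:
        if upper.J0 != 0.0:
            raise NotImplementedError("nonzero spontaneous curvature is not supported")
        terms += _monolayer_terms(upper, "upper")
        terms.append((sigma / 2.0, {("H_u", 1): 1.0}, {("H_u", 1): 1.0}))
    if lower.J0 != 0.0:
        raise NotImplementedError("nonzero spontaneous curvature is not supported")
    terms += _monolayer_terms(lower, "lower")
    terms.append((sigma / 2.0, {("H_l", 1): 1.0}, {("H_l", 1): 1.0}))

    for coef, fa, fb in terms:
        ra, rb = row(fa), row(fb)
        Q += coef * (np.outer(ra, rb) + np.outer(rb, ra))
    # the loop double-counts the symmetric product: w = sum c (a.z)(b.z)
    # corresponds to Q += c (ra rb^T + rb ra^T), i.e. 1/2 z^T Q z doubles
    # diagonal terms correctly; nothing further to do.
    return RegionModel(fields=fields, Q=Q, upper=upper, lower=lower, sigma=sigma)


def region_model(upper: PhaseParameters | None, lower: PhaseParameters,
                 sigma: float) -> RegionModel:
    """Build (and cache) the quadratic energy form of a homogeneous region."""
    ukey = None if upper is None else upper.key
    return _region_model_cached(ukey, lower.key, float(sigma), upper, lower)


def energy_density(values: dict, model: RegionModel) -> float:
    """Evaluate the elastic energy per unit area at one point.

    Parameters
    ----------
    values : dict mapping ``(field, derivative_order)`` -> value of the
        *deviation* field; missing entries are treated as zero.  Fields not
        active in the region (e.g. ``n_u`` under a peptide strip) are
        ignored, implementing the contract that only the lower-monolayer
        terms are evaluated there.
    model : RegionModel built by :func:`region_model`.
    """
    z = np.zeros(3 * model.nfields)
    for (fname, order), v in values.items():
        if fname in model.fields and order <= 2:
            z[model.zindex(fname, order)] = v
    return 0.5 * float(z @ model.Q @ z)


def misregistration_energy(L: float, density: float) -> float:
    """Energy per unit boundary length of a misregistered strip of width |L|.

    A strip in which an ordered monolayer faces a disordered one across the
    bilayer mid-plane costs ``density`` per unit area, i.e.
    ``density * |L|`` per unit boundary length.
    """
    return density * abs(L)
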