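"""Scenario builders: domain boundaries, peptide strips, domain pairs.

Geometry conventions
--------------------
The scan coordinate ``x`` runs perpendicular to the (straight) domain
boundary; ``z`` points up.  Peptides adsorb on the *upper* leaflet only.
For a single boundary (ordered phase on the left) the *upper*-monolayer
Lo/Ld edge sits at ``x = 0`` and the lower edge at ``x = L``, so ``L > 0``
means the lower-leaflet ordered region extends farther toward ``+x`` (the
upper-leaflet domain is the smaller one).  Peptide positions ``X`` are the
right-edge coordinate in the same frame.  For a domain pair, ``D`` is the
edge-to-edge distance between the *lower*-monolayer domain edges (the
registered reference leaflet); each facing edge carries its own signed
shift, positive when the domain is larger in the upper leaflet (the upper
edge extends into the gap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from memelastic.parameters import ParameterSet, PhaseParameters, default_parameter_set

__all__ = [
    "ConfigurationError",
    "RegionSpec",
    "StripSpec",
    "MembraneConfiguration",
    "BoundaryTopology",
    "PeptideStrip",
    "director_jump",
    "mixed_director_jump",
    "build_configuration",
    "single_boundary",
    "isolated_peptide",
    "single_boundary_with_peptide",
    "domain_pair",
]

_MIN_WIDTH = 1e-9   # regions thinner than this are merged away


class ConfigurationError(ValueError):
    """Inconsistent or geometrically infeasible scenario."""


class GeometricInfeasibilityError(ConfigurationError):
    """Requested geometry cannot be realized (e.g. peptides overlap)."""


# ----------------------------------------------------------------------
# peptide boundary conditions


def director_jump(delta_L: float, h: float) -> float:
    """Imposed director jump across a peptide strip in a single phase.

    The directors at the two peptide edges point toward the center of the
    hydrophobic region beneath the helix, giving

        dn_x = delta_L / sqrt((delta_L/2)^2 + (h/2)^2)

    for helix diameter ``delta_L`` and monolayer thickness ``h``.
    """
    if delta_L <= 0 or h <= 0:
        raise ConfigurationError("delta_L and h must be positive")
    return delta_L / math.hypot(delta_L / 2.0, h / 2.0)


def mixed_director_jump(delta: float, jump_s: float, jump_d: float) -> float:
    """Director jump for a strip straddling the phase boundary.

    ``delta`` is the fraction of the strip over the liquid-disordered phase;
    the jump interpolates linearly between the pure-phase values ``jump_s``
    (disordered) and ``jump_d`` (ordered).
    """
    if not 0.0 <= delta <= 1.0:
        raise ConfigurationError(f"phase fraction delta must be in [0, 1], got {delta}")
    return delta * jump_s + (1.0 - delta) * jump_d


@dataclass(frozen=True)
class PeptideStrip:
    """A rigid adsorbed helix on the upper leaflet, centered at X0."""

    X0: float
    delta_L: float = 1.3

    @property
    def xL(self) -> float:
        return self.X0 - self.delta_L / 2.0

    @property
    def xR(self) -> float:
        return self.X0 + self.delta_L / 2.0


# ----------------------------------------------------------------------
# compiled configuration (solver input)


@dataclass(frozen=True)
class RegionSpec:
    a: float
    b: float
    upper: PhaseParameters | None     # None under a peptide strip
    lower: PhaseParameters


@dataclass(frozen=True)
class StripSpec:
    xL: float
    xR: float
    delta: float      # fraction of the strip over the disordered upper phase
    jump: float       # imposed director jump n(xR) - n(xL)
    delta_L: float


@dataclass(eq=False)
class MembraneConfiguration:
    """The full boundary-value problem statement for the solver."""

    regions: list
    strips: list
    sigma: float
    constant_energy: float
    misregistration_width: float
    params: ParameterSet
    #: optionally also match the director derivatives at interfaces
    #: (conforming treatment of the splay-gradient term); the model's
    #: stated interface conditions do not include it
    director_derivative_continuity: bool = False
    #: characteristic roots with |Re lambda| below this cutoff [1/nm] form
    #: the quasi-rigid tension-bending branch (decay length tens of nm at
    #: physiological tension); a positive cutoff excludes them from the
    #: solution basis as a sensitivity experiment.  The default solves the
    #: full functional.
    soft_mode_cutoff: float = 0.0
    #: sensitivity variant: treat the whole membrane beneath each peptide
    #: as rigid (the strip interval carries no elastic fields; the lower
    #: monolayer is linked across it as a rigid plank).  Default: only the
    #: upper monolayer is replaced by the peptide, the lower one deforms.
    freeze_lower_under_peptide: bool = False


# ----------------------------------------------------------------------
# layout compiler


class _Layout:
    """Piecewise-constant phase assignment of one monolayer."""

    def __init__(self, breaks, labels):
        if len(labels) != len(breaks) + 1:
            raise ConfigurationError("need one more phase label than breakpoints")
        if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
            raise ConfigurationError("breakpoints must be strictly increasing")
        self.breaks = list(breaks)
        self.labels = list(labels)

    def label_at(self, x: float) -> str:
        i = sum(1 for b in self.breaks if b <= x)
        return self.labels[i]

    def intervals_of(self, label: str):
        """Intervals carrying a given phase label, as (a, b) pairs."""
        edges = [-math.inf] + self.breaks + [math.inf]
        return [(edges[i], edges[i + 1]) for i, lab in enumerate(self.labels)
                if lab == label]


def _overlap_fraction(xL: float, xR: float, intervals) -> float:
    total = 0.0
    for a, b in intervals:
        total += max(0.0, min(xR, b) - max(xL, a))
    return total / (xR - xL)


def build_configuration(
    upper_breaks, upper_labels, lower_breaks, lower_labels,
    strips, params: ParameterSet, *,
    include_misregistration: bool = True,
    extra_constant_energy: float = 0.0,
    freeze_lower_under_peptide: bool = False,
) -> MembraneConfiguration:
    """Compile monolayer phase layouts and peptide strips into solver input."""
    upper = _Layout(upper_breaks, upper_labels)
    lower = _Layout(lower_breaks, lower_labels)

    strips = sorted(strips, key=lambda s: s.X0)
    for s1, s2 in zip(strips, strips[1:]):
        if s2.xL < s1.xR - _MIN_WIDTH:
            raise GeometricInfeasibilityError(
                f"peptide strips at X0={s1.X0} and X0={s2.X0} overlap")

    pep = params.peptide
    strip_specs = []
    dis_intervals = upper.intervals_of("disordered")
    for s in strips:
        if s.delta_L != pep.delta_L:
            raise ConfigurationError("strip width differs from the peptide parameters")
        delta = _overlap_fraction(s.xL, s.xR, dis_intervals)
        js = director_jump(pep.delta_L, params.disordered.h)
        jd = director_jump(pep.delta_L, params.ordered.h)
        strip_specs.append(StripSpec(xL=s.xL, xR=s.xR, delta=delta,
                                     jump=mixed_director_jump(delta, js, jd),
                                     delta_L=pep.delta_L))

    # breakpoints: all phase edges and strip edges; upper phase edges strictly
    # inside a strip do not bound a region (the upper monolayer is absent there)
    def _inside_strip(x: float) -> bool:
        return any(s.xL + _MIN_WIDTH < x < s.xR - _MIN_WIDTH for s in strip_specs)

    raw_pts = sorted(
        [b for b in upper.breaks if not _inside_strip(b)]
        + list(lower.breaks)
        + [v for s in strip_specs for v in (s.xL, s.xR)]
    )
    pts = []
    for p in raw_pts:  # merge near-coincident breakpoints
        if not pts or p - pts[-1] > _MIN_WIDTH:
            pts.append(p)
    edges = [-math.inf] + pts + [math.inf]

    regions = []
    misreg = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < _MIN_WIDTH:
            continue
        xm = 0.5 * (a + b) if math.isfinite(a) and math.isfinite(b) else (
            b - 1.0 if math.isinf(a) else a + 1.0)
        under_strip = any(s.xL - _MIN_WIDTH <= a and b <= s.xR + _MIN_WIDTH
                          for s in strip_specs)
        up = None if under_strip else params.phase(upper.label_at(xm))
        lowp = params.phase(lower.label_at(xm))
        if up is not None and up.phase_label != lowp.phase_label:
            misreg += b - a
        if regions and regions[-1].upper is up and regions[-1].lower is lowp:
            regions[-1] = RegionSpec(a=regions[-1].a, b=b, upper=up, lower=lowp)
        else:
            regions.append(RegionSpec(a=a, b=b, upper=up, lower=lowp))

    const = extra_constant_energy
    if include_misregistration:
        const += params.system.misregistration_density * misreg

    if freeze_lower_under_peptide:
        regions = [r for r in regions if r.upper is not None]

    return MembraneConfiguration(
        regions=regions, strips=strip_specs, sigma=params.system.sigma,
        constant_energy=const, misregistration_width=misreg, params=params,
        freeze_lower_under_peptide=freeze_lower_under_peptide)


# ----------------------------------------------------------------------
# scenario builders


def single_boundary(L: float, params: ParameterSet | None = None, *,
                    ordered_side: str = "left",
                    include_misregistration: bool = True) -> MembraneConfiguration:
    """A single Lo/Ld boundary with relative monolayer shift ``L``.

    The ordered phase occupies the left half-line.  The upper-monolayer
    edge is at x = 0 and the lower edge at x = L, so ``L > 0`` means the
    *lower*-leaflet ordered region extends farther toward +x.  A strip of
    width ``|L|`` where an ordered monolayer faces a disordered one carries
    the misregistration penalty.
    """
    params = params or default_parameter_set()
    if ordered_side not in ("left", "right"):
        raise ConfigurationError("ordered_side must be 'left' or 'right'")
    labels = ["ordered", "disordered"] if ordered_side == "left" else \
             ["disordered", "ordered"]
    return build_configuration([0.0], labels, [L], labels, [], params,
                               include_misregistration=include_misregistration)


def isolated_peptide(phase_label: str, params: ParameterSet | None = None,
                     X0: float = 0.0, *,
                     freeze_lower_under_peptide: bool = False) -> MembraneConfiguration:
    """A single peptide strip on a homogeneous membrane of the given phase."""
    params = params or default_parameter_set()
    strip = PeptideStrip(X0=X0, delta_L=params.peptide.delta_L)
    return build_configuration([], [phase_label], [], [phase_label],
                               [strip], params,
                               freeze_lower_under_peptide=freeze_lower_under_peptide)


def single_boundary_with_peptide(
    L: float, X: float, params: ParameterSet | None = None, *,
    include_misregistration: bool = True,
    freeze_lower_under_peptide: bool = False,
) -> MembraneConfiguration:
    """Single boundary (shift ``L``) plus a peptide with *right edge* at ``X``.

    ``X`` is measured from the upper-monolayer domain edge (x = 0, the
    leaflet the peptide adsorbs on); the lower edge sits at x = L.  The
    peptide phase fraction ``delta`` follows from the geometric overlap of
    the strip with the upper-monolayer disordered region (x > 0).
    """
    params = params or default_parameter_set()
    strip = PeptideStrip(X0=X - params.peptide.delta_L / 2.0,
                         delta_L=params.peptide.delta_L)
    return build_configuration([0.0], ["ordered", "disordered"],
                               [L], ["ordered", "disordered"],
                               [strip], params,
                               include_misregistration=include_misregistration,
                               freeze_lower_under_peptide=freeze_lower_under_peptide)


@dataclass(frozen=True)
class BoundaryTopology:
    """Discrete label of a two-domain configuration.

    ``left_sign``/``right_sign`` are +1 when that domain is larger in the
    upper leaflet at its facing boundary (the upper Lo edge extends into the
    gap), -1 otherwise.  ``peptide_sides`` lists the facing boundaries
    occupied by a peptide ("left" and/or "right").
    """

    left_sign: int
    right_sign: int
    peptide_sides: tuple = ()

    def __post_init__(self):
        if self.left_sign not in (-1, 1) or self.right_sign not in (-1, 1):
            raise ConfigurationError("shift signs must be +1 or -1")
        if any(s not in ("left", "right") for s in self.peptide_sides):
            raise ConfigurationError("peptide_sides entries must be 'left'/'right'")

    @property
    def peptide_count(self) -> int:
        return len(self.peptide_sides)

    @staticmethod
    def enumerate(peptide_count: int):
        """Non-equivalent topologies for 0, 1 or 2 peptides.

        With no peptides the four sign combinations are energy-equivalent;
        one representative is returned.  One peptide (at the right facing
        boundary, by convention) breaks both mirror and leaflet-swap
        symmetry: four topologies.  Two peptides retain the mirror symmetry
        that identifies (+,-) with (-,+): three topologies.
        """
        if peptide_count == 0:
            return [BoundaryTopology(1, 1)]
        if peptide_count == 1:
            return [BoundaryTopology(s1, s2, ("right",))
                    for s1 in (1, -1) for s2 in (1, -1)]
        if peptide_count == 2:
            return [BoundaryTopology(1, 1, ("left", "right")),
                    BoundaryTopology(-1, -1, ("left", "right")),
                    BoundaryTopology(1, -1, ("left", "right"))]
        raise ConfigurationError("peptide_count must be 0, 1 or 2")


def domain_pair(
    D: float,
    topology: BoundaryTopology,
    L_left: float,
    L_right: float,
    params: ParameterSet | None = None,
    peptide_positions: dict | None = None,
    *,
    include_misregistration: bool = True,
) -> MembraneConfiguration:
    """Two ordered domains separated by a disordered gap of width ``D``.

    The domains are half-infinite (their far boundaries do not interact
    with the gap): the lower-monolayer edges sit at -D/2 and +D/2 and the
    upper edges at -D/2 + L_left and +D/2 - L_right, with the shift
    magnitudes signed by the topology (positive = upper leaflet larger,
    extending into the gap).  ``peptide_positions`` maps "left"/"right" to
    the strip center X0 for each occupied boundary.
    """
    params = params or default_parameter_set()
    if D < 0:
        raise ConfigurationError("domain separation D must be >= 0")
    if np.sign(L_left) not in (0, topology.left_sign) or \
       np.sign(L_right) not in (0, topology.right_sign):
        raise ConfigurationError("shift signs inconsistent with the topology")

    uL = -D / 2.0 + L_left
    uR = +D / 2.0 - L_right
    if uR - uL < _MIN_WIDTH:
        raise GeometricInfeasibilityError(
            f"upper-monolayer gap closed (D={D}, L_left={L_left}, L_right={L_right})")

    peptide_positions = peptide_positions or {}
    strips = []
    for side in topology.peptide_sides:
        if side not in peptide_positions:
            raise ConfigurationError(f"missing peptide position for side {side!r}")
        strips.append(PeptideStrip(X0=peptide_positions[side],
                                   delta_L=params.peptide.delta_L))
    labels = ["ordered", "disordered", "ordered"]
    return build_configuration(
        [uL, uR], labels, [-D / 2.0, D / 2.0], labels, strips, params,
        include_misregistration=include_misregistration)
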