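"""Closed-form estimates converting per-length energetics to absolute scales.

The 1D solver reports energies per unit length of the (straight) domain
boundary.  For a circular domain of radius ``R`` the deformation overlap
zone along the rim has an effective length ``2 sqrt(2 lambda R)``, where
``lambda ~ 1 nm`` is the decay length of the membrane deformations;
multiplying a per-length barrier by this length gives the absolute energy
in k_B*T.  A peptide of helix length ``Lp`` perturbs the membrane over an
effective length ``1.3 Lp``, which converts the boundary well depth per
unit length into an absolute binding energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "RaftGeometry",
    "effective_interaction_length",
    "peptide_concentration_full_boundary",
    "absolute_well_depth",
    "absolute_fusion_barrier",
]

#: Ratio of the effective peptide deformation length to the helix length.
PEPTIDE_DEFORMATION_FACTOR = 1.3


def _require_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class RaftGeometry:
    """Geometry of a raft-forming membrane for concentration estimates."""

    R: float            # mean domain radius [nm]
    phi_d: float        # area fraction of the ordered phase [0..1]
    a_L: float = 0.6    # mean area per lipid [nm^2]
    A0: float | None = None  # total membrane area [nm^2]; cancels in ratios

    def __post_init__(self) -> None:
        _require_positive(R=self.R, a_L=self.a_L)
        if not 0.0 < self.phi_d < 1.0:
            raise ValueError(f"phi_d must be in (0, 1), got {self.phi_d}")
        if self.A0 is not None:
            _require_positive(A0=self.A0)


def effective_interaction_length(lambda_decay: float, R: float) -> float:
    """Effective rim length 2*sqrt(2*lambda*R) of the domain-domain overlap [nm]."""
    _require_positive(lambda_decay=lambda_decay, R=R)
    return 2.0 * math.sqrt(2.0 * lambda_decay * R)


def peptide_concentration_full_boundary(geom: RaftGeometry, Lp: float) -> float:
    """Peptide/lipid ratio P/L that saturates every domain boundary.

    With N_d = phi_d A0 / (pi R^2) domains, total rim length 2 pi R N_d and
    one peptide per helix length Lp of rim, against A0/a_L lipids (single
    leaflet, the one the peptides adsorb on):

        P/L = 2 a_L phi_d / (Lp R).

    The total area A0 cancels.
    """
    _require_positive(Lp=Lp)
    return 2.0 * geom.a_L * geom.phi_d / (Lp * geom.R)


def absolute_well_depth(well_per_length: float, Lp: float) -> float:
    """Absolute boundary-well depth [k_B*T] for a peptide of helix length Lp.

    The per-length depth is integrated over the effective deformation
    length 1.3*Lp of the adsorbed helix.
    """
    _require_positive(Lp=Lp)
    if well_per_length < 0:
        raise ValueError("well depth per length must be >= 0")
    return well_per_length * PEPTIDE_DEFORMATION_FACTOR * Lp


def absolute_fusion_barrier(barrier_per_length: float, lambda_decay: float,
                            R: float) -> float:
    """Absolute coalescence barrier [k_B*T] for domains of radius R."""
    if barrier_per_length < 0:
        raise ValueError("barrier per length must be >= 0")
    return barrier_per_length * effective_interaction_length(lambda_decay, R)
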