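"""Elastic parameters of the two lipid phases and derived moduli.

Internal unit system
--------------------
Energies are measured in units of the thermal energy k_B*T at T = 300 K and
lengths in nm, so that energy densities are k_B*T/nm^2 and per-length
energies are k_B*T/nm.  Lateral tension given in mN/m is converted on
ingestion.  The conversion constant is fixed at

    k_B*T = 4.141e-21 J   (T = 300 K),

so 0.1 mN/m = 0.02415 k_B*T/nm^2.

Higher-order moduli
-------------------
The quadratic monolayer energy functional couples tilt, splay, the splay
gradient and the gradient of stretching-compression.  The four cross moduli
are not independent material constants: for a monolayer of hydrophobic
thickness ``h`` and tilt modulus ``kt`` they follow from the microscopic
derivation of the functional as closed forms,

    kc  = -kt h^2 / 6       (splay-tilt cross modulus,     k_B*T)
    kgr =  kt h^4 / 20      (splay-gradient modulus,       k_B*T nm^2)
    B   = -kt h / 2         (tilt / stretch-gradient,      k_B*T / nm)
    C   =  kt h^3 / 8       (stretch-gradient / splay,     k_B*T nm)

and are filled in automatically unless explicitly overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

__all__ = [
    "KBT_JOULE",
    "PhaseParameters",
    "SystemConstants",
    "PeptideParameters",
    "ParameterSet",
    "ParameterValidationError",
    "derive_higher_moduli",
    "spontaneous_stretching",
    "default_parameter_set",
    "tension_mN_per_m_to_kBT_per_nm2",
    "tension_kBT_per_nm2_to_mN_per_m",
]

#: Thermal energy at T = 300 K in joules; fixes the mN/m -> k_B T/nm^2 conversion.
KBT_JOULE = 4.141e-21

PhaseLabel = Literal["ordered", "disordered"]


class ParameterValidationError(ValueError):
    """A physical parameter violates its admissibility constraints."""


def tension_mN_per_m_to_kBT_per_nm2(sigma_mN_per_m: float, temperature: float = 300.0) -> float:
    """Convert a lateral tension from mN/m to k_B*T/nm^2.

    1 mN/m = 1e-3 J/m^2 = 1e-21 J/nm^2.  The thermal energy scales linearly
    with absolute temperature relative to the 300 K reference constant.
    """
    kbt = KBT_JOULE * temperature / 300.0
    return sigma_mN_per_m * 1e-21 / kbt


def tension_kBT_per_nm2_to_mN_per_m(sigma_kBT_per_nm2: float, temperature: float = 300.0) -> float:
    """Inverse of :func:`tension_mN_per_m_to_kBT_per_nm2`."""
    kbt = KBT_JOULE * temperature / 300.0
    return sigma_kBT_per_nm2 * kbt / 1e-21


def derive_higher_moduli(kt: float, h: float) -> dict[str, float]:
    """Closed-form higher-order moduli from the tilt modulus and thickness.

    Parameters
    ----------
    kt : float
        Tilt modulus [k_B*T/nm^2]; must be positive.
    h : float
        Monolayer hydrophobic thickness [nm]; must be non-negative
        (``h = 0`` is the degenerate zero-thickness limit, all moduli zero).

    Returns
    -------
    dict with keys ``kc``, ``kgr``, ``B``, ``C``.
    """
    if kt <= 0:
        raise ParameterValidationError(f"tilt modulus kt must be positive, got {kt}")
    if h < 0:
        raise ParameterValidationError(f"monolayer thickness h must be non-negative, got {h}")
    return {
        "kc": -kt * h**2 / 6.0,
        "kgr": kt * h**4 / 20.0,
        "B": -kt * h / 2.0,
        "C": kt * h**3 / 8.0,
    }


def spontaneous_stretching(
    sigma: float,
    kA: float,
    temperature: float = 300.0,
    sigma_unit: Literal["mN/m", "kBT/nm2"] = "mN/m",
) -> float:
    """Spontaneous stretching-compression alpha0 = sigma / kA (dimensionless).

    Under a lateral tension ``sigma`` the relaxed, flat monolayer is
    pre-stretched by ``alpha0``; the elastic energy is measured relative to
    this pre-stretched state.
    """
    if kA <= 0:
        raise ParameterValidationError(f"stretching modulus kA must be positive, got {kA}")
    if sigma_unit == "mN/m":
        sigma = tension_mN_per_m_to_kBT_per_nm2(sigma, temperature)
    elif sigma_unit != "kBT/nm2":
        raise ParameterValidationError(f"unknown tension unit {sigma_unit!r}")
    return sigma / kA


@dataclass(frozen=True)
class PhaseParameters:
    """Elastic constants of one monolayer phase (liquid-ordered or -disordered).

    All moduli are per monolayer.  ``kc``, ``kgr``, ``B``, ``C`` default to
    the closed forms of :func:`derive_higher_moduli`; ``alpha0`` defaults to
    ``sigma/kA`` and is normally filled by :class:`ParameterSet`.
    """

    phase_label: PhaseLabel
    h: float                  # hydrophobic thickness [nm]
    km: float                 # bending modulus [kBT]
    kt: float = 12.0          # tilt modulus [kBT/nm^2]
    kA: float = 30.0          # stretching-compression modulus [kBT/nm^2]
    J0: float = 0.0           # spontaneous curvature [1/nm]
    kc: float = None          # splay-tilt cross modulus [kBT]
    kgr: float = None         # splay-gradient modulus [kBT nm^2]
    B: float = None           # tilt / stretch-gradient modulus [kBT/nm]
    C: float = None           # stretch-gradient / splay modulus [kBT nm]
    alpha0: float = 0.0       # spontaneous stretching-compression [-]

    def __post_init__(self) -> None:
        if self.phase_label not in ("ordered", "disordered"):
            raise ParameterValidationError(f"unknown phase label {self.phase_label!r}")
        for name in ("h", "km", "kt", "kA"):
            if getattr(self, name) <= 0:
                raise ParameterValidationError(
                    f"{name} must be positive for phase {self.phase_label!r}, "
                    f"got {getattr(self, name)}"
                )
        derived = derive_higher_moduli(self.kt, self.h)
        for name in ("kc", "kgr", "B", "C"):
            if getattr(self, name) is None:
                object.__setattr__(self, name, derived[name])
        if self.kgr < 0:
            raise ParameterValidationError("kgr must be non-negative")

    def with_(self, **kwargs) -> "PhaseParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def key(self) -> tuple:
        """Hashable identity used for caching solver factorizations."""
        return (self.phase_label, self.h, self.km, self.kt, self.kA, self.J0,
                self.kc, self.kgr, self.B, self.C, self.alpha0)


@dataclass(frozen=True)
class SystemConstants:
    """Bilayer-level constants shared by both phases."""

    sigma: float = 0.0                   # lateral tension per monolayer [kBT/nm^2]
    misregistration_density: float = 0.016  # energy per misregistered area [kBT/nm^2]
    temperature: float = 300.0           # [K]

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ParameterValidationError("lateral tension sigma must be >= 0")
        if self.misregistration_density < 0:
            raise ParameterValidationError("misregistration density must be >= 0")
        if self.temperature <= 0:
            raise ParameterValidationError("temperature must be positive")


@dataclass(frozen=True)
class PeptideParameters:
    """Geometry of the adsorbed alpha-helical amphipathic peptide."""

    delta_L: float = 1.3   # alpha-helix diameter [nm]
    Lp: float = 3.5        # helix length [nm]

    def __post_init__(self) -> None:
        if self.delta_L <= 0:
            raise ParameterValidationError("helix diameter delta_L must be positive")
        if self.Lp <= 0:
            raise ParameterValidationError("helix length Lp must be positive")


@dataclass(frozen=True)
class ParameterSet:
    """Complete parameterization: both phases, system constants, peptide."""

    ordered: PhaseParameters
    disordered: PhaseParameters
    system: SystemConstants = field(default_factory=SystemConstants)
    peptide: PeptideParameters = field(default_factory=PeptideParameters)

    def __post_init__(self) -> None:
        if self.ordered.phase_label != "ordered":
            raise ParameterValidationError("'ordered' slot must hold the ordered phase")
        if self.disordered.phase_label != "disordered":
            raise ParameterValidationError("'disordered' slot must hold the disordered phase")

    def phase(self, label: PhaseLabel) -> PhaseParameters:
        return self.ordered if label == "ordered" else self.disordered


def default_parameter_set(
    sigma_mN_per_m: float = 0.1,
    temperature: float = 300.0,
) -> ParameterSet:
    """The default parameterization of the two-phase bilayer.

    Liquid-ordered (raft) phase: h = 1.8 nm, km = 20 k_B*T; liquid-disordered
    phase: h = 1.3 nm, km = 10 k_B*T.  Both phases share kt = 12 k_B*T/nm^2,
    kA = 30 k_B*T/nm^2, J0 = 0 and a lateral tension of 0.1 mN/m per
    monolayer; the monolayer misregistration penalty is 0.016 k_B*T/nm^2.
    Higher-order moduli and alpha0 are filled in from their closed forms.
    """
    sigma = tension_mN_per_m_to_kBT_per_nm2(sigma_mN_per_m, temperature)
    alpha0 = sigma / 30.0
    ordered = PhaseParameters(phase_label="ordered", h=1.8, km=20.0, alpha0=alpha0)
    disordered = PhaseParameters(phase_label="disordered", h=1.3, km=10.0, alpha0=alpha0)
    system = SystemConstants(sigma=sigma, temperature=temperature)
    return ParameterSet(ordered=ordered, disordered=disordered, system=system,
                        peptide=PeptideParameters())
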