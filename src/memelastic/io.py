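"""Configuration loading and result serialization.

The parameter file is a flat YAML mapping with explicit unit suffixes, so
that the two tension conventions (mN/m vs k_B*T/nm^2) can never be
silently confused::

    ordered.h_nm: 1.8
    ordered.km_kBT: 20.0
    disordered.h_nm: 1.3
    disordered.km_kBT: 10.0
    system.sigma_mN_per_m: 0.1
    system.misregistration_kBT_per_nm2: 0.016
    peptide.delta_L_nm: 1.3
    peptide.Lp_nm: 3.5

Omitted keys fall back to the defaults; higher-order moduli are derived
from their closed forms unless explicitly overridden (a user override that
disagrees with its own kt and h by more than 5% logs a warning and wins).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from memelastic.parameters import (
    ParameterSet,
    ParameterValidationError,
    PeptideParameters,
    PhaseParameters,
    SystemConstants,
    default_parameter_set,
    derive_higher_moduli,
)
from memelastic.scans import EnergyProfile

__all__ = ["load_config", "write_profile", "read_profile", "RunRecord"]

logger = logging.getLogger("memelastic")

_PHASE_KEYS = {
    "h_nm": "h", "km_kBT": "km", "kt_kBT_per_nm2": "kt",
    "kA_kBT_per_nm2": "kA", "J0_per_nm": "J0", "kc_kBT": "kc",
    "kgr_kBT_nm2": "kgr", "B_kBT_per_nm": "B", "C_kBT_nm": "C",
}
_SYSTEM_KEYS = {
    "sigma_mN_per_m": "sigma_mN_per_m",
    "misregistration_kBT_per_nm2": "misregistration_density",
    "temperature_K": "temperature",
}
_PEPTIDE_KEYS = {"delta_L_nm": "delta_L", "Lp_nm": "Lp"}


def load_config(path) -> ParameterSet:
    """Load a flat key-value parameter file into a :class:`ParameterSet`.

    Unknown keys are rejected; all values must carry the expected unit
    suffix in the key name.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParameterValidationError("config must be a flat key-value mapping")

    phases = {"ordered": {}, "disordered": {}}
    system: dict = {}
    peptide: dict = {}
    for key, value in raw.items():
        try:
            prefix, name = key.split(".", 1)
        except ValueError:
            raise ParameterValidationError(f"malformed key {key!r} (expected prefix.name)")
        if prefix in phases:
            if name not in _PHASE_KEYS:
                raise ParameterValidationError(
                    f"unknown or unit-less phase key {key!r}; expected one of "
                    f"{sorted(_PHASE_KEYS)}")
            phases[prefix][_PHASE_KEYS[name]] = float(value)
        elif prefix == "system":
            if name not in _SYSTEM_KEYS:
                raise ParameterValidationError(f"unknown system key {key!r}")
            system[_SYSTEM_KEYS[name]] = float(value)
        elif prefix == "peptide":
            if name not in _PEPTIDE_KEYS:
                raise ParameterValidationError(f"unknown peptide key {key!r}")
            peptide[_PEPTIDE_KEYS[name]] = float(value)
        else:
            raise ParameterValidationError(f"unknown section {prefix!r} in key {key!r}")

    defaults = default_parameter_set(
        sigma_mN_per_m=system.pop("sigma_mN_per_m", 0.1),
        temperature=system.get("temperature", 300.0),
    )
    sigma = defaults.system.sigma
    sysconst = SystemConstants(
        sigma=sigma,
        misregistration_density=system.get(
            "misregistration_density", defaults.system.misregistration_density),
        temperature=system.get("temperature", 300.0),
    )

    built = {}
    for label in ("ordered", "disordered"):
        base = dataclasses.asdict(getattr(defaults, label))
        overrides = phases[label]
        kt = overrides.get("kt", base["kt"])
        h = overrides.get("h", base["h"])
        derived = derive_higher_moduli(kt, h)
        fields = dict(base)
        # rederive higher moduli for the (possibly overridden) kt and h
        fields.update(derived)
        fields.update(overrides)
        fields["alpha0"] = sigma / fields["kA"]
        for name in ("kc", "kgr", "B", "C"):
            if name in overrides and derived[name] != 0:
                rel = abs(overrides[name] - derived[name]) / abs(derived[name])
                if rel > 0.05:
                    logger.warning(
                        "%s.%s=%g differs by %.0f%% from its closed form %g "
                        "(kt=%g, h=%g); the explicit value wins",
                        label, name, overrides[name], 100 * rel, derived[name], kt, h)
        built[label] = PhaseParameters(**fields)

    pep = PeptideParameters(**{**dataclasses.asdict(defaults.peptide), **peptide})
    return ParameterSet(ordered=built["ordered"], disordered=built["disordered"],
                        system=sysconst, peptide=pep)


def write_profile(profile: EnergyProfile, path) -> Path:
    """Write an energy profile as a TSV table plus a JSON summary sidecar.

    The table holds one row per grid point (abscissa [nm], energy
    [kBT/nm]); the sidecar records the abscissa name, the subtracted
    reference and the located extrema.  Returns the table path.
    """
    if profile.grid.size == 0:
        raise ValueError("refusing to write an empty profile")
    path = Path(path)
    df = pd.DataFrame({
        f"{profile.abscissa_name}_nm": profile.grid,
        "energy_kBT_per_nm": profile.energy,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {k: v for k, v in profile.meta.items() if _jsonable(v)}
    sidecar.write_text(json.dumps({
        "abscissa": profile.abscissa_name,
        "reference_kBT_per_nm": profile.reference,
        "truncated": profile.truncated,
        "extrema": profile.extrema,
        "meta": meta,
    }, indent=2, default=str))
    return path


def _jsonable(v) -> bool:
    return isinstance(v, (int, float, str, bool, type(None)))


def read_profile(path) -> EnergyProfile:
    """Round-trip reader for :func:`write_profile` output."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid_col = [c for c in df.columns if c.endswith("_nm")][0]
    prof = EnergyProfile(
        abscissa_name=sidecar["abscissa"],
        grid=df[grid_col].to_numpy(),
        energy=df["energy_kBT_per_nm"].to_numpy(),
        reference=sidecar["reference_kBT_per_nm"],
        truncated=sidecar["truncated"],
        meta=sidecar.get("meta", {}),
    )
    prof.extrema = sidecar["extrema"]
    return prof


@dataclasses.dataclass
class RunRecord:
    """Reproducibility record of one CLI invocation."""

    command: str
    config_snapshot: dict
    outputs: list
    summary: dict
    version: str

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        return path


def parameter_snapshot(params: ParameterSet) -> dict:
    """Fully resolved parameter values, for run records."""
    return {
        "ordered": dataclasses.asdict(params.ordered),
        "disordered": dataclasses.asdict(params.disordered),
        "system": dataclasses.asdict(params.system),
        "peptide": dataclasses.asdict(params.peptide),
    }
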