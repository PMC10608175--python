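"""Parameter scans: line tension, peptide-boundary profiles, fusion barriers.

All drivers are deterministic: grids plus local parabolic refinement, no
stochastic search.  Nuisance variables (monolayer shifts, peptide
positions) are minimized at every scan point with warm starts from the
neighboring point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from memelastic.configurations import (
    BoundaryTopology,
    GeometricInfeasibilityError,
    domain_pair,
    isolated_peptide,
    single_boundary,
    single_boundary_with_peptide,
)
from memelastic.parameters import ParameterSet, default_parameter_set
from memelastic.solver import solve_equilibrium

__all__ = [
    "EnergyProfile",
    "JointMinimum",
    "line_tension_vs_shift",
    "peptide_domain_profile",
    "joint_minimum_peptide_shift",
    "interaction_profile",
    "fusion_barrier",
    "isolated_boundary_optimum",
]

_PENALTY = 1e3  # energy surrogate outside the feasible geometry


@dataclass
class EnergyProfile:
    """A scanned energy curve with located extrema.

    ``energy`` is per unit boundary length [kBT/nm], measured relative to
    ``reference`` (already subtracted).
    """

    abscissa_name: str            # "L", "X" or "D"
    grid: np.ndarray              # strictly increasing sample points [nm]
    energy: np.ndarray            # E - reference [kBT/nm]
    reference: float              # subtracted reference energy [kBT/nm]
    extrema: list = field(default_factory=list)
    truncated: bool = False       # scan cut short by geometric infeasibility
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.grid.size == 0:
            raise ValueError("empty profile grid")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("profile grid must be strictly increasing")

    def minima(self):
        return [e for e in self.extrema if e["kind"] == "min"]

    def maxima(self):
        return [e for e in self.extrema if e["kind"] == "max"]


def _parabolic_refine(f, xs, ys, kind: str, iters: int = 4):
    """Refine a bracketed extremum by successive parabolic interpolation.

    ``xs``/``ys`` are three points bracketing the extremum; ``f`` is called
    for new trial points.  Returns (x*, f(x*)).
    """
    xs, ys = list(xs), list(ys)
    sgn = 1.0 if kind == "min" else -1.0
    for _ in range(iters):
        (x0, x1, x2), (y0, y1, y2) = xs, ys
        denom = (x0 - x1) * (y1 - y2) - (x1 - x2) * (y0 - y1)
        if abs(denom) < 1e-14:
            break
        xv = x1 - 0.5 * (((x1 - x0) ** 2 * (y1 - y2)
                          - (x1 - x2) ** 2 * (y1 - y0))
                         / ((x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)))
        if not (min(xs) < xv < max(xs)) or any(abs(xv - x) < 1e-10 for x in xs):
            break
        yv = f(xv)
        pts = sorted(zip(xs + [xv], ys + [yv]))
        best = min(range(4), key=lambda i: sgn * pts[i][1])
        lo, hi = max(0, min(best - 1, 1)), min(4, max(best + 2, 3))
        if best == 0:
            lo, hi = 0, 3
        elif best == 3:
            lo, hi = 1, 4
        else:
            lo, hi = best - 1, best + 2
        xs = [p[0] for p in pts[lo:hi]]
        ys = [p[1] for p in pts[lo:hi]]
    i = min(range(3), key=lambda k: sgn * ys[k])
    return xs[i], ys[i]


def _locate_extrema(f, grid, values, kinds=("min", "max")):
    out = []
    for i in range(1, len(grid) - 1):
        y0, y1, y2 = values[i - 1], values[i], values[i + 1]
        if "min" in kinds and y1 < y0 and y1 <= y2:
            x, y = _parabolic_refine(f, grid[i - 1:i + 2], [y0, y1, y2], "min")
            out.append({"kind": "min", "position": float(x), "value": float(y)})
        elif "max" in kinds and y1 > y0 and y1 >= y2:
            x, y = _parabolic_refine(f, grid[i - 1:i + 2], [y0, y1, y2], "max")
            out.append({"kind": "max", "position": float(x), "value": float(y)})
    return out


# ----------------------------------------------------------------------
# single boundary


def line_tension_vs_shift(L_grid=None, params: ParameterSet | None = None, *,
                          include_misregistration: bool = True) -> EnergyProfile:
    """Elastic line-tension contribution vs the relative monolayer shift L.

    Solves the single-boundary problem on the grid (default [-5, 5] nm,
    0.05 nm step) and refines the two symmetric minima.
    """
    params = params or default_parameter_set()
    if L_grid is None:
        L_grid = np.arange(-5.0, 5.0001, 0.05)
    L_grid = np.asarray(L_grid, dtype=float)

    def f(L):
        cfg = single_boundary(L, params,
                              include_misregistration=include_misregistration)
        return solve_equilibrium(cfg).energy_per_length

    E = np.array([f(L) for L in L_grid])
    prof = EnergyProfile("L", L_grid, E, reference=0.0,
                         meta={"include_misregistration": include_misregistration})
    prof.extrema = _locate_extrema(f, L_grid, E, kinds=("min",))
    return prof


_ISO_CACHE: dict = {}
_JOINT_CACHE: dict = {}


def isolated_boundary_optimum(sign: int, params: ParameterSet | None = None):
    """Optimal shift and energy of an isolated boundary on one sign branch.

    Returns (L*, E*) with L* restricted to sign(L) = ``sign``.
    """
    params = params or default_parameter_set()
    key = (id(params), sign)
    if key in _ISO_CACHE:
        return _ISO_CACHE[key]

    def f(L):
        return solve_equilibrium(single_boundary(L, params)).energy_per_length

    grid = sign * np.arange(0.1, 4.0001, 0.1)
    grid = np.sort(grid)
    E = np.array([f(L) for L in grid])
    i = int(np.argmin(E))
    i = min(max(i, 1), len(grid) - 2)
    L, Emin = _parabolic_refine(f, grid[i - 1:i + 2], E[i - 1:i + 2], "min")
    _ISO_CACHE[key] = (float(L), float(Emin))
    return _ISO_CACHE[key]


# ----------------------------------------------------------------------
# peptide vs boundary


def _peptide_reference(L0: float, params: ParameterSet) -> float:
    """Energy of the boundary (shift L0) and a peptide far away in Ld."""
    e_boundary = solve_equilibrium(single_boundary(L0, params)).energy_per_length
    e_pep = solve_equilibrium(isolated_peptide("disordered", params)).energy_per_length
    return e_boundary + e_pep


def peptide_domain_profile(L0: float, X_grid=None,
                           params: ParameterSet | None = None) -> EnergyProfile:
    """Energy vs the coordinate X of the peptide's right edge, at fixed shift L0.

    The reference (subtracted) is the peptide-at-infinity energy: isolated
    boundary at shift L0 plus an isolated peptide in the disordered phase.
    X < 0 places the peptide over the ordered domain, X >> 0 deep in the
    disordered phase where the profile tends to zero.
    """
    params = params or default_parameter_set()
    if X_grid is None:
        X_grid = np.arange(-8.0, 10.0001, 0.1)
    X_grid = np.asarray(X_grid, dtype=float)
    ref = _peptide_reference(L0, params)

    def f(X):
        cfg = single_boundary_with_peptide(L0, X, params)
        return solve_equilibrium(cfg).energy_per_length - ref

    E = np.array([f(X) for X in X_grid])
    prof = EnergyProfile("X", X_grid, E, reference=ref, meta={"L0": L0})
    prof.extrema = _locate_extrema(f, X_grid, E)
    return prof


@dataclass
class JointMinimum:
    """Joint optimum over (shift L, peptide right edge X) on one sign branch."""

    sign: int
    L: float
    X: float
    energy: float          # absolute energy per length [kBT/nm]
    reference: float       # boundary at its own optimal shift + far peptide
    well_depth: float      # reference - energy (>0: peptide bound at boundary)


def joint_minimum_peptide_shift(params: ParameterSet | None = None, *,
                                L_step: float = 0.1, X_step: float = 0.1):
    """Minimize the boundary+peptide energy jointly over (L, X) per sign branch.

    Returns {"positive": JointMinimum, "negative": JointMinimum}.  The well
    depth is measured against the peptide-at-infinity reference with the
    boundary at its own no-peptide optimal shift on the same branch.
    """
    params = params or default_parameter_set()
    key = (id(params), L_step, X_step)
    if key in _JOINT_CACHE:
        return _JOINT_CACHE[key]
    e_pep = solve_equilibrium(isolated_peptide("disordered", params)).energy_per_length
    out = {}
    for sign, name in ((1, "positive"), (-1, "negative")):
        L_iso, E_iso = isolated_boundary_optimum(sign, params)
        reference = E_iso + e_pep

        def e_joint(L, X):
            cfg = single_boundary_with_peptide(L, X, params)
            return solve_equilibrium(cfg).energy_per_length

        # coarse X well search at the isolated optimal shift
        Xs = np.arange(-6.0, 8.0001, 2 * X_step)
        Es = np.array([e_joint(L_iso, X) for X in Xs])
        X_best = Xs[int(np.argmin(Es))]

        def min_over_X(L, X_center):
            Xs = np.arange(X_center - 2.0, X_center + 2.0001, X_step)
            Es = [e_joint(L, X) for X in Xs]
            i = int(np.argmin(Es))
            i = min(max(i, 1), len(Xs) - 2)
            return _parabolic_refine(lambda X: e_joint(L, X),
                                     Xs[i - 1:i + 2], Es[i - 1:i + 2], "min")

        Ls = sign * np.arange(0.1, 4.0001, L_step)
        Ls = np.sort(Ls)
        results = []
        Xc = X_best
        for L in (Ls if sign > 0 else Ls[::-1]):
            X, E = min_over_X(L, Xc)
            Xc = X
            results.append((L, X, E))
        results.sort(key=lambda t: t[0])
        i = int(np.argmin([r[2] for r in results]))
        i = min(max(i, 1), len(results) - 2)
        bracketL = [results[k][0] for k in (i - 1, i, i + 1)]
        bracketE = [results[k][2] for k in (i - 1, i, i + 1)]
        Xc = results[i][1]

        def f_L(L):
            return min_over_X(L, Xc)[1]

        L_opt, E_opt = _parabolic_refine(f_L, bracketL, bracketE, "min")
        X_opt, E_opt = min_over_X(L_opt, Xc)
        out[name] = JointMinimum(sign=sign, L=float(L_opt), X=float(X_opt),
                                 energy=float(E_opt), reference=float(reference),
                                 well_depth=float(reference - E_opt))
    _JOINT_CACHE[key] = out
    return out


# ----------------------------------------------------------------------
# domain-domain interaction


def _pair_energy(D, topology, u, params, x_iso, optimize_peptides,
                 include_misregistration=True):
    """Energy of a domain pair; ``u`` stacks |L_left|, |L_right| and the
    peptide-center offsets from their facing upper-monolayer domain edges
    (measured toward the gap).

    Returns a penalized value for geometrically infeasible combinations so
    that derivative-free minimizers stay in the feasible set.
    """
    uL, uR = u[0], u[1]
    if uL < 0 or uR < 0 or uL > 4.0 or uR > 4.0:
        return _PENALTY * (1 + abs(uL) + abs(uR))
    L_left = topology.left_sign * uL
    L_right = topology.right_sign * uR
    gapL = -D / 2.0 + L_left   # upper-monolayer edge of the left domain
    gapR = D / 2.0 - L_right   # upper-monolayer edge of the right domain
    if gapR - gapL < 0.05:
        return _PENALTY * (1 + gapL - gapR)
    positions = {}
    k = 2
    dl = params.peptide.delta_L
    for side in topology.peptide_sides:
        off = u[k] if optimize_peptides else x_iso[side]
        positions[side] = (gapL + off) if side == "left" else (gapR - off)
        k += 1
    if len(positions) == 2 and positions["right"] - positions["left"] < dl:
        return _PENALTY * (1 + dl - (positions["right"] - positions["left"]))
    try:
        cfg = domain_pair(D, topology, L_left, L_right, params,
                          peptide_positions=positions,
                          include_misregistration=include_misregistration)
        return solve_equilibrium(cfg).energy_per_length
    except GeometricInfeasibilityError:
        return _PENALTY


def _pair_reference(topology, params, joint=None):
    """E(D = infinity): additive sum of the isolated facing boundaries.

    A facing boundary with topology sign s (+1: upper leaflet larger,
    extending into the gap) corresponds to the single-boundary branch with
    shift sign -s (the single-boundary frame puts the ordered phase left,
    the upper edge at 0 and the lower edge at L).  Returns the reference
    energy and, per occupied side, the optimal peptide-center offset from
    the facing upper-monolayer edge (measured toward the gap).
    """
    e = 0.0
    x_iso = {}
    if joint is None and topology.peptide_count:
        joint = joint_minimum_peptide_shift(params)
    for side, sign in (("left", topology.left_sign), ("right", topology.right_sign)):
        branch = "positive" if -sign > 0 else "negative"
        if side in topology.peptide_sides:
            jm = joint[branch]
            e += jm.energy
            x_iso[side] = jm.X - params.peptide.delta_L / 2.0
        else:
            e += isolated_boundary_optimum(-sign, params)[1]
    return e, x_iso


def interaction_profile(D_grid=None, topology: BoundaryTopology | None = None,
                        params: ParameterSet | None = None, *,
                        optimize_peptides: bool = True,
                        refine_step: float = 0.1,
                        _joint=None) -> EnergyProfile:
    """E(D) - E(inf) for two domains approaching to edge distance D.

    At each D the energy is minimized over both shift magnitudes and (by
    default) the peptide positions within +-2 nm of their boundary wells,
    with warm starts from the previous D.  The far-field reference is the
    additive sum of the isolated facing-boundary energies.
    """
    params = params or default_parameter_set()
    topology = topology or BoundaryTopology(1, 1)
    if D_grid is None:
        D_grid = np.arange(1.0, 15.0001, 0.25)
    D_grid = np.asarray(D_grid, dtype=float)

    reference, x_iso = _pair_reference(topology, params, joint=_joint)
    jm_pos = {}
    for side, sign in (("left", topology.left_sign), ("right", topology.right_sign)):
        jm_pos[side] = abs(isolated_boundary_optimum(-sign, params)[0])

    def minimized(D, u_start):
        nvar = 2 + (len(topology.peptide_sides) if optimize_peptides else 0)
        u0 = np.array(u_start[:nvar])
        # shifts within [0, 4]; peptide-center offsets within +-2 nm of the
        # isolated boundary well (offsets measured from the facing upper edge)
        bounds = [(0.0, 4.0), (0.0, 4.0)]
        if optimize_peptides:
            for side in topology.peptide_sides:
                c = x_iso[side]
                bounds.append((c - 2.0, c + 2.0))
                k = 2 + list(topology.peptide_sides).index(side)
                u0[k] = min(max(u0[k], c - 2.0), c + 2.0)
        res = optimize.minimize(
            lambda u: _pair_energy(D, topology, u, params, x_iso, optimize_peptides),
            u0, method="Powell", bounds=bounds,
            options={"xtol": 5e-3, "ftol": 1e-6, "maxfev": 60 * nvar})
        return float(res.fun), np.array(res.x)

    # start at the largest D with the isolated optima
    u = [jm_pos["left"], jm_pos["right"]]
    if optimize_peptides:
        for side in topology.peptide_sides:
            u.append(x_iso[side])
    u = np.array(u)

    Ds, Es = [], []
    truncated = False
    for D in D_grid[::-1]:
        E, u_new = minimized(D, u)
        if E >= 0.5 * _PENALTY:
            truncated = True
            break
        u = u_new
        Ds.append(D)
        Es.append(E - reference)
    Ds, Es = np.array(Ds[::-1]), np.array(Es[::-1])

    prof = EnergyProfile("D", Ds, Es, reference=reference, truncated=truncated,
                         meta={"topology": topology,
                               "optimize_peptides": optimize_peptides})

    # refine around the barrier with a finer local D grid
    if len(Ds) >= 3:
        i = int(np.argmax(Es))
        lo = max(Ds[0], Ds[max(i - 1, 0)])
        hi = min(Ds[-1], Ds[min(i + 1, len(Ds) - 1)])
        if hi > lo:
            fine = np.arange(lo, hi + 0.5 * refine_step, refine_step)
            uf = np.array(u) * 0 + u  # copy
            Ef = []
            for D in fine:
                E, uf = minimized(D, uf)
                Ef.append(E - reference)
            grid = np.concatenate([Ds, fine])
            vals = np.concatenate([Es, Ef])
            order = np.argsort(grid)
            grid, vals = grid[order], np.array(vals)[order]
            keep = np.concatenate([[True], np.diff(grid) > 1e-9])
            prof.grid, prof.energy = grid[keep], vals[keep]

    def f(D):
        E, _ = minimized(D, u)
        return E - reference

    prof.extrema = _locate_extrema(f, prof.grid, prof.energy)
    return prof


def fusion_barrier(profile: EnergyProfile, require_plateau: bool = True):
    """Barrier (D*, height) of a domain-domain interaction profile.

    The height is the maximum of E(D) - E(inf); zero if the profile is
    monotone non-increasing toward contact.  By default the profile must
    level off at its far end (reference already subtracted); with
    ``require_plateau=False`` a residual far-field offset (as produced by
    the long-ranged tension-bending branch in peptide-dressed
    configurations) is tolerated and the raw maximum is reported.
    """
    if require_plateau and abs(profile.energy[-1]) > 0.02:
        raise ValueError(
            "no far-field plateau detected; extend the D grid "
            f"(E at D={profile.grid[-1]:.2f} is {profile.energy[-1]:.3f})")
    maxima = profile.maxima()
    i = int(np.argmax(profile.energy))
    grid_max = float(profile.energy[i])
    best = max([m["value"] for m in maxima] + [grid_max])
    if best <= 0.0:
        return float(profile.grid[i]), 0.0
    if maxima and max(m["value"] for m in maxima) >= grid_max - 1e-9:
        m = max(maxima, key=lambda m: m["value"])
        return float(m["position"]), float(m["value"])
    return float(profile.grid[i]), grid_max
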