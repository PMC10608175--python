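"""Independent finite-difference minimization of the elastic functional.

This module rebuilds the energy of a :class:`MembraneConfiguration` on a
dense uniform grid over a truncated domain and minimizes it directly as a
sparse equality-constrained quadratic program.  It shares nothing with the
exponential-basis solver except the physical parameter values, and serves
as the verification oracle: on a converged grid the two routes must agree
to well below a percent.

Discretization
--------------
Each field lives on per-region node blocks with independent degrees of
freedom; interface conditions are imposed explicitly as constraints:
value continuity for the directors and neutral surfaces (plus one-sided
director-derivative continuity when the configuration requests the
conforming treatment), and nothing for the mid-surface M, which may jump
between regions.  First derivatives and averages are cell-local differences;
second derivatives at cell midpoints use 4-node stencils one-sided at
block ends, so no stencil crosses an interface.  The outer boundary is
clamped to the flat rest state.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from memelastic.elastic_core import region_model, rest_offset

__all__ = ["fd_energy_minimum"]

_FIELDS = ("n_u", "n_l", "H_u", "H_l", "M")


def _midpoint_d2_stencil_rows(nb: int, h: float):
    """(nb-1, nb) second-derivative-at-midpoint stencils, one-sided at ends."""
    D2 = np.zeros((nb - 1, nb))
    c = np.array([1.0, -1.0, -1.0, 1.0]) / (2 * h * h)
    left = np.array([3.0, -7.0, 5.0, -1.0]) / (2 * h * h)
    for i in range(nb - 1):
        if i == 0:
            D2[i, 0:4] = left
        elif i == nb - 2:
            D2[i, nb - 4:nb] = left[::-1]
        else:
            D2[i, i - 1:i + 3] = c
    return D2


class _BlockField:
    """One field on independent per-block node ranges."""

    def __init__(self, blocks, dof_start: int, step: float, ncells: int):
        self.blocks = blocks              # list of (i0, i1) node ranges, i1 exclusive
        self.step = step
        self.offsets = []
        off = dof_start
        for (i0, i1) in blocks:
            self.offsets.append(off)
            off += i1 - i0
        self.dof_end = off
        self.ncells = ncells

    def block_of_cell(self, cell: int):
        for b, (i0, i1) in enumerate(self.blocks):
            if i0 <= cell < i1 - 1:
                return b
        return None

    def dof(self, block: int, node: int) -> int:
        i0, i1 = self.blocks[block]
        assert i0 <= node < i1
        return self.offsets[block] + (node - i0)

    def operators(self, nvar: int):
        """Sparse (ncells, nvar) D0 (midpoint avg), D1, D2 over active cells."""
        h = self.step
        r0, c0, v0 = [], [], []
        r1, c1, v1 = [], [], []
        r2, c2, v2 = [], [], []
        for b, (i0, i1) in enumerate(self.blocks):
            nb = i1 - i0
            if nb < 4:
                raise ValueError("each block needs at least 4 nodes")
            D2b = _midpoint_d2_stencil_rows(nb, h)
            for k in range(nb - 1):
                cell = i0 + k
                d0, d1 = self.dof(b, i0 + k), self.dof(b, i0 + k + 1)
                r0 += [cell, cell]; c0 += [d0, d1]; v0 += [0.5, 0.5]
                r1 += [cell, cell]; c1 += [d0, d1]; v1 += [-1.0 / h, 1.0 / h]
                idx = np.nonzero(D2b[k])[0]
                r2 += [cell] * len(idx)
                c2 += [self.dof(b, i0 + j) for j in idx]
                v2 += list(D2b[k, idx])
        shape = (self.ncells, nvar)
        return (sp.csr_matrix((v0, (r0, c0)), shape=shape),
                sp.csr_matrix((v1, (r1, c1)), shape=shape),
                sp.csr_matrix((v2, (r2, c2)), shape=shape))


def fd_energy_minimum(config, half_width: float = 15.0, step: float = 0.01,
                      return_fields: bool = False):
    """Minimize the configuration energy on a dense grid; return the energy.

    ``half_width`` is the clamped-box margin beyond the outermost finite
    interface; all finite interfaces must fall on grid nodes.
    """
    if getattr(config, "freeze_lower_under_peptide", False):
        raise NotImplementedError(
            "the finite-difference oracle covers the default (elastic lower "
            "monolayer) peptide treatment only")
    finite = [v for r in config.regions for v in (r.a, r.b) if np.isfinite(v)]
    if not finite:
        finite = [0.0]
    lo, hi = min(finite) - half_width, max(finite) + half_width
    n = int(round((hi - lo) / step))
    nodes = lo + step * np.arange(n + 1)
    nn = len(nodes)
    ncells = nn - 1

    def node_of(x: float) -> int:
        i = int(round((x - lo) / step))
        if abs(nodes[i] - x) > 1e-9:
            raise ValueError(f"interface at {x} does not fall on the grid")
        return i

    models = [region_model(r.upper, r.lower, config.sigma) for r in config.regions]
    mid = 0.5 * (nodes[:-1] + nodes[1:])
    cell_region = np.empty(ncells, int)
    for ri, r in enumerate(config.regions):
        a = lo if np.isinf(r.a) else r.a
        b = hi if np.isinf(r.b) else r.b
        cell_region[(mid > a) & (mid < b)] = ri

    breaks = sorted({node_of(v) for r in config.regions
                     for v in (r.a, r.b) if np.isfinite(v)})
    edges = [0] + breaks + [nn - 1]
    all_blocks = [(edges[i], edges[i + 1] + 1) for i in range(len(edges) - 1)]
    upper_active = []
    for (i0, i1) in all_blocks:
        xm = 0.5 * (nodes[i0] + nodes[i1 - 1])
        ri = int(cell_region[min(np.searchsorted(mid, xm), ncells - 1)])
        upper_active.append(config.regions[ri].upper is not None)
    upper_blocks = [blk for blk, act in zip(all_blocks, upper_active) if act]

    fields = {}
    off = 0
    for name in _FIELDS:
        blocks = upper_blocks if name in ("n_u", "H_u") else all_blocks
        f = _BlockField(blocks, off, step, ncells)
        off = f.dof_end
        fields[name] = f
    nvar = off

    ops = {name: f.operators(nvar) for name, f in fields.items()}

    # ------------------------------------------------------------------
    # energy assembly: E = 1/2 y^T K y + f^T y + e0
    K = sp.csr_matrix((nvar, nvar))
    fvec = np.zeros(nvar)
    e0 = 0.0
    for ri, (r, model) in enumerate(zip(config.regions, models)):
        cells = np.nonzero(cell_region == ri)[0]
        if len(cells) == 0:
            continue
        w = np.zeros(ncells)
        w[cells] = step
        W = sp.diags(w)

        terms = []
        for leaflet, phase in (("upper", r.upper), ("lower", r.lower)):
            if phase is None:
                continue
            h = phase.h
            if leaflet == "upper":
                nf, Hf, t_s, a_s = "n_u", "H_u", -1.0, -1.0
            else:
                nf, Hf, t_s, a_s = "n_l", "H_l", +1.0, +1.0
            o = rest_offset(phase)
            S = ({(nf, 1): 1.0}, 0.0)
            P = ({(nf, 2): 1.0}, 0.0)
            T = ({(nf, 0): 1.0, (Hf, 1): t_s}, 0.0)
            A = ({(nf, 1): -h / 2.0, (Hf, 0): a_s / h, ("M", 0): -a_s / h}, o / h)
            dA = ({(nf, 2): -h / 2.0, (Hf, 1): a_s / h, ("M", 1): -a_s / h}, 0.0)
            Gr = ({(Hf, 1): 1.0}, 0.0)
            terms += [
                (phase.km / 2.0, S, S), (phase.kt / 2.0, T, T), (phase.kc, T, P),
                (phase.kgr / 2.0, P, P), (phase.kA / 2.0, A, A),
                (-phase.kc, dA, dA), (phase.B, T, dA), (phase.C, dA, P),
                (config.sigma / 2.0, Gr, Gr),
            ]

        def matrix_of(form):
            mat = None
            for (fname, order), coef in form.items():
                part = coef * ops[fname][order]
                mat = part if mat is None else mat + part
            return mat

        for coef, (fa, ka), (fb, kb) in terms:
            Ma, Mb = matrix_of(fa), matrix_of(fb)
            K = K + coef * (Ma.T @ W @ Mb + Mb.T @ W @ Ma)
            fvec += coef * kb * np.asarray((Ma.T @ W).sum(axis=1)).ravel()
            fvec += coef * ka * np.asarray((Mb.T @ W).sum(axis=1)).ravel()
            e0 += coef * ka * kb * w.sum()

    # ------------------------------------------------------------------
    # constraints
    crows, ccols, cvals, crhs = [], [], [], []
    ncon = 0

    def add_row(entries: dict, rhs: float):
        nonlocal ncon
        for j, v in entries.items():
            crows.append(ncon); ccols.append(int(j)); cvals.append(float(v))
        crhs.append(rhs)
        ncon += 1

    # clamp outer boundary nodes (2 per side) to the rest state
    for which in (0, -1):
        model = models[which]
        rest = dict(zip(model.fields, model.rest_vector()))
        for name in _FIELDS:
            f = fields[name]
            b = 0 if which == 0 else len(f.blocks) - 1
            i0, i1 = f.blocks[b]
            if which == 0 and i0 != 0:
                continue   # upper field absent at this outer edge
            if which == -1 and i1 != nn:
                continue
            ns = (i0, i0 + 1) if which == 0 else (i1 - 2, i1 - 1)
            for i in ns:
                add_row({f.dof(b, i): 1.0}, rest.get(name, 0.0))

    # junction conditions between adjacent blocks sharing a node
    def oneside_d1(f, b, i, direction):
        hh = step * direction
        return {f.dof(b, i): -3.0 / (2 * hh), f.dof(b, i + direction): 4.0 / (2 * hh),
                f.dof(b, i + 2 * direction): -1.0 / (2 * hh)}

    dcont = getattr(config, "director_derivative_continuity", False)
    for name in ("n_u", "n_l", "H_u", "H_l"):
        f = fields[name]
        for b in range(len(f.blocks) - 1):
            (a0, a1), (b0, b1) = f.blocks[b], f.blocks[b + 1]
            if a1 - 1 != b0:
                continue   # separated by a peptide strip
            i = b0
            add_row({f.dof(b, i): 1.0, f.dof(b + 1, i): -1.0}, 0.0)
            if dcont and name in ("n_u", "n_l"):
                left = oneside_d1(f, b, i, -1)
                right = oneside_d1(f, b + 1, i, +1)
                entries = dict(left)
                for k, v in right.items():
                    entries[k] = entries.get(k, 0.0) - v
                add_row(entries, 0.0)

    # peptide strip conditions (absolute fields: literal jump + rotation tie)
    for strip in config.strips:
        iL, iR = node_of(strip.xL), node_of(strip.xR)
        fu, fH = fields["n_u"], fields["H_u"]
        bL = next(b for b, (i0, i1) in enumerate(fu.blocks) if i1 - 1 == iL)
        bR = next(b for b, (i0, i1) in enumerate(fu.blocks) if i0 == iR)
        half = strip.delta_L / 2.0
        add_row({fu.dof(bR, iR): 1.0, fu.dof(bL, iL): -1.0}, strip.jump)
        add_row({fH.dof(bR, iR): 1.0, fH.dof(bL, iL): -1.0,
                 fu.dof(bR, iR): -half, fu.dof(bL, iL): -half}, 0.0)

    B = sp.csr_matrix((cvals, (crows, ccols)), shape=(ncon, nvar))
    KKT = sp.bmat([[K, B.T], [B, None]], format="csc")
    rhs = np.concatenate([-fvec, np.array(crhs)])
    sol = spla.spsolve(KKT, rhs)
    y = sol[:nvar]
    energy = 0.5 * float(y @ (K @ y)) + float(fvec @ y) + e0
    total = energy + config.constant_energy
    if return_fields:
        out = {"x": nodes}
        for name, f in fields.items():
            vals = np.full(nn, np.nan)
            for b, (i0, i1) in enumerate(f.blocks):
                vals[i0:i1] = y[f.offsets[b]:f.offsets[b] + (i1 - i0)]
            out[name] = vals
        return total, out
    return total
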