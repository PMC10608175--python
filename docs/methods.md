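# Methods

## The physical problem

Multicomponent lipid bilayers phase-separate into thicker, stiffer
liquid-ordered (Lo, "raft") domains and a thinner liquid-disordered (Ld)
background.  The hydrophobic-thickness mismatch forces elastic
deformations at every Lo/Ld boundary; these deformations carry the
elastic part of the boundary line tension, mediate an interaction between
two approaching domains (a barrier opposing raft coalescence), and couple
to the deformations induced by rigid amphipathic helices adsorbed on one
leaflet.  The package computes all three within one-dimensional continuum
elasticity: the boundary is a straight line, all fields depend on the
transverse coordinate `x` [nm], and energies are per unit boundary length
[k_B·T/nm].

## Elastic model

Each monolayer carries the quadratic tilt–splay energy density (per unit
area, measured from the flat, tension-relaxed state)

    w = km/2 (n')² + kt/2 T² + kc T n'' + kgr/2 (n'')²
        + kA/2 (α − α0)² − kc (α')² + B T α' + C α' n''
        + σ/2 (H')²

with director projection `n(x)`, tilt `T = n ∓ H'` (upper/lower leaflet),
neutral-surface height `H(x)`, bilayer mid-surface `M(x)`, and the
stretching–compression following from monolayer volumetric
incompressibility,

    α_u = −(h/2) n_u' − (H_u − M − h)/h ,
    α_l = −(h/2) n_l' + (H_l − M + h)/h .

Spontaneous curvature is zero in both phases.  The four cross moduli are
closed forms of the tilt modulus and thickness: `kc = −kt h²/6`,
`kgr = kt h⁴/20`, `B = −kt h/2`, `C = kt h³/8`.

Default parameters (both phases share kt, kA, σ):

| quantity | Lo | Ld | units |
|---|---|---|---|
| hydrophobic thickness h | 1.8 | 1.3 | nm |
| bending modulus km | 20 | 10 | k_B·T |
| tilt modulus kt | 12 | 12 | k_B·T/nm² |
| stretching modulus kA | 30 | 30 | k_B·T/nm² |
| lateral tension σ (per monolayer) | 0.1 mN/m = 0.0242 | — | k_B·T/nm² |
| spontaneous stretching α0 = σ/kA | 8×10⁻⁴ | — | — |
| misregistration penalty | 0.016 | — | k_B·T/nm² |

Energies are in k_B·T at the fixed conversion k_B·T = 4.141×10⁻²¹ J
(300 K).  Where an ordered monolayer faces a disordered one across the
mid-plane (a misregistered strip of width |L|), the constant area penalty
0.016·|L| is added to every reported total (a flag removes it for
sensitivity checks).

## Peptides

An adsorbed amphipathic helix of diameter ΔL = 1.3 nm is a rigid object
occupying a strip of the upper leaflet.  The upper monolayer carries no
elastic energy under the strip; the lower monolayer and mid-surface
remain elastic beneath it (a `freeze_lower_under_peptide` flag instead
makes the whole membrane under the strip rigid, for sensitivity checks).
Across the strip the director is discontinuous by

    Δn_x = ΔL / sqrt((ΔL/2)² + (h/2)²)

(1.414 in Ld, 1.171 in Lo; a strip straddling the phase edge uses the
overlap-weighted mixture δ·Δn_s + (1−δ)·Δn_d with δ the geometric
fraction over Ld), and the helix may rotate about its axis: the
neutral-surface offset across the strip equals ΔL times the mean edge
director.

## Coordinate conventions

Single-boundary scans put the ordered phase on the left, the
upper-monolayer edge at x = 0 and the lower edge at x = L; L > 0 thus
means the lower-leaflet domain extends farther (the upper-leaflet domain
is smaller).  This is the only frame in which the published optimal
peptide positions (in particular X* = 0 on the upper-leaflet-larger
branch) are internally consistent.  Peptide positions X are the strip's
right-edge coordinate.  For a domain pair, D is the distance between the
facing lower-monolayer edges; the topology label (+1/−1 per domain) says
whether the upper leaflet domain is the larger one, i.e. whether its edge
extends into the gap.

## Solution method

Within each homogeneous region the Euler–Lagrange equations form a linear
constant-coefficient ODE system of total order 14 (4th order in each
director, 2nd in the three surfaces).  Characteristic roots are found by
companion linearization of the 5×5 polynomial matrix `A(λ)` (with a few
Newton polish steps on `det A`); they come in sign-symmetric sets.  At the
default tension the nonzero roots split into a nanometre branch
(|Re λ| ≈ 0.75–22 nm⁻¹) and one quasi-rigid tension–bending pair
(|Re λ| ≈ 0.049 nm⁻¹, the classic sqrt(σ/km) length).  The zero-root
block (rigid vertical shift and its Jordan partner) is built from
polynomial solutions.  Repeated roots are clustered at 10⁻⁹ relative
tolerance and handled by Jordan chains.

Fields are expanded in these modes per region — exact exponential decay in
the semi-infinite outer regions, all modes in interior regions — and the
energy becomes a quadratic form in the coefficients (Gauss–Legendre panel
quadrature, exact to machine precision for this integrand class).  The
stated interface conditions — continuity of the directors and of the two
neutral surfaces, the peptide jump and rotation tie, decay at ±∞ — enter
as linear equality constraints and the minimizer solves the KKT system.
The mid-surface M is an auxiliary field of the incompressibility relation
and carries no interface condition; imposing its continuity raises the
boundary line tension from 0.28 to 0.44 k_B·T/nm and is not part of the
model.  Director-derivative continuity (the conforming treatment of the
splay-gradient term) is optional and changes boundary energetics by well
under a percent.

Near-collinear mode combinations (slowly decaying exponentials vs the
polynomial block over narrow regions) are removed by an SVD rank filter
(3×10⁻⁸ relative) so the KKT system stays well conditioned; constraint
residuals are checked after every solve.

### Verification

An independent finite-difference route (`memelastic.fdcheck`) discretizes
the same functional on a dense clamped grid (per-region one-sided
second-derivative stencils, explicit continuity constraints, sparse KKT)
and agrees with the basis solver to a few parts in 10⁴ on boundary
configurations and to ~10⁻³ on peptide configurations when the clamping
box is wide enough (≥ 60 nm) to hold the slow tension–bending tail.  The
energy-density transcription and the Euler–Lagrange operator are also
cross-checked symbolically (sympy) in the test suite.

## Scans

- `line_tension_vs_shift`: E(L) on [−5, 5] nm (0.05 nm step), parabolic
  refinement of the two symmetric minima.
- `peptide_domain_profile`: E(X) at fixed shift, referenced to the
  isolated boundary plus an isolated peptide in Ld.
- `joint_minimum_peptide_shift`: nested deterministic grids (0.1 nm) with
  parabolic refinement, per shift-sign branch.
- `interaction_profile`: E(D) minus the additive isolated-boundary
  reference, minimizing at each D over both shift magnitudes (|L| ≤ 4 nm)
  and, by default, the peptide positions within ±2 nm of their isolated
  wells (bounded Powell search, warm-started by continuation from large
  D; a flag freezes the peptides at their wells instead).  Geometric
  infeasibility (closed upper gap, overlapping strips) is handled by
  penalty values and profile truncation.
- `fusion_barrier`: maximum of E(D) − E(∞) with local refinement; it
  requires a far-field plateau unless told otherwise (see limitations).

Default problem sizes (201-point shift scans, 0.25 nm D-grids to 15 nm
with 0.1 nm refinement near the barrier) keep a full reproduction run in
minutes while changing reported barriers by well under 2% relative to
halved grids.

## Headline numbers the defaults produce

The elastic line tension is minimal at |L| = 2.30 nm with
0.280 k_B·T/nm.  On the upper-leaflet-larger branch the peptide binds the
boundary exactly at the domain edge (X* = 0) with a well of
0.89 k_B·T/nm; crossing from the well into the Lo interior costs
1.26 k_B·T/nm on that branch.  The no-peptide coalescence barrier is
0.051 k_B·T/nm.  The closed-form estimates give P/L = 1/50, 1/500,
1/1000 at R = 5, 50, 100 nm and an absolute well depth of 3.6 k_B·T for
a magainin-length helix.

## Known limitations

- **The quasi-rigid tension–bending branch.**  The imposed director jump
  couples strongly to the slow sqrt(σ/km) mode: the minimizer tilts the
  surfaces to absorb most of the jump, producing a deep, wide depression
  under each peptide whose amplitude grows as the tension decreases.
  Per-length energies remain finite and well defined (and are verified
  against the finite-difference oracle), but peptide-dressed
  configurations interact over tens of nanometres through this branch:
  peptide-dressed domain-pair profiles have no plateau by D = 15 nm, and
  their barriers (reported from the additive infinite-separation
  reference) are dominated by it.  A `soft_mode_cutoff` option excludes
  the branch from the solution basis as a sensitivity experiment; this
  restores nm-scale decay but is not a consistent variational model (the
  excluded content re-enters through finite interior regions), so the
  default solves the full functional.  One-dimensionality is the root
  cause: the model's peptide is an infinite ridge, which exaggerates the
  long-range surface response a finite helix could never drive.
- Jointly optimized positions carry ~0.2–0.5 nm systematic uncertainty
  from the shallow, nearly degenerate valleys they live in.
- Linear elasticity: the imposed director jumps (~1.4) and the resulting
  slopes are outside the strictly small-deformation regime; all energies
  are quadratic-order estimates.
- No 2D or curved-boundary geometry, no thermal fluctuations, no
  peptide-induced softening, no chemical (non-elastic) contribution to
  the line tension.
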