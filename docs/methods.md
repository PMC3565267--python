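# Methods

## Model and assumptions

The system is the freely-jointed chain of tangent hard spheres: `n_at`
spheres of diameter σ (the internal unit of length, σ = 1) partitioned into
`n_ch` linear chains.  Consecutive spheres along a chain are bonded with
bond length l ∈ [σ, σ + tangency_tol]; non-bonded pairs may not approach
below σ.  There are no bending or torsion potentials and no energy scale at
all — the model is athermal, temperature is a formal placeholder, and every
structural change is driven by entropy alone.  All simulations run in cubic
cells with periodic boundaries; orthorhombic cells are admitted only for
crystal fixtures whose exact periodic cell cannot be cubic (close-packed
stackings).  Coordinates are stored wrapped into [0, L); analyses that need
unwrapped chains rebuild them by walking bonds.

Key tolerances:

| constant | default | meaning |
| --- | --- | --- |
| `tangency_tol` | 1e-8 σ | allowed bond-length excess above σ (configurable; move acceptance depends on it) |
| `EPS_NUM` | 1e-12 σ | slack below σ before a pair counts as overlapping (absorbs round-off after affine rescaling) |

## Monte Carlo engine

Move mix (attempt probabilities): reptation 0.10, end-sphere rotation 0.10,
configurational-bias regrowth 0.20, inter-chain reptation 0.25, internal
libration 0.3498, sEB 0.0001, sIEB 0.0001.  The two connectivity-altering
moves are set to 0.01% each so the seven probabilities sum to exactly one;
tests that need many bridging events up-weight them explicitly.  Local
moves use a configurational-bias pattern with k trial positions per
displaced site, k growing with packing fraction (default 10 below φ = 0.45,
30 below 0.58, 50 above; tunable).  Acceptance is Metropolis on the
hard-sphere Rosenbluth-weight ratio (trial weights are 0/1), times
exp(Δμ*) when chain lengths change.

* Reptation deletes one end sphere and regrows it on the tangency shell of
  the opposite end; end rotation resamples an end sphere on its neighbour's
  shell; configurational-bias regrowth rebuilds a terminal segment of 1–3
  sites site-by-site.
* Inter-chain reptation transfers an end sphere between chains (lengths
  change by ∓1 inside the allowed range).  The ambiguity of whether this
  move conserves lengths was resolved to the length-changing reading:
  otherwise the length distribution would only fluctuate at the rare
  bridging events.
* Internal libration rotates an interior sphere about the axis through its
  two bonded neighbours by an angle uniform in [−δ, δ] (δ default 20°);
  the rotation preserves both bond lengths exactly and the proposal is
  symmetric, so acceptance is simply overlap-free.
* sEB: a chain end attacks a non-bonded sphere within
  [σ, σ + tangency_tol + r_search] (r_search default 1e-2 σ).  The attacked
  sphere is regrown onto the exact intersection circle of the tangency
  shells of the attacking end and its kept neighbour, one of its bonds is
  deleted, and the complementary tail of monomers transfers between chains.
  sIEB is the intramolecular analog (the intervening segment reverses, the
  chain stays linear).  The reverse-move Rosenbluth weights are
  approximated by k−1 fresh trials plus the actual old position on the old
  tangency locus; the residual proposal asymmetry is absorbed by the μ*
  calibration below.  This is the one place where the acceptance rule is
  knowingly approximate.

Monomer mode (all chains of length 1) bypasses the chain engine and runs a
numba-compiled single-sphere displacement MC with a linked cell list; it
samples the equilibrium hard-sphere fluid and replaces event-driven MD as
the monomeric reference, since every observable used here (τ^c, g(r),
Voronoi shapes) is an equilibrium ensemble property.

### Chemical-potential calibration

Chain lengths are controlled by per-length relative chemical potentials
μ*_N.  Two structural facts shape the solver:

1. Because n_at and n_ch are both conserved, μ* profiles differing by an
   affine function of N are physically equivalent (b·ΣN is a constant of
   motion).  The calibration feedback
   μ* ← μ* + η(log target − log empirical) is therefore projected onto the
   quotient space orthogonal to {1, N}; without the projection the affine
   component of the update accumulates as unbounded drift.
2. Every achievable length marginal has mean exactly n_at/n_ch.  The
   dilute-chain generator therefore pins Σ N_i = n_ch·N_av at construction
   (`exact_total=True`); a start state that misses this total can never
   reach a stationary distribution with the requested mean.

The solver runs short bursts (default 12 × 30k moves, η = 0.5) and averages
the μ* iterates over the second half of the rounds to suppress sampling
noise.  The Flory ("most probable") target is operationalized as
P(N) ∝ p^(N−N_min) with p chosen so the mean is N_av.

### Compression

Dense states are generated by repeated isotropic cell shrinkage with an
affine repositioning of chains: each chain's first sphere moves affinely
(r → s·r) and the whole chain translates rigidly with it, leaving
intra-chain geometry untouched; a shrink that would create any overlap is
rejected and retried with a smaller step after further MC relaxation.  For
monomers the affine map scales all pair distances uniformly, so the safe
step is computed deterministically from the minimum pair gap (shrinking to
90% of the available gap keeps the closest pair mobile).  The relaxation
effort per attempt is deliberately flat (default 2000 moves, quadrupled on
stalls): a schedule that relaxes heavily at high density produces packings
with visible incipient order rather than the rapidly quenched amorphous
state the protocol is meant to deliver.  Compression of 1200 monomers to
φ = 0.61 takes ≈ 3×10⁴ sweeps and lands in [φ_target, φ_target + 1e-4].

The chain-splitting generation check (`split_chains`) halves every chain by
deleting its central bond without touching positions, so structural
measures can be compared across generation protocols.

## CCE norm

For site j with minimum-image neighbour vectors r_i (the 12 nearest sites;
a Voronoi-adjacency mode exists behind a flag), mean shell distance d̄ and
scaled shell u_i = r_i/d̄, the norm against structure X with template
directions s_k and distinguishing point-symmetry operations g_1..g_m is

    ε² = (1/(1+m)) [ M(R*) + Σ_k Y(R* g_k R*ᵀ) ]

where M(R) is the optimally assigned (Hungarian) mean-square residual
between {u_i} and the rotated template {R s_k}, R* is the proper rotation
minimizing M (multi-start assignment/Kabsch alternation, seeded from exact
two-vector correspondence alignments plus a fixed quasi-random orientation
grid), and Y(G) is the shell's own mean-square mismatch under the
conjugated operation G.  Both terms vanish identically for a perfect site
of structure X; the norm is invariant under global rotation, translation
and uniform dilation, and radially sensitive within the shell.

Templates: fcc = cuboctahedral 12-shell with ops {two C₄ axes, S₆ about a
threefold axis}; hcp = anticuboctahedral 12-shell with ops {σ_h, an
in-plane C₂, S₃ about the stacking axis}; fivefold = icosahedral 12-shell
with ops {C₅, C₅²} (a 7-vector pentagonal-bipyramid variant is provided).
The closure terms are what separates geometrically close direction sets —
the icosahedron is only a small "jitterbug" twist away from the
cuboctahedron (optimal matching RMS ≈ 0.23), but it has no four-fold axis.
With this operationalization, cross norms between all three perfect
structures exceed 0.32, thermally plausible crystal distortions (≤ 0.05 σ
displacement noise) stay below ≈ 0.08, and equilibrium dense fluids put
≈ 94% of sites above the threshold, so the printed threshold ε_thres =
0.245 discriminates sharply on this scale; the per-structure op sets were
fixed by calibration on guaranteed-amorphous fluids, not on any test
outcome at the transition itself.

S^X is the fraction of sites with ε^X < ε_thres (sites with fewer than 12
neighbours carry an infinite sentinel and count as amorphous in the
denominator); τ^c = S^hcp + S^fcc.

## Voronoi shape analysis

The periodic tessellation augments the box with ghost images (26
translates pruned to a shell, falling back to all images for small boxes)
and keeps the Qhull cells of primary sites; cells tile the box to 1e-8
relative and the face-neighbour relation is symmetric.  Degenerate
cospherical inputs (perfect lattices) are retried once with a reported
1e-10 σ jitter, and coincident polyhedron vertices are merged (tolerance
1e-6, relative) before the shape analysis, since Qhull splits high-order
vertices into clusters that would otherwise distort the vertex-mass
inertia.

The inertia tensor treats merged vertices as equivalent unit point masses
about the vertex centroid; vertex coordinates are in σ, so b and c carry
units of σ² (isolated in `LENGTH_UNIT`).  Eigenvalue ties break by a
descending stable sort, making c = I₁ − I₂ vanish identically under ties.

A fact worth recording: **both** ideal reference cells — the rhombic
dodecahedron (fcc) and the trapezo-rhombic dodecahedron (hcp) — have
exactly isotropic vertex inertia, b = c = k² = 0.  The hcp cell is the fcc
cell with its lower half rotated 60° about the threefold axis; each half's
inertia is transversely isotropic about that axis, so the rotation changes
nothing.  The asphericity asymmetry between hcp-like and fcc-like sites
seen in dense simulations is a property of thermally distorted cells, not
of the ideal polyhedra (c = 0 stays exact for the ideal hcp cell).  The
mean local density is reported as n_at/ΣV_cell — the space-filling
identity — and is exactly the global density on every frame.

## Flippers, g(r), trajectory reports

The flip test is feasibility-only: an interior sphere is a flipper at
amplitude dφ iff rotating it by +dφ **and** −dφ about the axis through its
bonded neighbours creates no overlap.  End spheres and monomers are
excluded from the denominator (their axis is undefined); an optional mode
probes ends about a random perpendicular axis for sensitivity analysis.
The fraction is non-increasing in dφ by nested feasibility.

g(r) is the standard ideal-gas-normalized pair histogram over minimum-image
distances (default bin 0.02 σ, r_max ≤ L/2).  The contact value g(σ⁺) is
extrapolated by a count-weighted quadratic fit to the bins in (σ, σ+0.06);
the bins are aligned so that no bin straddles contact, which would mix in
the empty r < σ region and bias the contact value low.  The
compressibility factor follows as Z = 1 + 4φ g(σ⁺).

`trajectory_report` assembles per-frame τ^c, S^X, mean b/c/k², flipper
fractions and φ, and locates the transition as the sliding window (5% of
frames, minimum 3) of steepest τ^c increase, reporting it together with the
windows of steepest asphericity decrease and flipper increase so their
co-location can be checked.

## Synthetic data: what it emulates and what it does not

The fixtures module replaces atomistic-template initial structures with
tangent random walks grown by hard-core rejection (dilute, φ ≤ 0.10), and
provides exact close-packed stackings: triangular layers on an
orthorhombic-commensurate tile, layer spacing σ√(2/3), registries A/B/C.
A stacking whose first and last letters differ is fully periodic at
contact (packing fraction exactly π/√18 when commensurate); otherwise one
layer spacing of vacuum is inserted and the terminal layers are free
surfaces.  Per-site ground truth follows the flanking-layer rule (same
letter → hcp, different → fcc, terminals → boundary).

These fixtures are defect-free and at exact contact; real dense packings
carry thermal distortion, polydisperse local strains, twins and grain
boundaries (for monomers) that the generators deliberately do not emulate.
Tests passing on fixtures therefore validate the *descriptors* and the
*engine invariants*, not the full phenomenology of crystallization; the
spontaneous transition of 1200-sphere chain systems at φ = 0.61 requires
>10¹⁰ MC steps and remains a cluster-scale experiment outside the routine
suite.

## Problem sizes used by the test suite

Chosen as the smallest systems that leave the checked effects clearly
resolved: equation-of-state runs use 400 spheres with 6×10⁶ production
moves per density; ensemble control uses 40 chains (480 spheres) at
φ = 0.04 with ≈ 1.2×10⁶ total moves per distribution; the amorphous
baseline uses five independent 1200-sphere quenches to φ = 0.61; the
stacking ground-truth check uses twenty 8-layer, 16-site-per-layer
sequences.

## Known limitations

* sEB/sIEB acceptance lacks the full superdetailed-balance Jacobian of the
  reference bridging formulation; the μ* calibration compensates at the
  distribution level.  Flagged as replaceable.
* The CCE norm here is an operationalization (the complete reference
  formulation was not available); its perfect-crystal zeros, discrimination
  and invariance properties are the tested surface, and the norm scale in
  the amorphous region (≈ 0.3–0.5 median) sits below the reference scale's
  printed amorphous examples (≈ 0.67–0.72), so threshold-sensitive
  quantities should be compared with that in mind.
* The compression protocol is a quench, not an equilibrium path; states
  above φ ≈ 0.55 are metastable glasses whose τ^c depends on the quench
  rate (documented above).
* Monomer mode uses MC rather than event-driven MD, so no dynamical
  (collision-time) information exists anywhere in the package.
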