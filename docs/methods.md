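# Methods

## Problem

`trabfe` studies how degrading the axial resolution of a microCT scan of
trabecular bone changes the apparent elastic modulus computed by voxel-based
micro-finite-element analysis, and how that change relates to the
histomorphometric structure of the specimen. The package builds binary voxel
models from slice stacks, coarsens them by four schemes that emulate
lower-resolution acquisition, solves linear-elastic uniaxial compression on
the voxel-to-element hexahedral mesh, and regresses the modulus decay against
structural indices.

## Voxel models

A stack of N binary slices (36 µm square pixels, 36 µm increment by default)
yields a basic model of N−1 voxel layers: voxel (i, j, k) is bone iff pixel
(i, j) is bone in slices k *and* k+1 (the AND rule). Four coarsening schemes
produce models at voxel length d:

* **Hexahedral (H)** — tile the basic model with cubes ("cuberrilles") of
  side s ∈ 72–288 µm anchored at the grid origin; an output voxel is bone iff
  bone fills strictly more than 50 % of the *full nominal* cuberrille volume.
  Partial cuberrilles at far boundaries count their missing sub-voxels as
  empty; consequently, a remainder layer filled at exactly 50 % (e.g. the top
  layer when the layer count is odd and s = 72 µm) is dropped entirely.
  Quantitative comparisons therefore use grid dimensions divisible by every
  tested s/36, so boundary effects never masquerade as resolution effects.
* **First-Last (F-L)** — layer k (length d = m·36 µm) from slices k·m and
  (k+1)·m, AND rule: the pair is d apart, and only every m-th scan is needed.
* **First-Second (F-S)** — layer k from the successive pair k·m, k·m+1
  (36 µm apart), extruded to d.
* **First-Third (F-T)** — like F-S with the pair 72 µm apart; d ∈ 72·ℕ.

Layers tile the axis from slice 0; trailing slices that do not complete a
layer are dropped, so a model never exceeds the source extent. d ranges are
enforced as 72–1080 µm (72–288 µm for H) with an explicit override, since
they are study conventions rather than algorithmic limits.

## Morphometry

* **BV/TV**: bone volume over the examined volume (cylindrical-mask volume
  when a mask applies, else the bounding box).
* **Tb.Th**: maximal-inscribed-sphere local thickness. The bone phase is
  treated as the continuum union of voxel cubes; candidate sphere centres
  live on the half-voxel lattice (centres, faces, edges, corners), and each
  centre's clearance to the background phase is computed *exactly* by a
  Euclidean distance transform on the refined corner lattice (the nearest
  point of an axis-aligned cube to a half-lattice point is itself a
  half-lattice point). Space beyond the grid counts as bone continuation, so
  struts leaving the field of view are not artificially thinned. This makes
  an isolated voxel exactly one voxel thick and a two-voxel slab exactly two
  voxels thick — a voxel-centre-only sphere search cannot reproduce the
  latter. Dominated centres are pruned by a 26-neighbour ball-containment
  test before sphere painting.
* **Tb.N**: plate-model identity (BV/TV)/Tb.Th in mm⁻¹, so
  Tb.N·Tb.Th = BV/TV holds to machine precision by construction.
* **V_m**: mean bone volume per voxel layer (mm³).
* Cohort summaries report min, max, mean, sample SD and RSD = 100·SD/mean
  (percent) — the formula consistent with the reference specimen table.

## Micro-FE model

Each bone voxel maps to cubic 8-node trilinear hexahedra: one element per
cubic voxel, d/36 stacked elements per 36×36×d prism voxel. Shared nodes
merge exactly through integer lattice addressing. Elements outside the
largest face-connected component are eliminated before solving: edge- and
corner-only contacts transmit no stiffness through conforming hexahedra and
make the system singular. Components that span but do not touch both platens
are *not* additionally removed; a filtered mesh with no nodes on a loading
face is reported as a disconnected load path (E_app = 0 with a warning).

The material is homogeneous isotropic tissue, E = 10 GPa, ν = 0.3. One
24×24 element stiffness matrix (2×2×2 Gauss quadrature — exact, since the
trilinear B-matrix integrand is quadratic per axis) is reused for every
element.

Boundary conditions model frictionless rigid platens: axial displacement 0
on the bottom face, −ε·H on the top face (ε = 0.8 % by default), lateral
displacements free. The three remaining lateral rigid-body modes are pinned
minimally: one bottom-face node in both lateral directions and a second
bottom-face node with the same y in y only. Both pins are compatible with
the homogeneous-strain solution (uniform strain with free Poisson expansion
about the first pin), so the patch test is exact — a solid prism returns
E_app = E to ≲1e-9 for any ν — and the reaction force is insensitive to the
pin choice.

The sparse symmetric system is solved by direct LU factorization up to
250 000 free DOFs and by Jacobi-preconditioned conjugate gradients (relative
residual 1e-8, homogeneous-strain start vector) above. ILU preconditioning
was evaluated and rejected: its factorization cost exceeded the direct
solve at the relevant sizes.

The outcome is F, the total axial reaction on the driven platen, and
E_app = (F / A)/ε with A the *nominal* cross-section — the cylindrical mask
area when present, else the model's own in-plane grid box (never the bone
area). Equilibrium (|F_bottom + F_top|/|F_top| ≤ 1e-6) is reported as a
diagnostic.

## Analysis

Relative modulus RE(d) = E_app(method, d)/E_app(basic); the curve includes
the basic point (36 µm, 1). Two fit forms are provided because the source
analysis uses both without a stated rule: OLS linear in d, and logarithmic
RE = a·ln d + b restricted to d ≤ 300 µm. R² for a zero-variance response is
defined as 0. The slope-vs-index table regresses per-specimen |a| (log-fit)
on each of BV/TV, Tb.Th, Tb.N and V_m, one OLS cell per (method, index);
both the raw fitted slope and its magnitude are emitted so either sign
convention is inspectable.

## Synthetic specimens

No scans are distributed with the package, so validation runs on phantoms:

* deterministic fixtures with closed forms — solid block (E_app = E), prism
  column occupying area fraction φ (E_app = φ·E exactly, by uniform-stress
  statics), plate lattice (BV/TV = t/p, Tb.Th = t, Tb.N = 1/p; slabs centred
  in the period so none touches the lateral border), rod lattice;
* a stochastic **grf** specimen: seeded white noise blurred by a periodic
  anisotropic Gaussian kernel — in-plane standard deviation 80 µm and 3×
  that along the axis, emulating the preferential axial alignment of
  femoral-head trabeculae — thresholded at the empirical 1−BV/TV quantile.
  Quantile thresholding makes the realized stack bone fraction match the
  target within ±0.01 by construction across the study range (0.068–0.392);
  the basic model's BV/TV is slightly lower (the AND of consecutive slices
  erodes interfaces, ≈0.02 at default settings). Realized Tb.Th is
  ≈0.16–0.20 mm, near the reference specimens' mean. An isotropic kernel was
  rejected during design: at trabecular volume fractions its in-plane
  sections sit far below 2-D percolation, so every coarsening method
  collapsed to a disconnected load path immediately, which is not the
  physics under study.

**What the phantom does not emulate.** Gaussian excursion sets at ≤10 %
volume lie below the 3-D percolation threshold, so a finite window is
occasionally disconnected where an intact specimen of real, load-bearing
bone would not be; `make_grf_cohort` therefore draws consecutive seeds and
keeps specimens whose basic model has a spanning face-connected component —
a fixed measurability screen applied identically at every density. Second,
the mismatch between thresholded slices of a smooth Gaussian field grows
roughly linearly with axial lag, so F-T (72 µm pairs) systematically erodes
about twice as much bone as F-S (36 µm pairs); real trabeculae with
near-flat strut surfaces over tens of µm show essentially no F-S/F-T
difference. Passing cohort tests consequently demonstrate the ordering and
sign of the resolution effects, not a statistical F-S/F-T equivalence, which
this generator family cannot reproduce (see the known-limitations note in
the acceptance tests).

## Default study scale

Cohort experiments run at desk scale: 32×32 pixels in-plane with 65 slices
(ordering/sign findings, 5 specimens at BV/TV 0.22) or 33 slices
(low-vs-high density comparison, 3 specimens each at BV/TV 0.10 and 0.35),
36 µm spacing throughout. Layer and pixel counts are divisible by every
tested cuberrille side. The layered methods use their natural d-steps up to
the 300 µm fit window (36 µm for F-L/F-S, 72 µm for F-T); H uses exact
divisors of the cross-section ({72, 144, 288} µm). The generator's default
grid (64×64×120) is used where only a single model is needed (e.g. BV/TV
recovery checks).

## Numerical conventions and edge cases

* Grey thresholding uses ≥ (monotone: raising the threshold never adds
  bone); cylinder-mask membership is pixel-centre-in-disc.
* Coarsening parameter validity: d must be a positive multiple of the
  method's step; F-T requires multiples of 72 µm.
* Largest-component ties break toward the component containing the lowest
  element index (scan order).
* CG iteration cap max(20 000, 60·√n); non-convergence raises a solver
  error carrying iteration count and residual.
* Local-thickness coverage and dominance tests carry 1e-12-scale tolerances
  against floating-point ties; the thickness values themselves are exact for
  axis-aligned interfaces.
* Pipeline CSVs are written with a fixed float format; runs are
  byte-reproducible for a fixed config seed (per-phantom seeds derive from
  it and stay below 2³¹).

## Known limitations

* Linear elasticity only: no yield, damage, contact or large deformation.
* Homogeneous tissue modulus; no mineralization-based heterogeneity.
* Tb.Th/Tb.N follow the plate-model convention; no model-independent (MIL,
  SMI, direct-spacing) variants.
* The H method is the only scheme degrading in-plane resolution; no
  grey-level (partial-volume) coarsening.
* The grf phantom reproduces index ranges and qualitative mechanics, not
  specimen-specific anatomy; specimen-level reference values (per-specimen
  regression tables) are out of reach without the original scans.
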