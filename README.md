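# trabfe

Voxel-based micro-finite-element analysis of trabecular bone under
simulated resolution loss.

MicroCT resolves the strut-level architecture of cancellous bone at tens of
microns, but clinical imaging cannot: slice spacings of 100–500 µm are the
realistic regime. `trabfe` quantifies what that costs mechanically. It
builds binary voxel models from microCT slice stacks, degrades them with
four coarsening schemes that emulate lower-resolution acquisition, computes
the apparent elastic modulus of every model by voxel-to-element hexahedral
FE analysis, and relates the modulus decay to the specimen's
histomorphometric indices. It is written for bone-mechanics researchers who
want a transparent, fully testable reimplementation of this class of
resolution study, with synthetic specimen generators standing in for
patient scans.

## Model

A stack of N binary slices (36 µm pixels and increment) yields a basic
model of N−1 voxel layers: voxel (i,j,k) is bone iff pixel (i,j) is bone in
slices k **and** k+1. Four schemes emulate voxel length d > 36 µm:

| method | rule |
|---|---|
| Hexahedral (H) | tile with d-sided cubes; bone iff fill > 50 % of the cube |
| First-Last (F-L) | AND of slices k·m and (k+1)·m (pair d apart), m = d/36 |
| First-Second (F-S) | AND of slices k·m, k·m+1 (36 µm apart), extruded to d |
| First-Third (F-T) | AND of slices k·m, k·m+2 (72 µm apart), extruded to d |

Each bone voxel becomes d/36 stacked 8-node cubic elements (one for cubic
voxels); tissue is homogeneous isotropic with E = 10 GPa, ν = 0.3. After
removing everything outside the largest face-connected component, the model
is compressed by ε = 0.8 % between frictionless platens and

    E_app = (F / A) / ε

with F the axial reaction and A the nominal cross-section. The study
quantity is the relative modulus RE(d) = E_app(d)/E_app(36 µm), fitted as
RE = a·ln d + b over d ≤ 300 µm; per-specimen slope magnitudes |a| are then
regressed against BV/TV, Tb.Th (inscribed-sphere local thickness), Tb.N
(plate model, (BV/TV)/Tb.Th) and V_m (mean bone volume per layer).

## Worked example

```python
import trabfe
from trabfe.fesolve import LoadCase, MaterialProps, assemble_and_solve

mat, load = MaterialProps(10.0, 0.3), LoadCase(0.008)

solid = trabfe.build_basic_model(trabfe.make_solid_block((8, 8, 9)))
print(trabfe.compute_apparent_modulus(solid, mat, load))   # 10.000000 GPa

stack = trabfe.make_grf_phantom((32, 32, 65), target_bvtv=0.22, seed=0)
model = trabfe.build_basic_model(stack)
mesh  = trabfe.filter_connectivity(trabfe.voxels_to_elements(model))
res   = assemble_and_solve(mesh, mat, load)
print(res.e_app_gpa, res.force_n, mesh.n_elements)
```

Running `python examples/04_apparent_modulus.py` prints:

```
solid block : E_app = 10.000000 GPa (= tissue modulus)
prism 25%   : E_app = 2.500000 GPa (= 0.25 x 10 GPa)
grf specimen: E_app = 0.4660 GPa  (F = 4.95 N over 1.33 mm^2, 13019 elements, equilibrium error 2.9e-12)
```

The solid block reproduces the tissue modulus exactly (patch test); a
column covering 25 % of the cross-section carries 25 % of the stiffness;
and a trabecular specimen at 22 % bone fraction retains only ~5 % of the
tissue stiffness, because load travels through a sparse strut network.
`examples/05_resolution_study.py` runs the full coarsening study on a
miniature cohort and prints the slope-vs-index table; the other examples
cover phantoms, coarsening and morphometry individually.

A thin CLI mirrors the pipeline stages:

```sh
trabfe generate --kind grf --shape 32 32 65 --seed 1 stack.tif
trabfe indices stack.tif
trabfe solve --method FS -d 144 stack.tif
trabfe run config.yaml        # full study from one YAML config
```

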