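"""Degrade a specimen's resolution with the four coarsening methods.

All four emulate a lower-resolution acquisition at voxel length d:
H re-tiles the basic model with d-sided cubes (>50 % fill rule), while
F-L, F-S and F-T rebuild each d-long layer from just two source slices
(d, 36 µm and 72 µm apart, respectively) — so the slice-pair methods need
far fewer scans than the basic model.
"""
import trabfe

stack = trabfe.make_grf_phantom((32, 32, 65), target_bvtv=0.22, seed=3)
basic = trabfe.build_basic_model(stack)
print(f"basic model: {basic.shape} voxels of 36 µm, "
      f"BV/TV = {trabfe.compute_bvtv(basic):.3f}")

for method in ("H", "FL", "FS", "FT"):
    for d in (72.0, 144.0, 288.0):
        m = trabfe.coarsen(stack, method, d)
        n_layers = m.shape[0]
        # H consumes the full stack; F-L one scan per layer boundary;
        # F-S and F-T two scans per layer
        slices_needed = {"H": stack.n_slices, "FL": n_layers + 1,
                         "FS": 2 * n_layers, "FT": 2 * n_layers}[method]
        print(f"{method:2s} d={d:5.0f} µm: grid {m.shape}, "
              f"BV/TV {trabfe.compute_bvtv(m):.3f}, "
              f"source slices used ~{slices_needed}")

# The AND rule erodes bone as the paired slices move apart: F-L loses the
# most (pairs d apart), F-S the least (successive slices). H's majority
# rule removes struts thinner than half a cuberrille.
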