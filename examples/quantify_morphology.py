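"""Quantify network morphology: polygons, network density, border ratio.

Builds three reference assemblies with the synthetic generator — an ideal
honeycomb flower, a defective crystal, and an elongated chain — and runs the
morphology stack on their centre coordinates.
"""

from patchnet import (analyze_frame, make_compact_island,
                      make_elongated_island)

cases = {
    "ideal flower (2 rings)": make_compact_island(n_rings=2, seed=0),
    "defective crystal": make_compact_island(n_particles=100,
                                             defect_rates=(0.1, 0.1), seed=1),
    "elongated chain": make_elongated_island(30, branch_prob=0.1, seed=2),
}

for name, field in cases.items():
    rep = analyze_frame(field.points)
    isl = max(rep.islands, key=lambda s: s.island.size)
    counts = {k: v for k, v in isl.polygon_counts.items() if v}
    print(f"{name}")
    print(f"  particles {isl.island.size}, bonds {isl.island.n_edges}")
    print(f"  network density {isl.nd:.3f} "
          "(1 = maximally compact honeycomb)")
    print(f"  border ratio {isl.border:.3f} "
          "(1 = every polygon touches the rim, 0 = no polygons)")
    print(f"  polygons by size {counts or 'none'}\n")

print("The ideal crystal scores ND = 1 with pure hexagons; defects add 5/7-")
print("rings without destroying compactness; chains have no polygons at all.")
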