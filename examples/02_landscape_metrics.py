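"""Class-level landscape metrics inside circular buffers.

Generates a small neutral land-cover mosaic and measures the six metrics
(forest cover FC, secondary forest SF, patch density PD, aggregation AI,
isolation PI, edge contrast EC) around one focal point at three radii.
"""

from seedscape.landscape import clip_buffer, compute_metric
from seedscape.synthetic import DEFAULT_CLASS_PROPORTIONS, generate_landscape

raster = generate_landscape(
    width_m=4000,
    height_m=4000,
    cell_size=10,
    class_proportions=DEFAULT_CLASS_PROPORTIONS,
    clustering=0.5,
    seed=7,
)
centre = (2000.0, 2000.0)

print("radius   FC%    SF%   PD/ha    AI%    PI m    EC%")
for radius in (300, 600, 900):
    view = clip_buffer(raster, centre, radius)
    vals = [compute_metric(view, m) for m in ("FC", "SF", "PD", "AI", "PI", "EC")]
    print(
        f"{radius:5d} {vals[0]:6.1f} {vals[1]:6.1f} {vals[2]:7.3f} "
        f"{vals[3]:6.1f} {vals[4]:7.1f} {vals[5]:6.1f}"
    )
# FC/SF: percentage of the buffer covered by old-growth/secondary forest.
# PD: old-growth patches per hectare (fragmentation). AI: like-adjacency
# percentage of its maximum (compactness). PI: mean nearest-neighbour
# distance between forest patches. EC: quality-weighted edge contrast of
# forest patches against their neighbouring cover types.
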