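"""Build a synthetic actin-bundle network and inspect its geometry.

A droplet network is emulated by sampling points in a voxel grid, taking
the edges of their 3D Delaunay triangulation and rasterizing each edge as
a digital tube — a sparse 3D scaffold of 'bundles' like the regularly
spaced networks that self-assemble in real droplets.
"""

import actinmachine as am

spec = am.SynthSpec(kind="delaunay", extent=(64, 64, 8), n_points=40, tube_radius=2.0, seed=7)
matrix = am.synth_network(spec)

print(f"grid shape:           {matrix.shape}")
print(f"conductive voxels:    {matrix.n_conductive}"
      f" ({100 * matrix.n_conductive / matrix.grid.size:.1f}% of the grid)")
print(f"network nodes/edges:  {len(matrix.meta['points'])} / {len(matrix.meta['edges'])}")

# The conductive fraction is the 'bundle density' the excitation waves
# travel on; the nodes are natural electrode sites.
am.save_matrix(matrix, "scratch_network.tif")
print("written to scratch_network.tif (+ .json sidecar): 0/255 slice-per-page TIFF")
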