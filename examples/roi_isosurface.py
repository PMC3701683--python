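"""Build a triangulated boundary mesh around labeled ROI clusters.

A synthetic label volume carries two integer-labeled blocks; each label's
voxels become a closed isosurface in world coordinates.
"""

import numpy as np

import bnv
from bnv.fixtures import make_gradient_volume

volume = make_gradient_volume(shape=(10, 10, 10), pattern="labels", seed=3, n_labels=2)

for label in (1, 2, 3):
    mesh = bnv.roi_cluster_mesh(volume, label)
    n_vox = int((volume.grid == label).sum())
    if mesh.n_faces:
        c = mesh.vertices.mean(axis=0)
        print(f"label {label}: {n_vox} voxels -> {mesh.n_vertices} vertices, "
              f"{mesh.n_faces} faces, centroid ({c[0]:.1f}, {c[1]:.1f}, {c[2]:.1f})")
    else:
        print(f"label {label}: {n_vox} voxels -> empty mesh (label absent)")

print("\neach labeled cluster becomes a closed surface enclosing its voxels;")
print("an absent label yields an empty mesh rather than an error")
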