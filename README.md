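# bnv — headless ball-and-stick brain connectome visualization

`bnv` renders macro-scale brain networks — connectomes — as 3-D
ball-and-stick models: spheres for nodes (brain regions or voxels),
cylinders for edges (structural or functional connections), drawn over a
translucent triangulated cortical surface, optionally colored by a
volumetric statistical map. It is aimed at researchers who construct
networks with graph-theoretic pipelines and need publication figures or
rotation videos in batch, without a GUI.

## What it does

* **File formats.** ASCII surface meshes (`.nv`: vertex count, vertex
  coordinates, face count, 1-based triangle indices), 6-column node tables
  (`.node`: x y z color size label, `-` = no label), square association
  matrices (`.edge`), NIfTI-1 / Analyze 7.5 volumes, per-vertex scalar
  vectors, and a YAML display configuration. Eight of the fifteen possible
  input combinations are drawable (surface alone, nodes alone, surface+nodes,
  nodes+edges, …, all four); everything else is rejected with a clear error.
* **Network styling.** Nodes are selected by strict thresholds on their
  color or size column; radii are auto-scaled onto a range, taken raw, or
  equalized; colors come from a uniform choice, a colormap, a ≥20-color
  modular palette, or binarization. Edges are extracted by value threshold
  or sparsity *s* (the top `round(s·N(N−1)/2)` weights), optionally on
  absolute values or restricted to interhemispheric pairs (opposite world-x
  signs), and styled analogously — including binarization by Euclidean
  length (e.g. >90 mm = long-range) and endpoint-linked coloring.
  Asymmetric matrices yield directed (arrow) edges.
* **Glyph geometry.** Node spheres are latitude/longitude meshes with grid
  parameter n ∈ {100, 50, 20} (high/moderate/low detail); edge cylinders
  with n ∈ {20, 10, 5} circumferential samples are built along +z and moved
  into place by the axis–angle rotation with axis ẑ×d̂ and angle
  arccos(ẑ·d̂), where d̂ is the unit vector between the two node centers.
* **Volume-to-surface mapping.** Eight sampling rules (nearest voxel, 1-ring
  vertex averaging, 3×3×3 block mean/max/min/extremum, Gaussian
  pre-smoothing, trilinear interpolation), a positive/negative/both sign
  filter, 24 built-in colorbar presets (jet, hsv, hot, cold, winter, summer,
  …) plus custom n×3 tables, and marching-cubes isosurfaces around
  integer-labeled ROI clusters.
* **Scenes and export.** Layouts: single view (sagittal/axial/coronal or a
  custom camera), medium (4 panels: lateral+medial per hemisphere), full
  (6 panels for a non-divisible surface, 8 for a divisible one). Offscreen
  rendering to PNG/TIFF/BMP/JPEG/EPS at exact pixel (or cm/inch × DPI)
  dimensions, and rotation videos — by default one clockwise turn at one
  degree per frame: 360 frames, 30 FPS, 12 s, 735×534.
* **Hub statistic.** Nodal strength (functional connectivity strength) =
  sum of a node's connection weights; z-normalized with the sample SD;
  nodes with z strictly above 1 are hubs.

## Worked example

`examples/hubs_and_strength.py` builds a reproducible 12-node synthetic
network and flags its hubs:

```
node    strength       z  hub
N1         2.642   0.701
N2         0.812  -1.969
...
N9         3.143   1.433  *
N12        2.890   1.064  *

hubs: 2 of 12 nodes (strict z > 1.0)
```

Node N9's summed connection weight is 1.43 standard deviations above the
network mean, so it is a hub; N2 is the most weakly connected node. The
other scripts in `examples/` each demonstrate one capability — ball-and-stick
rendering, the eight mapping algorithms, ROI isosurfaces, the batch
pipeline, rotation video — and print what the numbers mean.

From a shell, the same pipeline is one command with order-free arguments
(kinds are recognized by suffix):

```sh
bnv net.node net.edge network.png --layout full --detail low
```

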