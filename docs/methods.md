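# Methods

This note documents the conventions, defaults and numerical choices behind
`bnv`, in the spirit of a model-description appendix: what each operation
computes, where the design was genuinely open, and what the synthetic test
data does and does not establish.

## Coordinate and file conventions

All geometry lives in world millimeter coordinates (MNI-like: x < 0 is the
left hemisphere). On disk, `.nv` triangle indices are 1-based; in memory
every face array is 0-based — the readers/writers are the single conversion
point. In all ASCII formats any run of spaces/tabs delimits fields, and
blank lines or lines starting with `#` are skipped (the formats themselves
are silent on comments; tolerating them costs nothing and helps hand-edited
files). The no-label sentinel in node tables is the ASCII hyphen; the
typographic minus and en dash are accepted on read because they survive
copy-paste from documents.

An edge matrix is flagged symmetric when `max|W − Wᵀ| ≤ 1e−8·max(1, max|W|)`
— loose enough to absorb text round-trip noise, far below any meaningful
asymmetry. The diagonal is carried but ignored by every downstream
operation (self-connections have no ball-and-stick rendering); a nonzero
diagonal is therefore not an error. 4-D volumes with one time point are
squeezed to 3-D; genuine time series are rejected rather than silently
truncated to the first volume.

The display configuration is schema-versioned YAML rather than an opaque
binary container: it round-trips exactly, unknown keys warn and are
ignored, and missing fields take their documented defaults.

## Glyph geometry

Node spheres use the latitude/longitude parametrization: grid point (i, j),
i, j ∈ {0..n}, at latitude −π/2 + πi/n and longitude 2πj/n, giving (n+1)²
grid vertices (pole rows are kept as degenerate zero-area quads — simpler
indexing, no rendering effect). Detail levels high/moderate/low set
n = 100/50/20 for spheres and 20/10/5 circumferential samples for
cylinders.

Edge cylinders are built canonically along +z with exactly two rings — a
straight tube gains nothing from intermediate rings, so the vertex budget
goes to the circumference — then rotated by the axis–angle rule
(axis = ẑ×d̂, angle = arccos(ẑ·d̂)) and translated. The antiparallel
degenerate case (d̂ = −ẑ, vanishing cross product) rotates about +x by π;
any axis perpendicular to ẑ would do, and fixing +x makes output
deterministic. Cylinders are uncapped; node spheres visually cap edge ends.
Directed edges use an 80% shaft / 20% cone head split with head base radius
2t — proportions chosen once for legibility; nothing in the rendering
contract depends on them.

## Styling rules

Every "above threshold" comparison is a strict `>`, applied uniformly to
node selection, value-mode edge extraction, binarized coloring and the hub
rule, so a value exactly at the threshold is never included.

Automatic sizing maps values affinely onto a target range — node radii
[1, 5] mm, edge radii [0.3, 1.5] mm by default ("a proper range" is
unquantified, so both are configurable) — with a constant input mapping to
the range midpoint. Sparsity extraction keeps the k = round(s·N(N−1)/2)
largest candidate weights (round-half-up; ties at the k-th weight broken by
smaller row, then smaller column index — determinism over ambiguity). When
the absolute-value option combines with sparsity, the absolute value is
applied first and the top-k is taken over |w|; the kept edge retains its
signed weight. Hemisphere membership is the sign of world x; a node at
exactly x = 0 belongs to both hemispheres and thus never satisfies the
interhemispheric ("crossing") filter. Mixed-endpoint node-linked edge color
is the mean of the two endpoint RGBs (a split-shaft rendering would be
renderer-dependent).

Nodal strength z-scores use the sample SD (divisor N−1); a zero SD (all
strengths equal) defines z ≡ 0 so no node is a hub, rather than NaN.

## Volume-to-surface mapping

The vertex's continuous voxel coordinate is the inverse affine applied to
its world position. The nearest voxel is the per-axis round-half-up index
(the rule has to be fixed somewhere; half-up is stated so results are
reproducible). The "neighborhood" of the block algorithms is the 3×3×3
voxel block clipped at volume borders. The extremum rule returns the block
value of largest magnitude with sign preserved; a |max| = |min| tie goes to
the positive value. Gaussian pre-smoothing defaults to σ = 1 voxel with the
kernel truncated at 2σ (configurable; σ = 0 degrades gracefully to nearest
sampling). The 1-ring vertex averaging does exactly one smoothing pass and
includes the center vertex in the mean. Vertices whose nearest voxel falls
outside the grid get value 0, are flagged unmapped, keep the surface base
color, and are excluded from colormap autoscaling.

The 24 colorbar presets comprise the six canonical names (jet, hsv, hot,
cold, winter, summer) plus 18 widely used ramps; `cold`, which has no
universal definition, is a blue→cyan ramp. Custom colorbars are n×3 RGB
tables in [0, 1]; vertex colors interpolate piecewise-linearly between rows
over the display range, clamping outside it.

ROI isosurfaces take the binary mask (grid == label), zero-pad it so
boundary clusters close, run marching cubes at level 0.5 in voxel space,
and push vertices through the affine. The construction requires
integer-valued grids and suggests rounding otherwise, instead of silently
exact-matching floats.

## Scenes, layout and export

Layout rules: single → 1 panel; medium → 4 (lateral and medial per
hemisphere); full → 6 panels when the surface is not hemisphere-divisible
(left, right, dorsal, ventral, anterior, posterior) and 8 when it is
(per-hemisphere lateral/medial plus the four whole-brain views). A surface
is divisible iff no triangle mixes strictly-negative-x and
strictly-positive-x vertices. Node and edge glyphs go to hemisphere panels
by the x sign of their centroid; whole-brain panels get everything. The
medium layout on a non-divisible surface is an error by default, with an
explicit fallback flag that draws the whole brain in each panel.

The named camera views are documented constants (the azimuth/elevation
table in `scene_render`); material/shading/lighting names map to distinct,
deterministic shading parameter sets. The contract is that each named
option is distinct and reproducible, not photometric identity with any
particular renderer — the `Scene` is a backend-independent inventory, and
the tests assert on it, not on pixels.

Images are rendered offscreen at exactly the requested pixel dimensions
(physical units convert as px = inches × DPI); rasters are produced from
the RGB frame buffer, EPS through the vector backend with the 3-D content
rasterized into the container. Rotation videos make one full clockwise
azimuthal turn; defaults (1°/frame, 30 FPS, 735×534) give a 12 s, 360-frame
video. GIF output is always available; AVI/MP4 require an ffmpeg-backed
imageio plugin and fail with an explicit message otherwise.

## Synthetic data

The generators produce the study conditions for every test: two
icosphere-derived jittered blobs at x = ±(gap/2 + extent) for a
hemisphere-divisible surface (gap 0 merges them into a non-divisible one);
toy networks of 2–200 nodes with coordinates split across hemispheres,
integer module indices, degree-proportional sizes, and exactly
round(density·N(N−1)/2) nonzero upper-triangle weights; and volumes that
are constant, the gradient value(i,j,k) = i + 10j + 100k (every voxel value
uniquely identifies its index, which makes sampling rules checkable by
hand), or disjoint integer-labeled blocks. All generation is seeded and
bitwise reproducible.

These fixtures are deliberately not anatomical: they exercise the
geometric, topological and file-format rules exactly, but passing tests say
nothing about anatomical plausibility of real cortical meshes, about
registration quality between a real volume and surface, or about rendering
aesthetics at 80k-vertex scale. Test sizes (tens of vertices, ≤12-node
matrices, ≤10³ voxel volumes, ≤480 px renders, ≤8-frame videos) were chosen
so the full suite exercises every code path in seconds; all operations are
O(vertices) or O(N²) and scale to atlas-sized inputs unchanged.

## Known limitations

Binary FreeSurfer/BrainVISA mesh formats, GIFTI/CIFTI, interactive viewing,
community detection (module indices are inputs), geodesic surface
smoothing, and photometric reproduction of any reference renderer are out
of scope. EPS output embeds a raster of the 3-D content. The matplotlib
backend paints whole triangles back-to-front per collection, so exact
occlusion between interpenetrating meshes can differ from a z-buffered
renderer.
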