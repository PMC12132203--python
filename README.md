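# sepalgrowth

Statistics for quantifying **cell-growth heterogeneity** and
**cortical-microtubule organization** in lineage-tracked plant tissue,
with a synthetic morphogenesis simulator used to calibrate and validate
every estimator.

Developing organs such as the *Arabidopsis* sepal reach remarkably
reproducible sizes and shapes even though the growth of their individual
cells is highly variable. One proposed mechanism is *spatiotemporal
averaging*: if a cell's deviation from the organ-scale growth pattern is
uncorrelated in time and space, fast and slow growth cancel out over
days and across neighborhoods, leaving cumulative growth uniform. When
fluctuations become temporally persistent or spatially clustered, that
averaging fails and growth becomes patchy. This package quantifies both
failure modes from time-lapse segmentation exports, and relates them to
microtubule organization.

## What it computes

Given per-cell tables (area, centroid, neighbors, normalized
proximal–distal position `x`, microtubule direction and anisotropy) and
per-interval lineage growth ratios `g` (final/initial footprint area
over each 24-h interval):

- **Target growth** `ĝ(x)`: an ordinary least-squares third-order
  polynomial of growth ratio versus proximal–distal position, fitted per
  replicate and interval — the smooth basipetal growth gradient.
- **Growth fluctuations** `f = g − ĝ(x)`: each cell's deviation from the
  organ-scale pattern.
- **Temporal correlation score** `r̄`: the Pearson correlation of `f_t`
  versus `f_{t+1}` across cells for each consecutive interval pair,
  averaged over pairs. High `r̄` means cells stay persistently fast or
  slow.
- **Patchiness** `P`: fluctuations of *cumulative* growth are averaged
  over each cell's immediate neighborhood (focal cell included), and `P`
  is the standard deviation of those neighborhood means. High `P` means
  over- and under-growth is spatially clustered.
- **Alignment statistics** (axial angles, doubled-angle trigonometry):
  the microtubule–growth score `A_mg = mean(−cos 2α)` where `α` is the
  angle between a cell's principal growth direction and its microtubule
  direction at the interval start (−1 parallel, +1 perpendicular), with
  optional weights `w = a_m · a_g` from the two anisotropies
  `(max − min)/(max + min)`; and the neighbor score
  `A_nn = mean(cos 2α)` over neighboring growth directions (+1 aligned,
  −1 perpendicular). Cells are stratified into over-/undergrowing
  relative to their neighbors and compared by permutation test.
- **Texture classification**: per-pixel structure-tensor coherence
  `c = (λ1 − λ2)/(λ1 + λ2)` labels microtubule-image pixels as
  *organized* (coherent, parallel fibers), *crisscrossed* (incoherent
  crossings / star nodes) or *background*.
- **Group tests**: Fisher z-test for comparing temporal-correlation
  scores between genotypes or treatments; seeded bootstrap for
  patchiness; permutation tests for alignment contrasts.

The `sepalgrowth.synthetic` module generates Voronoi-tessellated tissues
whose growth follows a cubic basipetal target profile plus AR(1)
fluctuations with tunable lag-1 autocorrelation `rho_time`, spatial
correlation length `ell_space`, microtubule fields coupled to growth
directions, and fiber-texture images with controllable orientation
dispersion — so every statistic can be checked against known ground
truth. See `docs/methods.md` for the model details.

## Worked example

Simulate a replicate with persistent, spatially clustered fluctuations
(`rho_time = 0.6`, `ell_space = 30 µm`, 500 cells, three 24-h
intervals), then analyze it:

```sh
sepalgrowth simulate --params params.json --out demo/
sepalgrowth analyze --cells demo/cells.csv --growth demo/growth.csv --out analysis/
```

prints

```
sim: r_bar=0.6695347446321738 patchiness=0.3653 A_mg=0.01850893315893314
```

The temporal-correlation score `r̄ ≈ 0.67` recovers the simulated
persistence (`rho_time = 0.6`; the per-pair correlations in
`analysis/report.json` are 0.637 and 0.702). Patchiness `P ≈ 0.365` is
roughly double the value obtained with the same noise level and
persistence but spatially white innovations (`P ≈ 0.175` at
`ell_space = 0`, same seed): fluctuations correlated over 30 µm survive
neighborhood averaging and accumulate into patches. `A_mg ≈ 0.02` is the
expected ≈ 0 for microtubule directions sampled independently of growth.
Full per-cell tables are written to `analysis/fluctuations.csv` and
`analysis/orientation.csv`.

Classifying a uniformly oriented (crisscrossed) fiber texture:

```python
import sepalgrowth as sg
img = sg.render_texture_image(sg.TextureParams(mode="crisscross", seed=4))
maps = sg.structure_tensor_maps(img)
sg.texture_fractions(sg.classify_texture(maps))
# {'organized': 0.0221, 'crisscrossed': 0.4503, 'background': 0.5275,
#  'organized_share': 0.0469}
```

Only ~5 % of foreground pixels are (mis)labelled organized; a parallel
fiber texture (`mode="organized", kappa_orient=20`) gives an organized
share above 0.99.

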