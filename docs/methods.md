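# Methods

This note documents the statistical model behind each estimator, the
synthetic data the package validates itself against, and the design
choices made where the analysis conventions were genuinely open.

## Data model

A tissue replicate is an ordered series of frames. Each frame holds
segmented cells with a positive footprint area (µm²), a 2-D projected
centroid (µm; the curved organ surface is assumed flattened upstream), a
symmetric, irreflexive neighbor graph, a normalized proximal–distal
coordinate `x ∈ [0, 1]` (0 = organ base, 1 = tip), and a per-cell
cortical-microtubule direction (axial degrees, `[0, 180)`) with
anisotropy in `[0, 1]`. Lineage is encoded by a `parent_id` on the later
frame; divisions produce several children of one parent, merges are
disallowed. Growth over an interval is stored per lineage as the
*footprint ratio* — summed descendant area at the interval end divided
by ancestor area at the start — so a growing cell has `g > 1`.
`pd_position` is normalized per frame to `[0, 1]`; how the distance map
underlying that coordinate is normalized across differently sized frames
is a convention of the exporting pipeline, and this package simply
consumes the normalized value.

## Fluctuation statistics

**Target growth.** For each replicate and each interval, an unweighted
ordinary least-squares cubic `ĝ(x) = c0 + c1 x + c2 x² + c3 x³` is
fitted to growth ratio versus interval-start position. OLS on the ratio
scale is the default; a `log_scale` flag fits `log g` instead for users
who prefer multiplicative residuals. A fit is refused (not silently
degraded) when fewer than `degree + 1` distinct positions are available.

**Fluctuations** are the residuals `f = g − ĝ(x)`; by the OLS normal
equations they sum to zero within each fit.

**Temporal correlation.** For each consecutive interval pair `(t, t+1)`
the Pearson correlation of `f_t` versus `f_{t+1}` is computed *across
cells*, and the per-pair correlations are averaged into the replicate
score `r̄`. Cells dividing between intervals stay matched through the
footprint lineage: daughters' fluctuations are averaged, weighted by
their interval-start areas, and paired with the parent. A per-cell
variant (each cell's own lag-1 autocorrelation, averaged over cells) is
provided behind a flag, but with the 3–4 interval series typical of
live imaging it is very noisy and the cross-cell estimator is the
default. A pair with zero variance is flagged as undefined rather than
propagated as NaN.

**Cumulative growth and patchiness.** Cumulative growth per first-frame
lineage is the final-frame footprint ratio, which equals the product of
per-interval ratios whenever divisions conserve area. A *fresh* cubic is
fitted to cumulative ratio versus first-frame position (the per-interval
fits are not reused — the cumulative profile is not the product of the
interval fits, and fitting it directly keeps the residual property
exact). Each cell's cumulative fluctuation is then averaged over the
cell *and* its immediate neighbors, and patchiness `P` is the population
standard deviation of those neighborhood means. Including the focal cell
makes the estimator reduce exactly to the plain SD on an empty graph and
keeps isolated cells well defined. `P` is invariant under adding a
constant to all fluctuations and scales linearly with them. For
spatially white fluctuations the averaging cancels noise
(`P ≈ σ/√(neighborhood size)`); spatially clustered fluctuations pass
through, so `P` rises with the correlation length of the noise.

**Group comparisons.** Temporal-correlation scores are compared with the
Fisher z-test, `z = (atanh r1 − atanh r2)/√(1/(n1−3) + 1/(n2−3))`, with
a two-sided normal p value. Patchiness is a standard deviation, not a
correlation, so the Fisher transform does not apply; patchiness between
two tissues is instead compared by a seeded bootstrap over cells
(resampling cells with replacement within each tissue, two-sided p from
the centered bootstrap distribution of the difference). This is a
deliberate deviation from treating every score with the correlation
z-test.

## Orientation statistics

All directions are axial (defined modulo 180°); every angular
computation doubles the angle, works on the circle, and halves back.
Interfaces use degrees.

- `α` between growth and microtubules is taken with the microtubule
  direction at the interval-*start* frame, the growth principal
  direction over the interval.
- The microtubule–growth score is the mean of `−cos 2α`: −1 when
  parallel everywhere, +1 when perpendicular everywhere. Weighting by
  `w = a_m · a_g` (product of the two `(max − min)/(max + min)`
  anisotropies) is applied to the angle histogram by default and to the
  score only behind a flag — per-cell group comparisons default to
  unweighted values.
- The neighbor score is, per cell, the mean of `cos 2α` to each
  neighbor, then the grand mean over cells with at least one neighbor;
  isolated cells are excluded and counted.
- Cells are *overgrowing* when their growth ratio exceeds the mean of
  their interval-start neighbors' ratios, *undergrowing* when below;
  exact ties and neighborless cells are excluded. Group differences use
  a two-sided permutation test on per-cell values: exhaustive
  enumeration when the number of relabelings is ≤ 10,000 (the p value
  is then exact), otherwise `(1 + #extreme)/(n_perm + 1)` over seeded
  random relabelings.
- Histogram default: 9 bins of 10° over `[0°, 90°]`, last bin closed.

## Texture classification

The trained-classifier step of interactive pixel classification is
replaced by a defined operator so that results are deterministic and
auditable. Per pixel, gradients are Gaussian derivatives at
`sigma_grad = 1 px`; the 2×2 structure tensor is averaged over a
Gaussian window `sigma_window = 6 px`; with eigenvalues `λ1 ≥ λ2 ≥ 0`,
coherence is `c = (λ1 − λ2)/(λ1 + λ2)` (0 where the tensor vanishes)
and energy is `λ1 + λ2`. Pixels are background where energy falls below
a threshold, organized where `c ≥ tau_coherence = 0.6`, crisscrossed
otherwise. Border pixels within `3·sigma_window` of the edge are
background (smoothing artifacts).

The default energy threshold is an Otsu split of *log*-energy, which
makes classification exactly invariant to multiplying the image by a
positive constant. Otsu always produces some split, including on a
pure-noise image whose energy histogram is unimodal; the classifier
therefore treats an image as all-background when the two Otsu classes
are separated by less than 0.6 natural-log units of energy. Pilot runs
on the generator put blank-noise separations at 0.18–0.29 and fibrous
images at ≥ 0.75, so the guard sits between the two populations.

`sigma_window = 6 px` and `tau_coherence = 0.6` were chosen together
with the generator's default fiber density (200 fibers of length 40 px
on a 192-px image): the averaging window must span several fiber
crossings, otherwise pixels of a globally disordered texture are locally
coherent (a lone fiber is perfectly "organized" at small scales) and a
crisscrossed texture misclassifies. No equivalence with any trained
classifier is claimed; the operator is validated against synthetic
textures with known orientation dispersion.

## Synthetic data generator

The generator produces data with the statistical structure the
estimators assume — it emulates the *form* of segmented organ data, not
any particular organ.

- **Tessellation**: jittered hexagonal seeds (spacing 10 µm, jitter SD
  1.5 µm) in a ~2:1 elongated rectangle; Voronoi cells clipped to the
  domain via mirrored seeds give areas and the symmetric neighbor
  graph; the long axis is the proximal–distal axis.
- **Growth**: `g_{i,t} = T(x_i) + f_{i,t}` with cubic target
  `T(x) = 1.7 − 1.2x + 0.9x² − 0.3x³` by default (≈1.7-fold per 24 h at
  the base declining to ≈1.1 at the tip, a basipetal gradient of the
  magnitude seen in young sepals). Fluctuations are additive on the
  ratio scale because the analysis fits the polynomial to the ratio
  directly. `f` follows a stationary AR(1) over intervals: SD
  `sigma_f = 0.1`, lag-1 autocorrelation `rho_time`, innovation SD
  `σ_f √(1 − ρ²)`. Innovations are spatially mixed by the Cholesky
  factor of a Gaussian-kernel correlation matrix on the initial
  centroids with length `ell_space` (µm; 0 = white). Draws producing
  `g ≤ 0` anywhere are rejected and resampled, at most 100 times.
  AR(1) plus a Gaussian kernel is the *minimal* parameterization with
  one temporal and one spatial knob; it is a stand-in for the real
  patchy phenotype, whose generative process is unknown.
- **Divisions** (default off): a cell splits when its footprint has
  doubled since birth; daughters take a uniform `[0.4, 0.6]` area
  fraction, inherit the parent's fluctuation state, position and
  neighbors, and the graph is rewired symmetrically.
- **Microtubules**: axial von Mises sampling (double the mean angle,
  sample with concentration `kappa_mt`, halve back) around a mean set
  by the coupling mode: uniform, parallel to growth, or perpendicular
  to growth (+90°).
- **Textures**: anti-aliased line segments rendered additively on a
  padded canvas (so edge clipping never bends orientations), blurred to
  the fiber width, plus Gaussian noise. `organized` draws orientations
  from an axial von Mises around one image-level mean; `crisscross` is
  the same with concentration 0; `star` groups 8 segments through
  shared centers (crossover nodes); `blank` is noise only.

All randomness derives from one integer seed through named per-operation
substreams; identical parameters give byte-identical outputs.

What the generator does **not** emulate: 3-D surface curvature,
mechanical feedback between neighbors, wall stiffness or turgor, cell
shape changes, segmentation/tracking errors, or microscope noise
statistics. Passing tests therefore demonstrate that the estimators
recover the statistical structure they target when their model holds —
not that real tissue satisfies that model.

## Validation problem sizes

- Temporal-correlation recovery: 500 cells × 4 intervals, 50 seeds per
  `rho_time ∈ {0, 0.3, 0.6, 0.9}`; the mean estimate is monotone with
  |bias| < 0.05 (pilot SD of a single estimate ≈ 0.013).
- Patchiness separation: 1000 cells × 4 intervals, `rho_time = 0.8`,
  `ell_space = 5` cell diameters versus 0, 100 paired seeds. The
  1000-cell domain is used because patchiness compares the fluctuation
  field to a cubic fitted along the proximal–distal axis: when the organ
  is only a few correlation lengths long the fit absorbs much of the
  patch signal, so the domain must hold enough patches for the contrast
  to be identifiable.
- Fisher z-test calibration: 1000 null comparisons of independent
  replicates simulated on one fixed 100-cell tessellation (2 intervals,
  `rho_time = 0`, `ell_space = 0`); the tessellation is fixed because
  the null calibration of the z-test does not depend on re-tessellating.
- Permutation-test calibration: 1000 null trials, two groups of 10,
  300 relabelings each.
- Texture ground truth: 5 seeds per mode at the defaults above.

## Numerical conventions

- Polynomial fits use `numpy.polynomial.polyfit` (least squares); the
  coefficient order is ascending in `x`.
- Population (ddof = 0) standard deviations throughout.
- Angles are reduced modulo 180° before any comparison; the acute angle
  between axes is `min(d, 180 − d)`.
- Anisotropy is 0 by convention when both principal magnitudes vanish;
  coherence is 0 where the structure tensor vanishes.
- The spatial correlation matrix receives 1e-9 diagonal jitter before
  Cholesky factorization and rows are rescaled to unit marginal
  variance.
- CSV floats are written with `repr` and read with pandas'
  `round_trip` parser, so write→read is the identity; neighbor sets are
  iterated in sorted order everywhere so results do not depend on hash
  randomization.

## Known limitations

- The temporal-correlation score is a cross-cell estimator; it can be
  inflated by any covariate (beyond the fitted cubic) that persistently
  differentiates cells, not only by genuine per-cell persistence.
- The Fisher z-test treats `r̄` as a single Pearson coefficient with
  `n` = number of matched cells; with spatially correlated fluctuations
  the effective sample size is smaller and p values are optimistic.
- The texture operator measures local orientation coherence; textures
  that are disordered at scales much larger than `sigma_window` but
  parallel locally will read as organized.
- Patchiness depends on the neighbor-graph density; comparisons are
  only meaningful between tissues with similar connectivity.
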