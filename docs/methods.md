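# Methods

This package studies how CT reconstruction choices — slice thickness and
reconstruction kernel — change the values of quantitative image features
(QIFs) computed from segmented lung lesions. It implements the full chain:
a seeded digital phantom cohort rendered at six acquisition settings, an
89-feature radiomic panel, redundancy reduction by rank-correlation
clustering, and inter-setting agreement measured with Lin's concordance
correlation coefficient (CCC). This note records the models, conventions
and numerical choices; nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Phantom model

A ground-truth lesion is rendered on a 0.25 mm isotropic grid (fine enough
that every clinical slice thickness of interest — 1.25, 2.5, 5 mm — is an
integer number of ground slices, making partial-volume averaging exact
slab arithmetic). Its components:

- **Geometry.** An ellipsoid with semi-axes `a = (a_z, a_y, a_x)` whose
  surface radius is modulated by a smooth angular term
  `r(θ, φ) = 1 + λ g(θ, φ)` with `|g| ≤ 1`; λ is the lobulation amplitude
  and g a two-harmonic product of sinusoids in the polar angles with
  seeded random phases. λ = 0 recovers a pure digital ellipsoid.
- **Interior texture.** A Gaussian random field: white noise smoothed with
  an isotropic Gaussian of the texture correlation length, standardized,
  and scaled to the texture amplitude (an SD in HU) around the interior
  mean density.
- **Margin diffuseness.** The binary interior indicator is blended over a
  per-lesion Gaussian of width `edge_width_mm` before compositing against
  the background, emulating the clinical spectrum from sharply
  circumscribed to ill-defined margins. This is what gives boundary
  sharpness features genuine between-lesion variance. The binary
  ground-truth mask itself stays sharp.

Cohort sampling ranges (one draw per lesion from a single master seed, so
a cohort is a pure function of its seed):

| parameter | range | rationale |
| --- | --- | --- |
| semi-axes | 6–15 mm per axis | volumes ≈ 0.9–14 × 10³ mm³: compact solid lesions at the lower end of the clinically reported size span; kept modest so the full 32 × 6 pipeline renders and extracts in minutes on one CPU |
| interior mean density | −500 to +60 HU | matches the span of within-mask mean density observed across real lung lesions (solid to ground-glass); this between-tumor spread is the variance against which CCC judges setting-induced shifts |
| texture amplitude | 20–80 HU (SD) | near-homogeneous to strongly heterogeneous lesions |
| texture correlation length | 1–3 mm | multi-millimetre tissue heterogeneity (necrosis, air bronchograms), not sub-voxel noise |
| lobulation amplitude / frequency | 0.05–0.14 / {3,4,5} cycles | mildly to clearly lobulated outlines |
| margin diffuseness | 0.3–2.0 mm | sharp to ill-defined boundaries |
| base noise SD | 6–14 HU | Standard-kernel noise at the 5 mm reference thickness |
| background | −800 HU | aerated lung parenchyma |

## Acquisition surrogate

Each setting is a (thickness, kernel) pair labelled `1.25L … 5S`. Rendering
a ground truth at a setting applies, in order:

1. **Partial volume:** exact slab averaging of the ground grid over the
   slice thickness (center-cropped so dropped ground slices split between
   the two z faces); the output carries the slice thickness as its axial
   spacing.
2. **Kernel:** in-plane Gaussian smoothing with σ_S = 0.8 mm for the
   Standard (smooth) kernel; the Lung (sharp) kernel is the smooth result
   plus an unsharp mask, `L = S + α(S − G_σu(S))` with α = 2.0 and
   σ_u = 1.5 mm.
3. **Noise:** additive white Gaussian noise with SD
   `σ_n · sqrt(5 mm / thickness) · (3 if Lung else 1)` — thinner slices
   average fewer photons and sharp kernels amplify quantum noise. Noise is
   drawn independently per setting from per-lesion derived seeds.

Masks are rendered per setting by slab-averaging the binary indicator and
thresholding at 0.5 (majority occupancy). A `perturb_mask` operation
produces independent-rater variants by shifting the signed Euclidean
distance of the boundary with a smooth zero-mean random field
(boundary-localized; magnitude 0 is the identity); three variants fused by
majority vote stand in for a multi-reader consensus.

This surrogate is deliberately not a sinogram-domain CT simulation; see
Limitations for what that omits.

## Preprocessing

All volumes are resampled to a 0.5 mm isotropic grid by trilinear
interpolation before feature extraction — the only intensity preprocessing.
The output grid tiles the input's physical cell extent with cell-centered
voxels (`center_k = origin − s/2 + (k + ½)t`). Cell-centered tiling was
chosen over anchoring output centers at `origin + k·t` because node
anchoring puts integer-ratio resampling points exactly on 0.5
interpolation midpoints, which biases thresholded masks by half a voxel
per face; with cell centering a 2× mask upsample preserves volume exactly,
and an equal-spacing resample is the identity. Values sampled outside the
input extent take the nearest-edge value. Masks are resampled by
interpolating the 0/1 field and thresholding at 0.5 (configurable to
nearest-neighbour); interpolate-then-threshold gives smoother surfaces for
the curvature and profile features. Multi-rater masks are fused by strict
majority (for three raters: at least two).

## The 89-feature panel

Nine families, frozen in a versioned manifest
(`FeatureRegistry.to_manifest`); counts in parentheses.

- **Size/shape (9).** Volume (voxel count × voxel volume), surface area
  (marching-cubes mesh), maximum 3D diameter (largest pairwise
  surface-voxel distance, via the convex hull), compactness
  36πV²/A³ ∈ (0, 1], sphericity (its cube root), major/minor axis lengths
  (4√λ of the inertia-tensor eigenvalues), eccentricity
  `sqrt(1 − λ3/λ1)`, elongation `sqrt(λ2/λ1)`.
- **Shape-index histogram (9).** The mask is smoothed with a 1 mm Gaussian
  and treated as an implicit surface; principal curvatures κ1 ≥ κ2 come
  from the implicit-surface mean/Gaussian curvature formulas (the 3×3
  adjugate computed via Cayley–Hamilton). The shape index
  `SI = (2/π)·arctan((κ1+κ2)/(κ1−κ2))` is histogrammed into 9 equal bins
  over [−1, 1] at surface voxels and normalized. Umbilic points
  (|κ1−κ2| < 1e−6) take SI = sign(κ1+κ2); flat points (both ≈ 0) are
  dropped.
- **Sigmoid sharpness (2).** Density profiles along outward surface
  normals (±4 mm, 0.25 mm steps, up to 64 evenly-subsampled normals) are
  fitted with `s(t) = A + B/(1 + exp(−(t−t0)/w))` by bounded nonlinear
  least squares (3 starts over t0; w ∈ [0.05, 10] mm). Per-profile
  sharpness is the fitted sigmoid's maximal slope |B|/(4w); the lesion
  features are the medians of slope and |B| over successful fits
  (contrast ≥ 10 HU). The fit-failure fraction is reported alongside but
  is not a panel feature.
- **Histogram statistics (10).** Mean, population SD, population skewness
  and excess kurtosis (both 0 by convention for constant regions), entropy
  of the 25-HU-binned histogram, and percentiles P10/P25/P50/P75/P90.
- **GLCM (5).** Densities quantized into 25-HU bins over the within-mask
  range (≤ 64 levels); co-occurrence counts accumulated at distance 1 over
  the 13 unique 3D directions (pairs with both voxels in the mask), summed
  across directions, symmetrized, normalized. Energy, entropy, contrast,
  homogeneity, correlation (correlation of a single occupied level is 1 by
  convention). Summing before normalization, rather than averaging
  per-direction features, is the single documented rotation-robust
  convention.
- **Laws' energy (14).** Separable 3D filters from the 5-tap vectors L5,
  E5, S5, R5, W5; the bank is the 14 factor multisets
  {ELL, SLL, RLL, WLL, EEL, SSL, RRL, WWL, ESL, SRL, EEE, SSS, RRR, WWW},
  every one containing a zero-sum factor (hence invariant to global HU
  shifts). Each feature averages the mean absolute response over the
  distinct axis-permutations of its multiset so no axis is privileged.
  Responses are measured inside the mask eroded by 2 voxels (filter
  support must not straddle the boundary); if erosion empties the mask the
  full mask is used.
- **LoG (12).** Laplacian-of-Gaussian at σ ∈ {1, 1.5, 2, 2.5} mm
  (converted to voxels through the spacing; Laplacian in physical HU/mm²
  units). The discrete truncated kernel is made exactly zero-sum by
  subtracting `f · LoG(1)`, so constant fields map to exactly zero. Per
  scale: within-mask mean, SD, and 64-bin response entropy; names carry
  the scale suffix (`LoG_Entropy_s2.5`).
- **Wavelet (28).** Separable orthogonal DWT, 4-tap Daubechies filter
  (PyWavelets `db2`) in periodized mode (energy-preserving), 2 levels; the
  7 detail subbands per level are summarized within the mask (carried down
  the pyramid by 2×2×2 max-pooling) by mean squared coefficient and
  magnitude entropy.

`extract_all` refuses non-isotropic input (resample first), returns one
finite value per registry entry in registry order, and is deterministic.

## Redundancy reduction

Each feature's profile is its value vector over all tumor × setting
observations (192 for the default study). Pairwise similarity is
Spearman's ρ (midranks); the clustering distance is `d = 1 − ρ` — signed,
so anticorrelated features are *not* merged (a `1 − |ρ|` switch exists;
which convention the original analysis used is not documented, and the
41/23 in-vivo cluster counts are the first thing to re-check under the
other mode). The tree is unweighted average linkage (UPGMA), implemented
in-package as the explicit O(n³) agglomeration with Lance–Williams
updates and a deterministic tie rule (among equal-distance pairs, the
pair whose name-ordered representatives are lexicographically smallest
merges first); at n = 89 leaves the cost is irrelevant and the explicit
loop keeps the tie rule exact. SciPy's average-linkage serves as an
independent cross-check in the tests via cophenetic distances.

Cutting at height t keeps merges with height ≤ t, i.e. groups features
whose average Spearman correlation is ≥ 1 − t; cuts are nested in t.
Zero-variance features have undefined ranks: they are dropped from the
tree, reported, and re-attached as singleton groups. Collapsed group
values are means of member z-scores (z fitted per feature over all
observations with the sample-SD convention), making the collapse
invariant to each member's location and scale; constant members are
excluded from the average (an all-constant group collapses to 0, logged).

## Inter-setting agreement

For one feature and one pair of settings, x and y are the per-tumor values
at the two settings and

    CCC = 2 cov(x, y) / (var x + var y + (mean x − mean y)²)

with population (1/n) moments (Lin's original estimator; a ddof switch is
provided). CCC is computed on **raw** feature values — per-setting
standardization would erase exactly the location/scale disagreements CCC
is designed to detect. If both vectors are constant the cell is flagged
(NaN), excluded from averages, and never imputed.

The six settings give C(6,2) = 15 unordered comparisons, categorized:
**a** same kernel / different thickness (6 pairs), **b** same thickness /
different kernel (3), **c** smooth kernel on the thinner slice vs sharp on
the thicker (3), **d** sharp on the thinner vs smooth on the thicker (3).
Group CCCs are arithmetic means of member-feature CCCs; summaries order
comparisons and groups by descending average CCC and count groups strictly
above 0.8 and strictly below 0.7.

## Problem sizes and runtimes

The default study is 32 lesions × 6 settings = 192 renderings; ground
grids are ≈ 130–180 voxels per side at 0.25 mm, analysis grids ≈ 65–90 per
side at 0.5 mm. On one CPU the full simulate→extract stage takes about
five minutes; clustering and agreement are seconds. These sizes are the
package's own defaults, chosen so the complete study runs interactively;
the generator accepts larger lesions and cohorts unchanged.

## What the phantom study does and does not show

The generator emulates the two effects under study — partial-volume slab
averaging and smooth-vs-sharp in-plane kernels with noise amplification —
with wide between-lesion heterogeneity in size, density, texture and
margin sharpness. Passing the cohort-level tests shows that the *pipeline*
recovers the expected qualitative structure from data with these
properties: volume and size features agree almost perfectly across all
settings; fine-texture features (GLCM, Laws, level-1 wavelets) lose
agreement fastest; same-kernel comparisons agree better than
sharp-thin-vs-smooth-thick ones (category a > d).

It does not certify behaviour on real CT. Known gaps:

- **Kernel realism.** Real reconstruction kernels differ far more than a
  Gaussian-plus-unsharp surrogate (strong MTF shaping, streaky spatially
  correlated noise). In the simulated cohort, changing kernel at fixed
  thickness (category b) therefore damages agreement *less* than it does
  in vivo, where b ranks below a; the surrogate reproduces a > c > d but
  not the in-vivo position of b. Conclusions about category b should come
  from the in-vivo feature table, not the phantom.
- No dose/kVp/mA or scanner-model effects; no sinogram physics.
- Lesion sizes span ~0.9–14 × 10³ mm³, the lower portion of the clinical
  span; very large lesions (up to 1.5 × 10⁵ mm³) are not exercised by
  default.
- The main pipeline uses geometric ground-truth masks rendered per
  setting; rater variability exists only through the optional
  `perturb_mask`/consensus path.

## Degenerate inputs and numerical conventions

- Readers reject empty grids, non-positive spacings, non-finite values and
  2D payloads; feature tables reject duplicate keys, ragged feature sets
  and non-numeric cells, naming the offending key.
- Constant regions: SD/entropy/skewness/kurtosis 0; GLCM single-cell
  matrix (energy 1, contrast 0, entropy 0, correlation 1); all Laws and
  detail-wavelet energies 0; LoG response exactly 0.
- Sigmoid fits on contrast-free profiles are flagged and excluded; a
  lesion where every fit fails is an error, not a silent zero.
- UPGMA heights are clamped monotone against float jitter (≤ 1e−12) and
  validated nondecreasing on every build.
- All seeds derive from a single integer via `numpy` Generators; identical
  seed and configuration reproduce every volume, table and matrix
  bit-identically.
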