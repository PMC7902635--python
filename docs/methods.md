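# Methods

This note records how each stage of `polypfeat` is defined, the defaults
and why they were chosen, and what the synthetic benchmark does and does
not demonstrate.

## Shape: polar sampling and the Fourier descriptor

The descriptor operates on the expert-marked binary mask, not on gray
levels: region-based shape analysis weighs all interior pixels, which is
robust to boundary noise in a way contour descriptors are not.

*Polar raster.* The mask is sampled on `R = 64` rings × `T = 64` angles
anchored at its centroid, with ring `R−1` on the minimal enclosing circle
centered there, bilinear interpolation, and zeros outside the image.
Powers of two comfortably oversample the retained 4 × 9 frequency band.
Centroid anchoring makes the descriptor translation-invariant by
construction (exact to floating-point round-off); rotating the mask
cyclically permutes the angular axis, so coefficient magnitudes are
rotation-invariant up to interpolation error.

*Transform and normalization.* The polar grid is Fourier-transformed with
the kernel `exp[−j2π(j ϱ / R + i ψ / T)]` (ring index `j`, angle index
`i`), a plain 2-D DFT on the raster whose DC term is the sample sum. The
first descriptor entry is `|DC|` divided by the bounding-circle area
*measured in raster samples* (`R·T`), i.e. the fill fraction of the
bounding circle in sampling measure. Measuring the circle in pixel units
would reintroduce a scale dependence that the normalization exists to
remove; the pixel-area variant remains available (`area="pixels"`) for
comparison. All other entries are divided by `|DC|`, which cancels any
uniform weighting of the samples. Entries are ordered radial-major:
(0,0), (0,1), …, (0,8), (1,0), …, (3,8) — 36 values.

*Segmentation.* When only a ground-truth-marked frame is available, the
mask is recovered by 2-cluster K-means on gray intensity (10 restarts,
fixed seed — invariant to positive affine intensity rescaling), keeping
the brighter cluster's largest connected component with holes filled.

## Texture and color: the nonsubsampled contourlet transform

Color conversion uses full-range BT.601 YCbCr: Y carries texture, Cb/Cr
carry color, and the chroma planes are decorrelated — the property that
makes per-plane sub-band statistics meaningful.

*Construction.* The transform iterates a two-channel à-trous pyramid
split (analysis kernels upsampled by `2^s` at stage `s`) and fans each
bandpass plane out through a nonsubsampled directional filter bank (depth
2 realized with quincunx-upsampled fan kernels). Level vector `[1, 2, 2]`
(coarse→fine directional depths) yields 1 + 2 + 4 + 4 = 11 sub-bands per
plane, all at input size. Boundary handling is periodic, which makes the
decomposition commute exactly with circular shifts.

*Filters.* All 2-D kernels are zero-phase and synthesized from 1-D
halfband prototypes expressed as Chebyshev polynomials in `cos ω`, mapped
to 2-D by the McClellan transform (near-circular map for the pyramid,
diamond map for the fans). Because the substitution is a ring
homomorphism, the 1-D Bezout identity `H0·G0 + H1·G1 = 1` carries to 2-D
exactly, so decompose → reconstruct is an identity to round-off — the
binding contract for every supported pair, enforced by tests at 1e-6 and
observed at ~1e-12.

  - `9-7`: the CDF 9/7 biorthogonal lowpass pair; the complementary
    channel is its modulation, so both highpass kernels vanish at DC.
  - `pyrexc`: the maximally-flat halfband with two vanishing moments,
    `p²(1+2q) + q²(1+2p) = 1` with `p = (1+cos ω)/2`, factored with the
    two highpass filters exchanged (the longer factor on the analysis
    side).
  - `pkva`: Lagrange (Deslauriers–Dubuc order-3) interpolating halfband —
    the prototype underlying ladder fan filters.
  - `sinc`: Hamming-windowed ideal halfband with the exact halfband
    structure enforced (odd taps only).

  Fan analysis pairs are complementary (`u0 + u1 = δ`), so directional
  synthesis is the plain sum; directional kernels are not additionally
  upsampled across pyramid stages — wedge selectivity is radially
  invariant, and mid-sector gratings concentrate >80 % of bandpass energy
  in the matching wedge.

*Sub-band statistics.* Sub-band coefficients are heavy-tailed, which the
two-parameter generalized Gaussian captures: density
`β/(2αΓ(1/β)) exp(−(|x|/α)^β)`, with β = 2 Gaussian and β = 1 Laplacian.
Coefficients are mean-centered before fitting (the lowpass band otherwise
carries the plane's mean). The ML shape estimate solves the profiled
estimating equation by bracketed root finding on β ∈ [0.1, 10]; when no
sign change exists (extremely flat or spiky samples) a 200-point
profile-likelihood grid is used and the fit flagged unconverged. The F2
statistics are the sample mean and standard deviation (ddof = 1); the σ
column is a standard deviation, not a variance. Feature order is fixed and
recorded in column names: channel-major (Y, Cb, Cr), sub-bands
lowpass→finest, the two parameters adjacent.

By default the transform sees the full frame; a mask-cropped variant can
be built by passing cropped arrays, but the default keeps texture context
around the polyp.

## Statistical screening

Families are screened on the class factor at α = 0.05. The family-level
ANOVA tests every feature dimension separately (two-way fixed-effects
without interaction when a filter factor with ≥2 levels is present,
one-way otherwise) and Bonferroni-corrects the smallest p by the dimension
count. A scalar-summary ANOVA (per-sample descriptor mean) is also
available, but opposing class effects on different parameters (e.g. α up,
β down) can cancel in a plain mean and mask a clearly separable family —
the per-dimension form is therefore the default. Cross-family redundancy
uses Pearson correlation between per-sample descriptor means with
|r| ≥ 0.8 flagged; the two fits of the same coefficients (F1, F2) flag
each other, the shape family does not flag either. T-tests on selected
subsets are pooled-variance by default with a Welch option.

## Fuzzy-entropy feature ranking

For each feature, sample-to-class distances are absolute differences to
the class means standardized by the feature's global σ (making the score
invariant to affine feature rescaling), converted to memberships by the
inverse-distance rule with exponent `2/(ρ−1)` and row-normalized.
Defaults: ρ = 2, ε = 1e-10 (singularity guard). The feature–class mutual
information uses the full c × c fuzzy joint `P(X_i, c_j) = Σ_{k∈class j}
μ_ik / T` with natural-log entropies: `MI = H(f) + H(C) − H(f,C)`. This
is a genuine mutual information — zero for uninformative features,
maximal when memberships align with labels. A diagonal-only joint (own-
class terms alone) degenerates for balanced two-class data (−½ln½ equals
−¼ln¼), scoring perfect and useless features identically, and is
therefore not used. Constant features are flagged and pinned to MI = 0.

The dimension sweep evaluates nested top-k subsets (k = 6, 12, …, m; the
floor of 6 avoids trivially small models) under one seeded fold partition
shared across k, so the comparison is free of fold-resampling noise; ties
break toward the smaller k. Because the full set is itself a candidate,
selection can never report lower accuracy than the full feature set under
the shared folds.

## Classification and evaluation

*LSSVM.* RBF kernel `exp(−γ_k‖x−z‖²)`; training solves the KKT system
`[[0, 1ᵀ],[1, K + I/γ]]·[b; a] = [0; y]` once, with a ridge-escalation
retry on singularity and a 1e-8 residual check. γ_k defaults to the
median-pairwise-distance heuristic; γ defaults to an inner 3-fold grid
search over {0.1, 1, 10, 100} when unspecified.

*MLP.* One hidden layer of `⌈(d + classes)/2⌉` units, Adam, fixed seed,
max 400 iterations. Early stopping is deliberately not used: at ~100
training samples per fold a 10–15 % validation split is too noisy to
stop on, and a fixed iteration budget keeps runs deterministic.

*Evaluation.* Stratified five-fold cross-validation, features
standardized per fold (fit on the training split only, preventing
leakage), positive class = neoplastic. Seven metrics per fold and as
mean ± std; zero-denominator ratios report 0 and are flagged. One seeded
partition is the default; repeated partitions are a caller loop away.

## The synthetic benchmark

The generator emulates the *structure* of clinical polyp frames — one
bright, roughly elliptical region per image with class contrasts in
boundary (extra harmonics h = 2..8, total amplitude 0.12 of the base
radius), oriented texture (cosine grating, contrast 6 intensity units,
orientation 30° ± 15°, wavelength 6–9 px) and chroma (red+5/blue−5
shift), over a shared smooth isotropic texture with σ = 6 sensor noise,
96 × 96 px, 60 images per class. These defaults were fixed once to land
the benchmark in the low-to-mid-90s accuracy regime typical of clinical
two-class polyp studies. Setting the three contrast knobs to zero makes
the classes distributionally identical (the null generator).

What passing the benchmark shows: the descriptors measure the cues they
claim to (each knob moves its own feature family), the pipeline's
plumbing is correct end-to-end, and selection behaves sanely. What it
does not show: clinical performance. Real frames have specular
highlights, vignetting, instrument shadows, non-elliptical and partially
occluded polyps, and expert masks with boundary uncertainty — none of
which the generator models. The mask given to the shape descriptor is the
exact generating region, so the shape cue is noise-free and separates the
synthetic classes more cleanly than expert masks would.

## Known limitations

- Directional filter-bank depth is limited to 2 (4 wedges), the depth the
  default level vector uses.
- The NSCT kernels satisfy perfect reconstruction and directionality but
  are not bit-identical to any particular published toolbox's kernels.
- The GGD fit assumes symmetric, unimodal, zero-mean coefficients; it is
  applied to the mean-centered lowpass band as well, where the symmetry
  assumption is weakest.
- Whole-frame texture features mix polyp and background statistics; a
  tight crop changes the features and may change the ranking.
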