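# polypfeat

Shape, texture and color feature engineering for two-class colonic polyp
classification from colonoscopy frames.

During colonoscopy, clinicians grade a polyp as **non-neoplastic** (benign,
C1) or **neoplastic** (dysplastic, C2) from three visual cues: the
irregularity of its boundary, the texture of its surface, and its color.
`polypfeat` turns those cues into a compact, interpretable feature vector
and a cross-validated classification pipeline:

1. **Shape — Generic Fourier Descriptor (GFD).** The expert-marked binary
   polyp mask is resampled on a centroid-anchored polar raster and a 2-D
   Fourier transform is taken on that raster (the modified polar Fourier
   transform, MPFT):

   `MPFT(ϱ, ψ) = Σ_r Σ_i f(r, θ_i) exp[−j2π(r/R · ϱ + i/T · ψ)]`

   Retaining 4 radial × 9 angular frequencies and normalizing (DC by the
   bounding-circle area, all other magnitudes by |MPFT(0,0)|) gives a
   36-dimensional descriptor invariant to translation, rotation and scale.

2. **Texture + color — Nonsubsampled Contourlet Transform (NSCT).** Each
   YCbCr plane is decomposed by a nonsubsampled pyramid + directional
   filter bank (levels [1, 2, 2] → 11 sub-bands per plane, 33 coefficient
   sets per image), with any of four filter combinations
   {9-7, pyrexc} × {sinc, pkva}. Each sub-band's coefficients are
   summarized by a maximum-likelihood generalized Gaussian fit
   (`F1`: scale α, shape β) or by first-order statistics (`F2`: μ, σ),
   giving a 66-dimensional vector; the combined shape+texture+color vector
   has 36 + 66 = 102 entries.

3. **Screening.** Per-family ANOVA on the class factor (Bonferroni
   per-dimension control) gates descriptor families in or out; Pearson
   correlation between family summaries flags redundant families;
   independent-sample t-tests check the selected subsets.

4. **Selection — fuzzy-entropy ranking.** Per-feature fuzzy memberships
   (inverse-distance rule on σ-standardized distances to class centers)
   feed a possibility-weighted mutual information `MI(f;C) = H(f) + H(C) −
   H(f,C)`; features are ranked by decreasing MI and the dimension
   k ∈ {6, 12, …, m} with peak cross-validated accuracy is kept.

5. **Classification.** Least-squares SVM (RBF kernel, single linear KKT
   solve) and a one-hidden-layer MLP, evaluated with stratified five-fold
   cross-validation and seven metrics: accuracy, sensitivity, specificity,
   precision, recall, F-measure, G-mean.

Because clinical datasets cannot be redistributed, the package ships a
seeded generator of synthetic polyp-like image/mask pairs whose two classes
differ exactly in the three clinical cues (boundary harmonics, oriented
grating texture, chroma shift), so the whole pipeline runs and is tested
end-to-end without any download.

## Worked example

```sh
polypfeat synth   --out demo/ds --n-per-class 20 --seed 42
polypfeat extract --manifest demo/ds/manifest.csv --out demo/features.csv --scheme combined
polypfeat gate    --table combined=demo/features.csv --out demo/gate.txt
polypfeat select-eval --table demo/features.csv --outdir demo/eval --seed 1
```

prints

```
wrote 40 images to demo/ds
wrote 40 x 102 feature table to demo/features.csv
family   p_class   p_filter  gate
combined   0.0000        NA  in
selected_k = 12
classifier: mlp
    accuracy: 100.00 (+/- 0.00) %
 sensitivity: 100.00 (+/- 0.00) %
 specificity: 100.00 (+/- 0.00) %
   precision: 100.00 (+/- 0.00) %
      recall: 100.00 (+/- 0.00) %
   f_measure: 100.00 (+/- 0.00) %
      g_mean: 100.00 (+/- 0.00) %
```

Reading: each of the 40 synthetic frames became a 102-dimensional
shape+texture+color vector; the ANOVA gate found the family significantly
class-dependent (p < 0.05); fuzzy-entropy ranking reduced 102 features to
12 with no loss of five-fold accuracy; and on this synthetic contrast the
MLP separates the two classes perfectly (clinical data is harder — the
generator's default contrast is deliberately benign-to-moderate, and the
texture/color-only scheme typically lands in the high-90s rather than at
100%).

The same stages are available as library calls (`polypfeat.pipeline`,
`polypfeat.gfd`, `polypfeat.nsct`, `polypfeat.features`,
`polypfeat.selection`, `polypfeat.classify`, `polypfeat.synthdata`).

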