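# histoseverity

Continuous inflammation-severity scoring of colon-histology image
cutouts from spatial-frequency (Gabor) texture features.

Histological grading of colitis — in ulcerative-colitis biopsies or
DSS-induced mouse colitis — is ordinarily done by experts on coarse
ordinal scales, which is slow and suffers inter-observer variability.
The diagnostic morphology (crypt distortion and loss, appearance of
small round inflammatory-cell infiltrates) is essentially a change in
the spatial-frequency content of the image. `histoseverity` quantifies
it:

1. **Preprocess** — grayscale conversion, additive illumination bias
   aligning each slide's white-region histogram peak to a reference,
   512×512 cutout extraction.
2. **Gabor bank** — convolution with 216 filters
   g(x,y) = exp(−(x′²+γ²y′²)/2σ²)·cos(2πx′/λ+φ) over
   θ ∈ {0°,…,150°}, γ ∈ {0.5, 2, 4}, λ ∈ {20, 30, 40} px,
   b ∈ {5, 10, 15, 20} octaves (σ/λ tied to b), then an elementwise
   maximum over the 6 orientations → 36 response maps.
3. **Features** — mean, histogram skewness and entropy of each pooled
   map → a 108-vector per cutout.
4. **Severity score** — PCA of the training feature matrix; the first
   principal component, min-max normalized to [0, 1] (1 = most severe),
   is the score: s = (ψ₁ᵀ(x − x̄) − PC1_min)/(PC1_max − PC1_min).

A pairwise expert-comparison protocol (agreement rate, mismatch-ratio
curve vs. score difference Δ, effective resolution) validates the score,
and a synthetic generator produces histology-like cutouts with known
latent severity so the whole pipeline is testable without real slides.

## Worked example

```python
import histoseverity as hs
from scipy.stats import spearmanr

# a synthetic cohort: 3 severity levels x 20 cutouts, known ground truth
cutouts, truth = hs.generate_cohort(20, [0.0, 0.5, 1.0], seed=7)

bank = hs.build_bank()                          # 216 filters
X = hs.compute_feature_matrix(cutouts, bank=bank)   # 60 x 108

model = hs.SeverityModel(X, labels=truth["severity"].to_numpy())
res = model.fit()
print(res.summary())

scores = res.training_scores["score"].to_numpy()
print("Spearman vs latent severity:",
      round(spearmanr(truth["severity"], scores).statistic, 3))
```

Output:

```
PC1 severity score — PCA of Gabor texture features
======================================================
cutouts (n):            60
features (m):           108
centering:              True
standardized:           False
PC1 variance fraction:  0.9988
PC2 variance fraction:  0.0009
raw PC1 range:          [-64.4571, 63.6954]
orientation sign:       -1
largest |PC1 loading| features:
  b5_lam40_gam0.5_mean         -0.4284
  b10_lam40_gam0.5_mean        -0.3989
  b15_lam40_gam0.5_mean        -0.3980
  b20_lam40_gam0.5_mean        -0.3980
  b5_lam30_gam0.5_mean         -0.2429
Spearman vs latent severity: 0.943
```

PC1 carries 99.9% of the feature variation on this cohort, and the
normalized score ranks the cutouts almost exactly as their latent
severity does (ρ = 0.94); mean scores rise strictly across the
healthy → intermediate → severe levels. `res.score(features)` scores
new cutouts (clipped into [0, 1] with a flag when they fall outside the
training range), `res.contributions()` gives per-feature PC1 loadings,
`res.plot_scree()` / `res.plot_contributions()` the standard plots.

A command-line interface mirrors the library:

```sh
histoseverity simulate --levels 0,0.5,1 --n 50 --seed 42 --out cohort/
histoseverity preprocess IMG.tif --reference REF.tif --cutouts coords.csv --out cuts/
histoseverity features cuts/*.png --out features.csv
histoseverity fit features.csv --labels labels.csv --out model.json
histoseverity score model.json features.csv --out scores.csv
histoseverity validate --scores scores.csv --choices choices.csv --bins 20 --threshold 0.05
```

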