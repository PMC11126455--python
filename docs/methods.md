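# Methods

## Texture features

All features operate on the masked droplet interior (the ROI).  First-order
statistics use the raw 8-bit intensities X(1..N_p) and the normalised
histogram p(i) over the N_g distinct values present:

* Mean, Variance (population, 1/N_p), Skewness μ₃/σ³, Kurtosis μ₄/σ⁴
  (not excess), RootMeanSquared, Energy = Σ(X+c)², Uniformity = Σp(i)²,
  Entropy = −Σ p(i) log₂(p(i)+ε).

The shift c defaults to 0 (8-bit input is non-negative) and ε is fixed at
2.2·10⁻¹⁶ in every entropy term.  Skewness and Kurtosis are defined as 0 on
zero-variance input so a constant frame never produces NaNs.

Matrix features operate on quantized gray levels: bin index
⌊intensity / bin_width⌋ with occupied bins remapped to consecutive levels
1..N_g.  The default matrix bin width is 25 (FOS always uses the raw
intensities).  The four matrices:

* **GLCM** P(i,j | δ,θ): symmetric pair counts at offset distance δ = 1 for
  θ ∈ {0°, 45°, 90°, 135°}; both pixels must lie inside the mask.  Eight
  features (Contrast, Correlation, IDM, MaximumProbability,
  DifferenceAverage, DifferenceVariance, SumEntropy, DifferenceEntropy)
  are computed per angle and arithmetically averaged.  Correlation uses
  (Σ p·ij − μₓμ_y)/(σₓσ_y) and is set to 1 on a constant region (0/0
  otherwise).  Degenerate angles (no valid pair) are excluded from the
  average.
* **GLRLM** P(i,j | θ): maximal constant-level runs along each lattice line
  in the four directions; masked-out pixels break runs, so
  Σ j·P(i,j|θ) = N_p per angle.  GrayLevelNonUniformity divides by N_r(θ);
  four features, averaged over angles.
* **GLSZM** P(i,j): 8-connected equal-level zones (rotation independent),
  Σ j·P(i,j) = N_p.  Five features; ZoneVariance uses the size-axis mean
  μ = Σ p·j by analogy with RunVariance.
* **GLDM** P(i,d): for each ROI pixel, d = number of in-mask neighbours
  within Chebyshev distance δ = 1 (centre excluded) whose level differs by
  ≤ α = 0; columns are indexed by the raw count d ≥ 0 and ΣP = N_p.  The two
  NonUniformity features divide by ΣP, mirroring the GLSZM normalisation.

These conventions (8-connectivity, Chebyshev neighbourhoods, consecutive
level indices in intensity-weighted means, the ε guard) are the 2D
reduction of the usual radiomics toolbox conventions.  Shape features are
deliberately out of scope: the droplet is pinned and its outline static, so
shape carries no class information in this setting.

## Stage segmentation

Normalised time is frame index / (n_frames − 1).  The drying process is
split at breakpoints (0.40, 0.75) of normalised time into initial / middle
/ final stages — intervals are left-closed, right-open, with the final
stage closed at 1, so every frame receives exactly one stage.  The
published stage durations (240 s + 210 s + 90 s of a ~600 s process) are
internally inconsistent (they sum to 540 s), so the breakpoints are
configurable; 0.40 = 240/600 and 0.75 = 450/600 are the defaults.

## The additive stage model

`TextureGAM` fits a Gaussian additive model of the encoded class
y ∈ {0, 0.25, 0.5, 0.75, 1} on the 30 features:

* Each smooth term is a **fixed-df natural cubic spline** with knots at the
  predictor's quantiles.  With the default `smooth_df = 4` a term
  contributes 3 basis columns (linear + 2 curvature), hence the uniform
  per-term Df of 3 in the fit report; `smooth_df = 2` degenerates to
  ordinary multiple regression, which is exploited as an exact oracle in
  the tests.  Fixed-df smoothing (rather than penalised splines) keeps the
  drop-one F tests exact F statistics and makes the fit a plain least
  squares problem.
* Predictors are z-scored per slice before basis expansion; constant
  columns are zeroed with a warning and collinear basis columns are dropped
  implicitly by the least-squares rank (a warning reports the rank
  deficiency).
* Per-term significance: drop-one comparison
  F = [(RSS₋ⱼ − RSS) / dfⱼ] / [RSS / df_resid], p from the F distribution.
  p-values are reported raw (no multiplicity correction) — there are thirty
  of them and they are descriptive, not confirmatory.
* Null deviance is the total sum of squares of y; AIC is the concentrated
  Gaussian form −2ℓ + 2k with k = the design rank.

The class encoding deserves a note: a five-level label fed to a
single-response Gaussian deviance machinery only makes sense if the levels
are coded numerically, and the concentrations have a natural order and
spacing, so 0x..1x → 0..1 is the default (any injective encoding can be
configured).  An ordered-numeric response means the model measures how well
texture *predicts concentration*, which is exactly the class-separation
question.

`compare_stages` fits the same model independently on four slices (all
frames, and each stage alone, each slice scaled on its own rows) and ranks
them by AIC.  AIC is not adjusted for the differing slice sizes — the
slices are the objects being compared, as wholes; a stage in which texture
pins down the class sharply yields a small residual deviance and a far
lower AIC despite its smaller n.

## Clustering and separability

Each slice is z-scored, then:

* **k-means** — Lloyd iterations from k-means++ starts, k = 5, 25 restarts,
  keeping the restart with minimal within-cluster sum of squares.  The
  restarts are realised as independent single-start runs (scikit-learn)
  with seeds derived from the user seed, so the per-restart WCSS vector is
  exposed and the best-of-restarts contract is directly checkable.  Empty
  clusters are re-seeded internally, keeping k fixed.
* **2D projection** — scores on the two leading principal components of the
  scaled feature matrix; explained-variance fractions equal the covariance
  eigenvalue fractions.
* **Overlap** — each class's projected scatter is summarised by a 2D
  Gaussian (sample mean and covariance; 1e-8 ridge when singular); the
  pairwise overlap is the Bhattacharyya coefficient exp(−D_B), which is 1
  for identical distributions and < 0.01 for equal-covariance classes ~10
  sd apart.  The 95% concentration ellipses used for plotting derive from
  the same Gaussians.
* **Agreement** — the adjusted Rand index between cluster assignments and
  true labels: 1 iff the clustering is a relabelling of the classes, ≈ 0
  under label shuffling.  The published analysis argues visually from
  non-overlapping ellipses; the agreement index is this package's
  quantitative stand-in.

PCA is computed per slice (not once globally): each slice is scaled and
analysed as its own dataset, consistent with the per-slice model fits.

## The synthetic study

`droptex.synthetic` generates the five-class study the analysis assumes.
Per class (profile defaults in parentheses, 0x → 1x):

| parameter | meaning | defaults |
| --- | --- | --- |
| `intensity_ceiling` | 8-bit level of bright domains in the final stage | 235, 205, 175, 145, 115 |
| `bright_fraction` | final ROI area covered by bright domains | 0.70, 0.60, 0.50, 0.40, 0.30 |
| `domain_scale` | correlation length (px) of the domain field | 8, 6, 4.5, 3, 2 |
| `surge_rate` | steepness of the middle-stage rise | 10, 9, 8, 3.5, 3 |
| `noise_sd` | per-frame additive noise (8-bit levels) | 4 |

Mechanism: a frozen Gaussian random field (white noise smoothed at
`domain_scale`, unit variance) is thresholded at a level that falls through
the middle stage, so bright domains nucleate and grow to the class's final
coverage; the mean level rises with a tanh ramp of steepness `surge_rate`
(a rate of 0 disables the rise exactly, giving a degenerate static movie
when noise and the initial texture are also zero).  The initial stage is a
dim smooth field (base level 20, texture sd 5) with a small sinusoidal
drift, nearly identical across classes — physically, early capillary flow
does not depend on the buffer concentration.  Everything outside the fixed
circular mask (radius 0.9 of the half-width, pinned contact line) is 0.

The monotone ceiling and coverage encode the salt-quenching of
birefringence; both falling together makes the five class centroids lie
close to a low-dimensional manifold in feature space, which is what gives
the final-stage slice its dominant two-component PCA share.  Determinism:
per-class seed = config seed + 1000·(class index + 1), so adding a class
never perturbs the others.

What the generator does **not** emulate: coffee-ring deposition profiles,
crack formation and film buckling mechanics, salt crystallisation, LC
director fields and defect structures, illumination drift, or camera
artefacts.  Passing tests on synthetic data therefore demonstrate that the
pipeline recovers class structure *of the kind the drying physics is
believed to produce* — not that it would recover it from any particular
real microscope's output.

## Problem sizes and defaults

The default simulation matches the emulated protocol: 300 frames per
droplet at 150×150 px (1500 frames total).  The acceptance script and the
heavier tests run a reduced study — 120 frames per droplet at 96×96 px over
ten seeds — which preserves all the qualitative structure (stage contrast,
class ordering, final-stage dominance) at a fraction of the cost; the
reduced size is the package's chosen trade-off between statistical
resolution and turnaround time.

## Numerical choices

* ε = 2.2·10⁻¹⁶ inside every entropy logarithm; entropies of single-cell
  distributions are ≈ 0 (exactly −log₂(1+ε)).
* Feature CSVs are written at 17 significant digits so a written-and-reread
  table reproduces model deviances to well below 1e-10.
* Least squares via LAPACK SVD (`numpy.linalg.lstsq`); rank decides the
  residual df, so collinear bases degrade gracefully.
* k-means restart seeds are drawn from a generator seeded by the user seed
  and kept below 2³¹.

## Known limitations

* One droplet per class (as in the emulated protocol) confounds droplet
  identity with class; the clustering agreement therefore measures
  droplet-level, not preparation-level, separability.
* The additive model assumes Gaussian errors around an ordered numeric
  class code; an ordinal or multinomial likelihood would be more principled
  but would not produce the deviance/AIC bookkeeping this analysis is built
  around.
* AIC comparisons across slices of different n are meaningful only as
  "which slice supports the better model of its own frames", not as a
  likelihood-ratio test.
* GLCM Correlation's zero-variance convention (1) and Skewness/Kurtosis (0)
  are conventions, not limits; they only matter for pathological constant
  frames.
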