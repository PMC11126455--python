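# droptex

Texture-based staging and classification of drying liquid-crystal/protein
droplet image series.

## The problem

A sessile droplet of protein solution doped with a thermotropic liquid
crystal (LC) dries in roughly ten minutes and, viewed between crossed
polarizers, passes through three visually distinct stages: a quiet
**initial** stage dominated by outward capillary flow, a dynamic **middle**
stage in which the receding fluid front and film buckling make bright
birefringent domains surge, and a stabilized **final** stage whose texture
is the droplet's "fingerprint".  Droplets prepared at different buffer
concentrations (0x, 0.25x, 0.5x, 0.75x, 1x PBS) end up with systematically
different final textures, because salt quenches both the intensity and the
area of the optically active LC domains.

`droptex` asks, quantitatively: **which drying stage best discriminates the
five droplet classes?**  It does so with the standard radiomics-style
texture toolchain:

1. **Feature extraction** — each masked frame is summarised by 30 gray-level
   texture features: 8 first-order statistics (FOS), 8 co-occurrence (GLCM)
   features averaged over the four lattice angles, 4 run-length (GLRLM)
   features, 5 size-zone (GLSZM) features and 5 dependence (GLDM) features.
2. **Additive modelling** — the class label, encoded as the numeric
   concentration y ∈ {0, 0.25, 0.5, 0.75, 1}, is regressed on smooth
   functions of every feature,
   `y ~ s(Mean) + s(Variance) + … + s(DependenceEntropy)`,
   with fixed-df natural cubic splines (Df = 3 per term).  Each term gets a
   drop-one F test, and the Gaussian AIC is compared across four data
   slices: all frames, and the initial / middle / final stage alone.
3. **Clustering** — each slice is z-scored and clustered with k-means
   (k = 5, best of 25 k-means++ restarts by within-cluster sum of squares),
   projected on its two leading principal components, and summarised by the
   adjusted Rand agreement with the true classes and the pairwise
   Bhattacharyya overlap of per-class concentration ellipses.

Because the original microscopy movies are not publicly deposited, the
package ships a first-class synthetic generator (`droptex.synthetic`) that
emulates the three-stage dynamics and the class structure described above;
every downstream step is developed and tested against it, and works
unchanged on real PNG/TIFF movies.

## Worked example

```python
import warnings, pandas as pd, droptex
from droptex.gam import slice_tables, compare_stages
from droptex.cluster import stage_separability_report
warnings.filterwarnings("ignore")

cfg = droptex.make_default_config(seed=1, n_frames=120, frame_size=96)
dataset = droptex.generate_dataset(cfg)          # 5 droplet movies
table = pd.concat([droptex.extract_feature_table(s) for s in dataset],
                  ignore_index=True)             # 600 rows x 34 columns
slices = slice_tables(table)

comp = compare_stages(slices)
for name, aic in comp.aic_by_slice.items():
    print(f"AIC[{name:7s}] = {aic:9.1f}")
print("best slice by AIC:", comp.best_slice)

rep = stage_separability_report(slices, k=5, n_restarts=25, seed=1)
for name, (proj, clus) in rep["slices"].items():
    print(f"{name:7s} agreement={proj.agreement:5.2f} "
          f"overlap={proj.mean_offdiag_overlap:6.3f} "
          f"PC1+PC2={100*sum(proj.explained_ratio):5.1f}%")
```

prints

```
AIC[all    ] =   -1165.6
AIC[initial] =    -531.1
AIC[middle ] =    -688.8
AIC[final  ] =   -2455.5
best slice by AIC: final
all     agreement= 0.19 overlap= 0.471 PC1+PC2= 81.0%
initial agreement= 0.52 overlap= 0.237 PC1+PC2= 76.3%
middle  agreement= 0.41 overlap= 0.338 PC1+PC2= 77.9%
final   agreement= 1.00 overlap= 0.000 PC1+PC2= 87.2%
```

The final drying stage is selected on every criterion: it has the lowest
AIC (the additive model predicts the class best there), its k-means
clusters agree perfectly with the true classes, its concentration ellipses
do not overlap, and its two leading principal components carry the largest
share of the variance.  Models fitted on the whole drying process do worst
— the early frames, where all classes look alike, dilute the signal.

## Command line

```bash
droptex simulate --seed 0 --out sim/            # PNG frames + masks + JSON
droptex extract  --config run.yaml --out out/   # 30-feature CSV
droptex model    --features out/features_all.csv --out out/
droptex cluster  --features out/features_all.csv --out out/
droptex run      --config run.yaml --out out/   # everything + verdict.json
```

Each stage consumes and produces the documented file formats, so stages are
independently re-runnable; `run` writes feature tables, fit reports,
clustering summaries, a verdict naming the best slice under both criteria,
and a provenance JSON.

## Layout

| module | contents |
| --- | --- |
| `droptex.synthetic` | `ClassProfile`, `SimulationConfig`, droplet-movie generator |
| `droptex.imaging` | `DropletSeries`, loading/resizing, masks, stage labels, quantization |
| `droptex.matrices` | GLCM / GLRLM / GLSZM / GLDM count-matrix builders |
| `droptex.features` | the 30 feature formulas and `extract_feature_table` |
| `droptex.gam` | `TextureGAM` / `TextureGAMResults`, `compare_stages` |
| `droptex.cluster` | k-means, 2D PCA, ellipse overlap, `stage_separability_report` |
| `droptex.pipeline` / `droptex.cli` | orchestration and the `droptex` command |

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
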