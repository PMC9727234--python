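# wmcov

Single-subject **w**hite **m**atter structural **cov**ariance connectivity:
3D wavelet-feature extraction from spatially normalized tissue-density
volumes, atlas-level correlation connectivity, weighted-network node
strengths, and cross-validated SVR brain-behaviour prediction — plus a
synthetic phantom generator so the whole pipeline is testable fully offline.

## Method overview

For each subject:

1. a level-3 separable 3D discrete wavelet transform (symlet `sym4` by
   default, symmetric boundary handling) decomposes the volume into
   `7·3 + 1 = 22` subbands;
2. subbands are block-replicated back to the native voxel grid, giving every
   voxel a 22-channel feature vector;
3. each atlas region is reduced to its mean feature vector;
4. the connectivity matrix is the Pearson correlation of regional feature
   vectors between every pair of regions (a KL-divergence similarity of
   regional intensity distributions is available as a baseline metric);
5. the strict upper triangle (`R(R−1)/2` edges, 66 for a 12-region atlas) is
   the subject's feature set.

Downstream analyses: weighted networks from significantly positive edges
with node strengths and FDR-corrected strength-score correlations; repeated
10-fold cross-validated epsilon-SVR prediction with per-fold correlation
feature selection, permutation p-values, age split-half transfer,
FDR-corrected predictive patterns, and Cohen's d model comparison.

## CLI

```bash
# synthetic cohort with a coupled edge between regions 3 and 7
wmcov phantom --grid 32,32,32 --regions 12 --subjects 200 \
      --edge 3:7:0.6 --noise 0.3 --seed 42 --out cohort/

# per-subject stages
wmcov features cohort/sub-0001.nii.gz --basis sym4 --levels 3 --out feat.nii.gz
wmcov connect feat.nii.gz cohort/atlas.nii.gz --metric wavelet --out conn/sub-0001_conn.csv
wmcov connect cohort/sub-0001.nii.gz cohort/atlas.nii.gz --metric kl --out kl.csv

# cohort-level analyses
wmcov strength conn/ --alpha 0.05 --out strengths.csv
wmcov strength-corr strengths.csv cohort/scores.csv --task score --out corr.csv
wmcov predict edges.csv cohort/scores.csv --repeats 1000 --folds 10 --seed 42 --out perf.csv
wmcov pattern edges.csv cohort/scores.csv --out pattern.csv
wmcov splithalf edges.csv cohort/scores.csv --out transfer.csv

# or everything at once from a YAML config
wmcov run config.yaml --out results/
```

A pipeline config is a YAML file; any omitted key falls back to defaults
(`levels: 3`, `folds: 10`, `repeats: 1000`, alphas 0.05):

```yaml
seed: 42
phantom:
  grid: [32, 32, 32]
  regions: 12
  subjects: 200
  edges: ["3:7:0.6"]
  score_noise_sd: 0.3
prediction:
  repeats: 100
  permutations: 1000
```

The pipeline writes all intermediates (cohort, per-subject connectivity,
edge table, strengths, performance, patterns) plus a `manifest.json`
recording the configuration and master seed; completed stages are skipped on
rerun, and identical config + seed reproduce byte-identical CSV outputs.

## Python API

```python
import numpy as np
from wmcov import (PhantomSpec, generate_atlas, generate_cohort, dwt3,
                   build_feature_volume, regional_features,
                   wavelet_pearson_connectivity, vectorize_edges,
                   repeated_cv, PredictionConfig)

atlas = generate_atlas((32, 32, 32), 12, seed=1)
spec = PhantomSpec(n_subjects=100, coupled_edges=[(3, 7, 0.8)],
                   score_noise_sd=0.3, seed=1)
volumes, table = generate_cohort(atlas, spec)

edges = []
for vol in volumes:
    fv = build_feature_volume(dwt3(vol, basis="sym4", levels=3))
    conn = wavelet_pearson_connectivity(regional_features(fv, atlas))
    edges.append(vectorize_edges(conn).values)

perf = repeated_cv(np.stack(edges), table["score"].to_numpy(),
                   PredictionConfig(n_repeats=50, seed=1))
print(perf.r_mean, perf.permutation_p)
```
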