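# betascape

Continental-scale modelling of insect **beta diversity** — the turnover in
species composition between sites — from raw georeferenced occurrence
records to fitted dissimilarity models and predicted beta-diversity maps.

The package is aimed at biodiversity informaticians and community
ecologists who want to ask: *do environmental gradients (climate,
vegetation cover) drive compositional turnover independently of
geographic distance, and which gradients matter most?*  Because the real
inputs of such a study (occurrence snapshots from aggregators, bioclim
and vegetation-cover rasters) are enormous and external, the package
ships a synthetic-world module with known ground truth so the entire
chain runs, and is verified, offline.

## The analysis chain

1. **Occurrences → sites.** Darwin-Core-style records are cleaned,
   records on 0.1° region-class boundaries removed, and coordinates
   grouped into geographic sample sites with the Markov Cluster
   algorithm (expansion/inflation on a Gaussian-kernel radius graph).
   The site × species count matrix is filtered to a fixed point
   (species at too few sites, sites with too few records).
2. **Environment.** Elevation/bioclim/vegetation-style rasters are
   sampled at site centroids, with a progressive nearest-neighbour
   coarsening fallback for nodata pixels; categorical clime/ecoregion
   grids provide class labels.
3. **Dissimilarity.** Pairwise Horn–Morisita dissimilarity

   d(x, y) = 1 − 2·Σᵢxᵢyᵢ / ((Σᵢxᵢ²/X² + Σᵢyᵢ²/Y²)·X·Y),  X = Σx, Y = Σy,

   an abundance-based overlap index robust to unequal sampling effort;
   plus Euclidean geographic distance and a Mantel contrast of
   between-class vs within-class dissimilarity.
4. **MRM.** Multiple regression on distance matrices: OLS on the
   unfolded triangles with significance from permutations of the
   response matrix, over the nested ladder *geographic*, *+climate*,
   *+vegetation*, *+both*.
5. **GDM.** Generalized dissimilarity modelling built from scratch:
   monotone I-spline transforms per predictor, negative-exponential
   link μ = 1 − exp(−η), non-negative coefficients fitted by
   deviance-minimizing IRLS with an NNLS inner step, site pairs
   weighted by species richness, and permutation tests of predictor
   significance.
6. **Maps.** Significant predictor rasters are transformed to
   biological space (partial ecological distance), reduced by PCA, and
   the first three components rendered as an RGB beta-diversity map.

## Worked example

The numbered scripts under `analysis/` run the chain on the packaged
synthetic world (24×24 grid, 5 environmental variables, 40 species,
20,000 records, 10:1 sampling-effort bias):

```bash
python analysis/01_simulate_world.py
python analysis/02_cluster_sites.py
...
python analysis/07_beta_map.py
```

Output of the site-formation and modelling steps (seed 1):

```
input records:      20000
  on boundaries:    283
  filtered out:     165
  retained:         19552
community matrix:   442 sites x 39 species

ecoregion contrast: r = 0.2882, p = 0.005 (199 permutations)

MRM model comparison (r² of compositional dissimilarity):
  ~ geographic                          r² = 0.316  p = 0.005
  ~ geographic + climate                r² = 0.359  p = 0.005
  ~ geographic + vegetation             r² = 0.333  p = 0.005
  ~ geographic + climate + vegetation   r² = 0.372  p = 0.005

GDM fitted on 97461 site pairs
percent null deviance explained: 62.0%
predictor magnitudes (sum of I-spline coefficients):
  lon              2.428  (p = 0.0476, significant)
  env04            1.448  (p = 0.0476, significant)
  ...
```

Read: composition differs more between synthetic ecoregions than within
(positive Mantel contrast); adding environmental distance matrices to
the geographic MRM model increases explained variance; the GDM explains
62% of null deviance, with longitude (the axis of the simulated
sampling-effort split and of several environmental gradients) carrying
the largest magnitude.  Step 07 writes `beta_map.tif`/`beta_map.png`,
where similar colors mean similar predicted communities.

The same pipeline is exposed as a CLI (`betascape simulate|sites|
extract|dissim|mrm|gdm|map|all --config cfg.yaml --seed N --out DIR`),
with every stage appending input/output hashes to a run manifest.

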