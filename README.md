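# soilfungnet

Analysis toolkit for **depth-stratified soil fungal communities** profiled
by amplicon sequencing: from a raw sample × OTU read-count matrix to
depth-preference statistics, probability-based β-diversity tests, and
compositionally aware co-occurrence networks with module extraction.

It is written for community ecologists working with soil-profile designs
— a grid of depth classes (spanning the O and A horizons and deeper) ×
horizontal positions × replicate cores — where sequencing effort is
strongly uneven across samples and read counts are compositional.

## What it computes

* **Preprocessing** — replicate merging, removal of OTUs with < 10 total
  reads, removal of OTUs found in negative controls, rarefaction to
  1000 reads/position, and per-depth prevalence filtering (≥ 1/3 of
  positions). Diversity analyses consume the rarefied matrix; network
  inference consumes the unrarefied counts (rarefying distorts
  compositional correlation estimates).
* **Habitat preference** — for depth *i* and OTU *j*,

  `HP(i,j) = [N_obs(i,j) − mean(N_rand(i,j))] / sd(N_rand(i,j))`

  where `N_obs` counts the samples of depth *i* containing OTU *j* and
  the null shuffles depth labels over samples. Two-sided permutation
  p-values with Benjamini–Hochberg FDR; an exhaustive-enumeration exact
  mode serves as an oracle. Scores above ~3 line up with significant
  preferences.
* **Community structure** — per-sample OTU richness with an OLS depth
  trend (F with (1, k−2) df over k depth means); Raup–Crick
  dissimilarity (occupancy-weighted null assembly); PERMANOVA
  (Anderson's pseudo-F, depth as numeric predictor, df = 1); PERMDISP
  (PCoA centroid distances with negative-eigenvalue correction); Mantel
  correlogram along the horizontal axis with progressive Holm
  correction.
* **Co-occurrence networks** — a SparCC-style log-ratio-variance basis
  correlation estimator (Dirichlet resampling, iterative exclusion,
  median aggregation) thresholded at |ρ| ≥ 0.4 into signed networks, and
  an MB-style CLR + lasso neighbourhood-selection estimator with
  StARS-style stability selection.
* **Modules** — connected components of the positive network with ≥ 2
  links, summarised by guild and taxonomy annotations.
* **Synthetic data** — a generator that emulates the sampling design
  (10 depths × 50 positions × 2 replicates, ~1200 OTUs, lognormal
  sequencing totals, ~40% position dropout) with *known planted* depth
  preferences and pairwise associations on latent basis abundances, so
  every stage can be validated against ground truth.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
import pandas as pd
from soilfungnet import (
    SyntheticConfig, generate_dataset, merge_replicates,
    filter_low_count_otus, remove_control_otus, rarefy,
    richness_per_sample, depth_trend_test, raup_crick, permanova,
    habitat_preference,
)

# 5 depths x 20 positions x 2 replicates; OTU_007 strongly prefers
# the shallowest depth (+2 cm above the O-A boundary)
cfg = SyntheticConfig(
    n_depths=5, n_positions_per_depth=20, n_replicates=2, n_otus=200,
    preference_effects={("OTU_007", dc): (3.0 if dc == "+2cm" else -3.0)
                        for dc in ["+2cm", "0cm", "-3cm", "-5cm", "-10cm"]},
    seed=7,
)
raw, metadata, truth = generate_dataset(cfg)          # 200 samples x 200 OTUs

merged, _ = merge_replicates(raw)                     # 100 positions
filtered, _ = filter_low_count_otus(merged)           # < 10 reads removed
cleaned, _ = remove_control_otus(filtered)
rarefied, _ = rarefy(cleaned, depth=1000, seed=1)     # 59 positions retained

richness = richness_per_sample(rarefied)
depth_of = pd.Series({s.sample_id: s.depth_value_cm for s in rarefied.samples})
trend = depth_trend_test(richness, depth_of)
print(f"richness trend: F(1,{trend.extra['df'][1]}) = {trend.statistic:.2f}, "
      f"p = {trend.p_value:.3f}")

dist = raup_crick(rarefied, n_null=499, seed=2)
res = permanova(dist, depth_of.reindex(dist.ids).to_numpy(), n_perm=999, seed=3)
print(f"PERMANOVA: pseudo-F = {res.statistic:.1f} (df = {res.extra['df'][0]}), "
      f"p = {res.p_value:.4f}")

hp = habitat_preference(rarefied, n_perm=9999, seed=4)
print(f"HP(+2cm, OTU_007) = {hp.hp.loc['+2cm', 'OTU_007']:.1f}, "
      f"q = {hp.q_value.loc['+2cm', 'OTU_007']:.4f}")
```

This prints:

```
richness trend: F(1,3) = 0.16, p = 0.712
PERMANOVA: pseudo-F = 3.4 (df = 1), p = 0.1760
HP(+2cm, OTU_007) = 5.7, q = 0.0445
```

No richness gradient or community-wide depth effect was planted, and
neither test flags one — the 41 dropped positions are the samples whose
sequencing totals fell below the 1000-read rarefaction threshold. The
single planted preference is recovered: OTU_007's occurrence count at
+2 cm sits 5.7 null standard deviations above the depth-label-shuffling
expectation, and it survives FDR control over all 890 depth × OTU tests.

## Command line

The same stages are exposed as a console script:

```bash
soilfungnet synth --seed 0 --out data/
soilfungnet preprocess --matrix data/counts.tsv --metadata data/metadata.tsv --out prep/
soilfungnet stats   --matrix prep/rarefied_counts.tsv --metadata prep/metadata_merged.tsv --out stats/
soilfungnet hp      --matrix prep/rarefied_counts.tsv --metadata prep/metadata_merged.tsv --out hp.tsv
soilfungnet network --matrix prep/merged_counts.tsv  --metadata prep/metadata_merged.tsv --depth "+2cm" --out nets/
soilfungnet modules --edges nets/sparcc_positive_p2cm.tsv --out mods/
soilfungnet run     --config pipeline.json      # everything, with a manifest
```

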