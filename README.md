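# megspeech

Sensor-space analysis of magnetoencephalography (MEG) recorded during
covert (imagined) and overt speech tasks, aimed at group comparisons
between a patient cohort (e.g. amyotrophic lateral sclerosis, ALS) and
healthy controls — and at detecting the cohort from *single trials*.

The package implements four complementary analyses on epoched
trial × channel × sample recordings:

1. **Sensor correlation** — Pearson correlation between every pair of
   gradiometer signals, computed per trial and averaged on *r*; summarized
   by the correlation density `D = Σ_{i<j} |r_ij| / (n(n−1)/2)`, the count
   of strong pairs (|r| > 0.5), and a bootstrap central 95% range of the
   pooled correlations.
2. **Canonical-band power distances** — Welch-integrated mean power in
   delta (1–4), theta (4–8), alpha (8–16), beta (16–30), gamma (30–59) and
   high-gamma (61–119 Hz); healthy-vs-patient channel-pair Euclidean
   distance heatmaps; a six-band one-way ANOVA with post-hoc Tukey HSD
   using the five task phrases as samples.
3. **Amplitude-envelope correlation (AEC) connectivity** — per band:
   zero-phase 4th-order Butterworth band-pass, Hilbert-envelope magnitude,
   pairwise Pearson correlation of envelopes, either averaged across single
   trials or on concatenated trials; summarized by the connectivity density
   (mean pairwise AEC) and a one-sided two-sample *t*-test between cohorts.
4. **Single-trial classification** — regularized linear discriminant
   analysis on per-channel band-power features with covariance shrinkage
   `S_γ = (1−γ)S + γ diag(S)` and coefficient threshold δ (weights with
   |w_j| ≤ δ are zeroed), tuned by stratified 10-fold grid search inside
   each fold of a **leave-one-participant-pair-out** cross-validation: every
   fold trains on 2 healthy + 2 patient participants and tests on the held-out
   healthy/patient pair, so accuracy measures generalization to unseen people.

Because raw clinical MEG is rarely shareable, the package ships a
first-class synthetic two-cohort generator (`megspeech.synth`) producing
epoched datasets with band-limited oscillatory sources over a 1/f
background, 60 Hz line noise, controllable inter-channel coupling ρ per
cohort, and a patient beta-band amplitude gain — so every stage is testable
end-to-end without any data download.

## Worked example

```python
import numpy as np
from megspeech import beta_effect_preset, generate_cohorts, SEGMENTS, CANONICAL_BANDS
from megspeech.preprocess import parse_segment
from megspeech.spectral import band_power, group_mean_band_power
from megspeech.band_distance import band_dissimilarity_summary
from megspeech.classify import extract_features, lopo_cv

es = generate_cohorts(beta_effect_preset(seed=1))       # 600 trials, 32 channels
covert = parse_segment(es, SEGMENTS["covert"])          # 1 s imagined-speech window
bpt = band_power(covert, CANONICAL_BANDS)

summary = band_dissimilarity_summary(group_mean_band_power(bpt))
print(summary.argmax_band, round(summary.anova.statistic, 1), summary.anova.df)

for band in ("delta", "beta"):
    cv = lopo_cv(extract_features(bpt, band), seed=1)
    print(band, round(cv.median_accuracy, 3))
```

Output:

```
beta 1689.5 (5, 24)
delta 0.505
beta 1.0
```

The planted patient effect (beta amplitude gain 1.5, coupling 0.6 vs 0.3)
makes beta the most dissimilar band between cohorts (ANOVA F = 1689.5 on
(5, 24) degrees of freedom — six bands × five phrases), and beta-band
features separate the cohorts perfectly across all nine
leave-one-pair-out folds while delta-band features stay at the 50%
chance level.

The same pipeline is available from a shell:

```bash
megspeech run-all --preset beta-effect --seed 1 --out-dir results/
megspeech simulate --preset null --seed 2 --out epochs.h5
megspeech classify epochs.h5 --band beta --segment covert --out cv.json
```

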