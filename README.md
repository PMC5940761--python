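# texturesurv

CT-texture survival stratification for 2-D lesion images: histogram and
grey-level co-occurrence (GLCM) texture features under multi-scale
Laplacian-of-Gaussian (LoG) filtering, ROC/Youden cutoff dichotomization with
leave-one-out cross-validation, and Kaplan–Meier / log-rank / forward-stepwise
Cox proportional-hazards analysis of disease-free survival (DFS) — plus a
synthetic cohort generator that ties lesion texture to outcome through a known
hazard model so the entire pipeline is testable end to end.

The scientific setting is radiomics of resected pancreatic-head
adenocarcinoma: lesions with *low* mean attenuation and *homogeneous* texture
(abundant desmoplastic stroma) tend to recur earlier. The package is for
researchers who want a reproducible, fully tested reference implementation of
that analysis chain — or of any 2-D masked-ROI texture → cutoff → survival
workflow — without access to patient data.

## The analysis

For a lesion image with ROI mask (stored intensity = HU + 1024; in-ROI pixels
below 0 HU are excluded as fat/air), eight features are computed at filter
scales σ ∈ {0, 1, 1.5, 2, 2.5} pixels, where σ = 0 is the unfiltered image
and larger σ band-passes coarser texture through a zero-DC LoG kernel:

* histogram: average μ, population SD, skewness, excess kurtosis;
* GLCM (symmetric, 4 directions at distance 1, raw integer gray levels):
  ASM = Σp², entropy = −Σp log₂p, contrast = Σ(i−j)²p(i,j),
  correlation = (Σij·p(i,j) − μxμy)/(σxσy).

Each feature is dichotomized at the cutoff c* maximizing Youden's index
J = sensitivity + specificity − 1 against the recurrence label (scanning every
observed value, both directions; LOOCV re-derives c* per fold and takes the
mode). Groups are compared by Kaplan–Meier restricted mean survival and the
log-rank test; per filter scale, a forward-stepwise Cox model (likelihood-
ratio entry at p < 0.05, Breslow ties, candidates pre-screened by univariate
log-rank) selects among the dichotomized features and nodal status, reporting
HR = exp(β) with Wald 95% CIs.

The synthetic generator draws spatially correlated Gaussian random-field
lesions inside polygonal ROIs (164–1,685 pixels) and survival times from an
exponential proportional-hazards model whose linear predictor uses the *true*
texture parameters, with the baseline hazard solved so the expected event
fraction matches the target (79.5% by default at n = 88).

## Worked example

```python
from texturesurv import (SyntheticConfig, generate_cohort, extract_features,
                         records_to_frame, youden_cutoff, dichotomize,
                         km_fit, logrank)
import numpy as np

lesions, records = generate_cohort(SyntheticConfig(n_patients=88, seed=42))
cohort = records_to_frame(records)
average = np.array([extract_features(l, sigmas=(0.0,))[0.0].average
                    for l in lesions])
cut = youden_cutoff(average, cohort.recurrence.to_numpy(bool), "average_0")
print(cut.describe(), "AUC", round(cut.auc, 3))
```

prints

```
average_0 <= 1089.831296 AUC 0.636
```

i.e. lesions whose unfiltered mean stored intensity is at or below ≈1090
(≈66 HU) form the high-risk group, with modest discrimination (AUC 0.64).
Continuing with Kaplan–Meier and the log-rank test
(`examples/survival_analysis.py`):

```
average <= 1089.83           mean DFS   12.8 months (95% CI 7.6-18.0, n=45)
other side                   mean DFS   26.7 months (95% CI 17.6-35.8, n=43)
log-rank p = 0.0096

            variable    coef     hr  hr_ci_low  hr_ci_high  p_value
average_above_cutoff -0.6155 0.5404     0.3367      0.8672   0.0108
```

Low-attenuation lesions recur markedly earlier (restricted mean DFS 12.8 vs
26.7 months), and being *above* the cutoff roughly halves the hazard
(HR 0.54) — the generator's low-average → higher-hazard design, recovered by
the full measurement-and-modelling chain.

The `examples/` directory has one short script per capability
(`simulate_cohort.py`, `texture_features.py`, `cutoff_dichotomization.py`,
`survival_analysis.py`, `full_pipeline.py`); each prints what it computes and
what the numbers mean.

## Pipeline and CLI

```bash
texturesurv init --config run.json        # write a default configuration
texturesurv all  --config run.json        # simulate -> extract -> cutpoints ->
                                          # survive, then render report.md
```

Stages can also run individually (`simulate`, `extract`, `cutpoints`,
`survive`, `report`); every stage writes plain CSV artifacts (`cohort.csv`,
`features.csv`, `cutoffs.csv`, `table1/3/4.csv`, `km_curves.csv`) plus 16-bit
PNG lesion/mask images, and re-running a config reproduces identical files.

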