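# normatt

**Normalization model of attention for center–surround suppression in human
motion processing.**

Viewing a small drifting grating becomes *harder* to judge when it is
embedded in a large, high-contrast surround drifting the same way — surround
suppression.  How strongly the surround suppresses depends on how widely
spatial attention is deployed: attending to both center and surround ("wide
attention") deepens suppression relative to attending to the center alone
("narrow attention"), both in duration thresholds and in motion-selective
cortical (hMT+) responses.  `normatt` implements the computational core of
that analysis as a tested, reusable Python package for psychophysicists and
cognitive neuroscientists:

* the **normalization model of attention (NMA)** over a space × motion-direction
  population,
* **suppression-index statistics** for behavioral thresholds and fMRI beta
  weights (one-sample *t* tests, 2×2 repeated-measures ANOVA, post hoc paired
  *t* tests with Bonferroni-corrected alphas),
* **model fitting** by multistart MSE minimization, with shuffle-null and
  fivefold cross-validation,
* a **1-up/3-down adaptive-staircase simulator** with maximum-likelihood
  Weibull threshold estimation, and
* a **synthetic-data generator** so the whole pipeline runs without any
  private participant data.

## The model

Population responses over spatial position *x* and drift direction *θ* follow
divisive normalization with a multiplicative attention field:

```
R(x, θ) = E(x, θ) · M(x, θ) / (S(x, θ) + σ)

E = e(x_e, θ_e) * N            (excitatory drive: stimulus pooled narrowly)
S = s(x_s, θ_s) * (E × M)      (suppressive drive: pooled broadly)
M = 1 + (g − 1) · Gauss(x; M_g) · circGauss(θ)   (attention field, baseline 1)
```

`N` is a sum of 2D Gaussians representing the center grating and the annular
surround; `*` is convolution (circular along direction, zero-padded along
space) and `×` is element-wise.  The fMRI response proxy is the mean of `R`
in a small window around its peak (`R_peak`), and duration thresholds follow
the inverse linking law `T = C / R_peak`.  Narrow vs. wide attention differ
only in the spatial width of the attention field (`M_g`): a wider field
recruits more surround into the suppressive pool, deepening suppression.

Suppression indices: behavioral `SI = (T_C+S − T_C) / T_C`; fMRI
`SI = B_C − B_C+S`.  Positive = suppression, negative = facilitation.

## Worked example

```python
import pandas as pd
from normatt import ConditionPredictor, ModelParams
from normatt.fitting import fit, normalize_betas
from normatt.synthetic import GeneratorConfig, gen_fmri_betas

predictor = ConditionPredictor()          # 121 × 72 space × direction lattice
params = ModelParams()                    # fitted group-level widths
pred = predictor.predict(params)
print({k: round(v, 3) for k, v in pred.normalized.items()})
print({k: round(v, 1) for k, v in pred.threshold_ms.items()})

betas = gen_fmri_betas(GeneratorConfig(seed=0), predictor)   # 10 participants
res = fit(normalize_betas(betas), predictor, n_starts=5, seed=0)
print(round(res.mse, 4), res.params.mg_narrow < res.params.mg_wide)
```

prints

```
{'center_only': 1.0, 'narrow_same': 0.594, 'narrow_opp': 0.949, 'wide_same': 0.414, 'wide_opp': 0.812}
{'center_only': 50.0, 'narrow_same': 84.2, 'narrow_opp': 52.7, 'wide_same': 120.7, 'wide_opp': 61.6}
0.0016 True
```

Reading the first line: a same-direction surround cuts the normalized center
response to 0.59 under narrow attention and 0.41 under wide attention, while
an opposite-direction surround barely suppresses — exactly the
attention × direction interaction seen in hMT+.  The second line shows the
corresponding predicted duration thresholds (center-only calibrated to
50 ms): thresholds rise where responses fall (84 ms narrow-same, 121 ms
wide-same).  The fit to noisy synthetic
group data is tight (MSE ≈ 2e-3) and recovers the wider attention field for
the wide-attention condition.

## Command line

```bash
normatt all --seed 1 --out run1 --shuffles 100 --folds 5
normatt stats --si-csv my_si_table.csv --out run2
```

Each run writes `data/`, `fits/`, `stats/`, `figures/` and a
`manifest.json` with content hashes; reruns with the same config and seed
reproduce identical outputs.

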