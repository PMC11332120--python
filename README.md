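# fir — fusion-induced recalibration of auditory speech perception

`fir` models and analyses a striking perceptual-learning phenomenon: after brief
daily exposure to a McGurk stimulus (incongruent auditory *baba* + visual *gaga*,
fused into *dada*), the auditory token **alone** can start to evoke the fusion
percept, and the change can persist for months.  The package is aimed at
researchers in multisensory speech perception who want to (re)analyse such
exposure studies or simulate them: it provides the causal-inference model that
predicts each participant's recalibration, the response-coding and exclusion
rules, the mixed-model and decay statistics, and a synthetic cohort generator so
the entire pipeline is testable without any data download.

## The model

Speech tokens live in a 2-D representational space (x = auditory features,
y = visual features).  A presentation creates axis-aligned Gaussian encodings:
auditory **A** (reliable along x), visual **V** (reliable along y).  Reliability
weighting pools them per axis,

    pooled_k = (A_k/σ²_{A,k} + V_k/σ²_{V,k}) / (1/σ²_{A,k} + 1/σ²_{V,k}),

and causal inference mixes the pooled estimate with **A** by the observer's
common-cause probability *p*<sub>c</sub>:

    AV = p_c · pooled + (1 − p_c) · A        (centers and covariances).

A percept is the nearest token mean to the encoded location; the distance
between the encoded A and AV locations is an error signal.  Over the first
exposure day the error shifts the auditory representation toward AV:

    A′ = A + f · (AV − A),    f = day-1 fusion fraction,

with unchanged covariance.  Auditory-only post-test percepts then follow A′;
with collinear token means the predicted %FIR (fusion percept rate) is an exact
univariate Gaussian interval mass, which doubles as the oracle for the
trial-level simulator.  *p*<sub>c</sub> is estimated per participant by
inverting the closed-form fusion rate of AV to match the observed exposure
fusion fraction (monotone bisection).

Around the model, the package implements the full behavioural analysis:
initial-consonant response coding into {Auditory, Visual, Fusion, Other},
schedule validation and control-accuracy exclusions, binomial GLMMs
(time × perceiver class, participant random intercept; Type-II analysis of
deviance; post-hoc odds ratios with log-odds-scale CIs, via lme4/car/emmeans
through `Rscript`), nonlinear least-squares decay fits
*fusion* = *a*·e<sup>*b·t*</sup> with an intercept-only model comparison, and
model evaluation by Pearson correlation with a Fisher r-to-z interval.

## Worked example

```python
import numpy as np
import fir
from fir import behavior_stats as bs
from fir.cims_model import predict_cohort
from fir.dataset_io import main_stimuli

trials, truth = fir.generate_cohort(seed=42)   # 28 participants, full design
pred = predict_cohort(trials, main_stimuli())
print(pred.head(3).to_string(index=False, float_format=lambda v: f"{v:7.3f}"))
summary = bs.evaluate_model(pred.predicted_fir, pred.observed_fir)
print(f"r = {summary.pearson_r:.3f}, 95% CI {summary.ci95[0]:.2f} to {summary.ci95[1]:.2f}")
```

prints

```
participant_id  day1_fusion_fraction  p_common  predicted_fir  observed_fir
          p001                 1.000     0.622         92.095       100.000
          p002                 0.000     0.358          0.000         0.000
          p003                 0.000     0.373          0.000         0.000
r = 0.980, 95% CI 0.96 to 0.99
```

Participant p001 fused on all five Day-1 McGurk trials, so their auditory
representation shifts fully onto the integrated AV representation and the model
predicts 92% fusion reports to the auditory-only token; they actually produced
100% (5/5 trials).  Participant p002 never fused, keeps A′ = A, and is predicted
and observed at 0%.  Across the cohort the model explains the individual
differences (r = 0.98 here, where the cohort is generated by the same model
family).

The `examples/` directory contains one short script per capability (cohort
simulation, response coding, model predictions, mixed-model contrasts,
long-term decay); each prints the numbers it computes and a line on what they
mean.  A thin CLI mirrors the pipeline: `fir simulate`, `fir code`,
`fir fit-model`, `fir analyze`, `fir run --config cfg.yaml --seed 7 --out out/`.

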