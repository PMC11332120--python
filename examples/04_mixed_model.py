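"""Binomial mixed-model contrasts of pre- vs post-test fusion reports.

Counts of fusion vs non-fusion responses to the auditory-only target are
modelled with fixed effects of time (pre/post) and perceiver class and a random
participant intercept (lme4 via Rscript).  Type-II analysis-of-deviance
chi-squares test the main effects and interaction; post-hoc pre/post odds
ratios are reported per class with CIs computed in log-odds space and
back-transformed.
"""

import fir
from fir import behavior_stats as bs

trials, _ = fir.generate_cohort(seed=42)
classes = bs.classify_perceivers(trials, "S1")
counts = bs.fusion_counts_prepost(trials, "S1_Aud", classes)
fit = bs.fit_fusion_glmm(counts)

print("type-II analysis of deviance:")
for name, eff in fit.effects.items():
    print(f"  {name:12s} chi2({eff.df}) = {eff.chi_square:8.2f}   p = {eff.p_value:.2g}")
print("\npost-hoc pre -> post odds ratios:")
for cls, c in fit.posthoc.items():
    print(f"  {cls:20s} OR = {c.odds_ratio:9.3g}   95% CI ({c.ci95[0]:.3g}, {c.ci95[1]:.3g})   p = {c.p_value:.2g}")
print(
    "\nOnly fusion perceivers increase their fusion reports after exposure;"
    "\nwith zero pre-test fusion counts the odds ratio is driven by the"
    "\nseparated pre-test cell and its CI is wide."
)
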