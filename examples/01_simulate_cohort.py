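"""Generate a synthetic McGurk-exposure cohort and inspect its structure.

Builds the default 28-participant cohort (Day-1 auditory pre-test, 14 exposure
days, Day-16 post-test, 6 monthly long-term tests), checks it against the study
schedule, and shows the bimodal split of McGurk susceptibility.
"""

import fir
from fir import behavior_stats as bs

trials, truth = fir.generate_cohort(seed=42)
report = fir.validate_schedule(trials, fir.main_schedule())
print(f"{len(trials)} trials, {truth.participant_id.nunique()} participants")
print(f"schedule deviations: {len(report)} (empty report = fully conformant)")

classes = bs.classify_perceivers(trials, "S1")
print("\nexposure fusion fraction per participant (S1, 70 trials each):")
for cls, sub in classes.groupby("perceiver_class"):
    fr = sub.exposure_fusion_fraction
    print(f"  {cls:20s} n={len(sub):2d}  mean={fr.mean():.2f}  range=({fr.min():.2f}, {fr.max():.2f})")
print(
    "\nHalf the cohort fuses the incongruent audiovisual syllable on nearly every"
    "\ntrial; the other half almost never does - the bimodal susceptibility the"
    "\nrecalibration analysis starts from."
)
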