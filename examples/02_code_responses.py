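"""Code free-text percept reports into the four response categories.

Coding is blind to everything but the response text and the eliciting stimulus:
the initial consonant of the normalized response is matched against the
stimulus's auditory, visual and expected-fusion tokens.  Auditory-only trials
are coded against their parent McGurk stimulus, so a report of "da" to the
auditory-only "ba" of a ba/ga pairing counts as a Fusion response.
"""

from fir import code_response, main_stimuli

reg = main_stimuli()
s1, s2_aud, s2 = reg["S1"], reg["S2_Aud"], reg["S2"]

print(f"McGurk stimulus S1: auditory '{s1.auditory_token}' + visual "
      f"'{s1.visual_token}' -> expected fusion '{s1.expected_fusion_token}'\n")
for raw in ["baba", "buh buh", "dada", "gaga", "tha tha", "ada", ""]:
    print(f"  {raw!r:12s} -> {code_response(raw, s1)}")

print("\nauditory-only 'ba' (from the S2 ba/ga pairing):")
for raw in ["ba", "da", "ga", "pa"]:
    print(f"  {raw!r:12s} -> {code_response(raw, s2_aud, parent=s2)}")
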