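"""Simulate a cued decision-bias cohort: decisions shift, confidence does not.

Observers view directionless 'adapting' motion and are told to default their
response to the direction of a static arrow cue whenever a test looks
ambiguous (compliance γ = 0.8).  No sensory change occurs, yet the decision
PSE shifts assimilatively; the confidence distribution stays put — the
dissociation that identifies a decisional aftereffect.
"""

from confdiag.io import RunConfig, run_pipeline

report = run_pipeline(
    RunConfig(design="exp2", mechanism="decision_bias", n_subjects=15, seed=2,
              compliance=0.8, congruence="congruent")
)
block = report["analyses"]["condition"]

print(f"ΔPSE  = {block['delta_pse']['mean']:+.2f} (SD {block['delta_pse']['sd']:.2f}), "
      f"BF10 = {block['diagnosis']['bf_decision']:.3g}")
print(f"ΔCONF = {block['delta_conf']['mean']:+.2f} (SD {block['delta_conf']['sd']:.2f}), "
      f"BF10 = {block['diagnosis']['bf_confidence']:.3g}")
print(f"difference BF10 = {block['diagnosis']['bf_difference']:.3g}")
print(f"diagnosis: {block['diagnosis']['label']}")
print()
print("ΔPSE is negative (assimilative: defaults follow the cue) and far from")
print("zero, while ΔCONF hugs zero with a Bayes factor favoring the null —")
print("decisions changed although nothing about perception did.")
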