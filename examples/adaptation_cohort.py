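"""Simulate a motion-adaptation cohort and diagnose the aftereffect mechanism.

Fifteen observers adapt to leftward or rightward coherent motion (a lateral
sensory shift of ±10 coherence % applied to both latent functions), complete
the 11-level × 10-repeat × 2-condition session, and the pipeline fits both
psychometric functions per condition and classifies the mechanism.
"""

from confdiag.io import RunConfig, run_pipeline

report = run_pipeline(
    RunConfig(design="exp1", mechanism="sensory_shift", n_subjects=15, seed=1, shift=10.0)
)
block = report["analyses"]["condition"]

print(f"mean left/right decision PSE : {block['condition_means']['l_pse']:+.2f} / "
      f"{block['condition_means']['r_pse']:+.2f}")
print(f"mean left/right conf. peak   : {block['condition_means']['l_conf']:+.2f} / "
      f"{block['condition_means']['r_conf']:+.2f}")
print(f"ΔPSE  = {block['delta_pse']['mean']:.2f} (SD {block['delta_pse']['sd']:.2f}), "
      f"BF10 = {block['diagnosis']['bf_decision']:.3g}")
print(f"ΔCONF = {block['delta_conf']['mean']:.2f} (SD {block['delta_conf']['sd']:.2f}), "
      f"BF10 = {block['diagnosis']['bf_confidence']:.3g}")
print(f"difference BF10 = {block['diagnosis']['bf_difference']:.3g}")
print(f"diagnosis: {block['diagnosis']['label']}")
print()
print("Both PSE estimates moved by about twice the adapting shift and by the")
print("same amount as each other, so the aftereffect is classified as a")
print("change in sensory evidence, not in decision strategy.")
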