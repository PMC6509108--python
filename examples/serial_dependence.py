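"""Serial dependence: a double dissociation across trial lags.

Each simulated observer carries two history mechanisms at once: the previous
test acts as a rapid adaptor (contrastive sensory shift of 3 coherence %,
moving decisions AND confidence), and the test two trials back tempts the
observer to repeat its direction on ambiguous trials (decision bias,
γ = 0.3, decisions only).  Splitting the same data by 1-back and by 2-back
stimulus direction recovers each mechanism's signature.
"""

from confdiag.io import RunConfig, run_pipeline

report = run_pipeline(
    RunConfig(design="exp3", mechanism="serial", n_subjects=22, seed=2,
              delta_1back=3.0, gamma_2back=0.3)
)
for lag in ("1back", "2back"):
    block = report["analyses"][lag]
    diag = block["diagnosis"]
    print(f"{lag}: ΔPSE = {block['delta_pse']['mean']:+.2f}, "
          f"ΔCONF = {block['delta_conf']['mean']:+.2f}  "
          f"[BF dec {diag['bf_decision']:.3g}, conf {diag['bf_confidence']:.3g}, "
          f"diff {diag['bf_difference']:.3g}] -> {diag['label']}")
print()
print("The 1-back split shifts both measures together (perceptual, like")
print("adaptation); the 2-back split shifts only decisions, in the opposite,")
print("assimilative direction (decisional, like the explicit cue).")
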