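"""Per-trial activity covariates predicting one-shot performance.

A synthetic per-trial activity value (standing in for a planning-period
signal from a region of interest) is generated with a known coupling to
subsequent NPA block-2 performance, then entered into the same
mixed-model machinery in place of the prior-knowledge predictor.
"""

from eventarena import (AgentParams, activity_models, assemble_model_table,
                        build_knowledge, simulate_cohort,
                        simulate_roi_activity)
from eventarena import decompose_block1_cohort

cohort = simulate_cohort(16, 36, AgentParams(seed=31), seed=31)
knowledge = build_knowledge(cohort)
block1 = decompose_block1_cohort(cohort)
npa2 = cohort[(cohort["phase"] == "NPA") & (cohort["block"] == 2)]
table = assemble_model_table(knowledge, block1, npa2)

activity = simulate_roi_activity(cohort, activity_beta=0.8, noise_sd=0.6,
                                 seed=31, roi_label="hippocampus_body")
results = activity_models(table, activity, omnibus=True)
res = results["hippocampus_body"]
row = res.term("value")
print(res.report())
print(f"\nactivity effect: b = {row['estimate']:.3f}, p = {row['p']:.2g}")
print("A negative coefficient means trials with higher planning-period "
      "activity end in lower (better) navigation PE.  No correction "
      "for multiple comparisons is applied across ROI models.")
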