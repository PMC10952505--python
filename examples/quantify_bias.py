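"""Quantify beta-arrestin bias with transduction ratios.

Simulates the default six-agonist, four-pathway scenario (one agonist,
carfentanil, is built 30-fold arrestin-biased), runs the full pipeline -
operational-model fits with a shared system maximum per pathway, then the
DeltaLog / DeltaDeltaLog(tau/K_A) ledger with ANOVA-gated Dunnett
statistics - and prints the primary pathway comparison.
"""

from gpcrbias import PipelineConfig, fentanyl_panel_scenario, run_pipeline

datasets, truths = fentanyl_panel_scenario(seed=11)
bundle = run_pipeline(PipelineConfig(out=None, seed=11), datasets=datasets)

bias = bundle.bias
primary = bias[(bias.pathway_1 == "arrestin") & (bias.pathway_2 == "gprotein")]
cols = ["agonist_id", "delta_log_p1", "delta_log_p2", "delta_delta_log",
        "se_delta_delta_log", "p_adjusted"]
print(primary[cols].to_string(index=False, float_format="%.3f"))

print(
    f"\nagonists flagged arrestin-biased: {bundle.biased_agonists}\n"
    "DeltaDeltaLog(tau/K_A) > 0 means coupling shifted toward the arrestin "
    "pathway relative to the reference agonist DAMGO; the generator's truth "
    "is log10(30) = 1.48 for carfentanil and 0 for everything else.  "
    "p_adjusted is Dunnett-corrected vs DAMGO (blank when the ANOVA gate "
    "is not passed)."
)
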