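"""Fit logistic concentration-response curves and compare agonist potency.

Simulates a G-protein activation assay for the reference peptide DAMGO and
for carfentanil with operational-model ground truth, applies the outlier
rule, fits four-parameter logistic curves per replicate, and prints the
potency summary plus the fold-potency ratio.
"""

import numpy as np

from gpcrbias import (
    GroundTruth,
    exclude_outliers,
    fit_logistic,
    fold_potency,
    potency_table,
    simulate_assay,
)

# tau = 5 partial-reserve system; K_A chosen so the curve EC50s sit near
# published mean values (-6.48 for DAMGO, -8.11 for carfentanil)
truths = [
    GroundTruth("DAMGO", "gprotein", tau=5.0, k_a=6 * 10.0 ** -6.48,
                noise_cv=0.05, seed=1),
    GroundTruth("carfentanil", "gprotein", tau=5.0, k_a=6 * 10.0 ** -8.11,
                noise_cv=0.05, seed=2),
]

fits = []
for truth in truths:
    dataset = exclude_outliers(simulate_assay(truth))
    fits.append(fit_logistic(dataset, model_kind="four_param"))

print(potency_table(fits).to_string(index=False))

fp = fold_potency(fits[1], fits[0])
print(
    f"\ncarfentanil is {fp.fold:.0f}-fold more potent than DAMGO "
    "(antilog of the mean log EC50 difference; ~42-fold is reported for the real assay "
    "for G-protein activation)"
)
print(
    "log EC50 is the log10 molar concentration producing half-maximal "
    "response; E_max the fitted top of each curve."
)
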