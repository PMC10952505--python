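# gpcrbias

Quantitative pharmacology of agonist signalling bias at G-protein-coupled
receptors, built around the assays used to characterise fentanyl-class
agonists at the μ opioid receptor: BRET G-protein activation, β-arrestin-2
recruitment, ELISA cell-surface receptor loss, and GIRK currents in
neurones. The package is aimed at pharmacologists who have long-format
concentration–response (or current-trace) data and want the full analysis
chain — empirical curve fitting through operational-model bias factors,
receptor-reserve estimation and desensitisation quantification — as
reproducible, tested code rather than spreadsheet steps.

## What it computes

**Empirical potency.** Four-parameter logistic fits (or the
three-parameter variant with Hill slope fixed at 1) on log₁₀
concentration, per biological replicate with mean ± SEM summaries, a
pooled curve, a leave-one-out >3 SD outlier rule applied per
concentration, and fold-potency ratios `10^(logEC50_ref − logEC50_drug)`.

**Operational-model bias.** The Black–Leff operational model

    E = basal + (E_max − basal) · τⁿ[A]ⁿ / (τⁿ[A]ⁿ + ([A] + K_A)ⁿ)

is fitted per agonist with the system maximum E_max (and transducer slope
n) shared within an assay. The identifiable composite Log(τ/K_A) — the
transduction ratio — is reported with a standard error even when τ and
K_A are separately ill-determined. Bias factors are differences of
differences: ΔLog(τ/K_A) against a reference agonist within a pathway,
then ΔΔLog(τ/K_A) between pathways, with ANOVA-gated Dunnett statistics
versus the reference (positive values = arrestin-side bias).

**Furchgott receptor-inactivation analysis.** Paired control /
β-funaltrexamine-pretreated curves are inverted at 20 equieffective
response levels; the pairs are fitted to

    [A] = [A′] · q · K_A / (K_A + (1 − q)[A′])

giving the functional affinity K_A and the surviving receptor fraction q
with 95% CIs, plus occupancy curves p = [A]/([A]+K_A), the receptor
reserve index K_A/EC50 and the occupancy needed for half-maximal
response.

**GIRK desensitisation.** Traces are baseline-subtracted, normalised to
the cell's noradrenaline reference current, and the post-peak segment is
fitted to a one-phase decay; percent desensitisation at 10 min post-peak
is read off the fitted curve and compared across drugs.

**Synthetic data.** Every stage is testable without raw data: a generator
draws assays from operational-model ground truth (Gaussian replicate
noise, depletion as τ → qτ) and GIRK traces with known decay parameters,
bit-reproducible given a seed.

## Worked example

`examples/furchgott_reserve.py` simulates a paired control/depleted
G-protein experiment with K_A = 5596 nM, q = 0.06 (published DAMGO values) and runs the inactivation workflow:

```text
K_A          =   5596.0 nM (95% CI 5596.0-5596.0; truth 5596)
q_functional =    0.060 (95% CI 0.060-0.060; truth 0.060)
K_A/EC50     =     35.2   (published value 35.2)
occupancy at half-maximal response = 2.76%
```

The recovered affinity and surviving fraction match the generating truth
(noiseless data), and K_A/EC50 = 35.2 ≫ 1 indicates substantial receptor
reserve: only ~2.8% of receptors need be occupied for half the maximal
response. The other examples cover curve fitting/fold potency
(`fit_dose_response.py`), the bias ledger on the six-agonist scenario
(`quantify_bias.py`, which flags exactly the one agonist simulated as
arrestin-biased), and desensitisation (`girk_desensitisation.py`).

A thin CLI mirrors the library (`gpcrbias simulate | fit-curves | bias |
furchgott | desens | run`); `gpcrbias run --config cfg.yaml` chains every
stage and writes report tables plus a seeded run log.

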