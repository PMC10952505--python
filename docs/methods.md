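# Methods

This note documents the models, the estimation choices, the synthetic
data generator, and the known limits of each analysis stage.

## Empirical concentration–response fitting

Curves are fitted on x = log₁₀[A] (M) with untransformed responses:

    E(x) = bottom + (top − bottom) / (1 + 10^((logEC50 − x)·h))

Two model kinds are exposed: `four_param` (h free, bounded to
[0.05, 10]) and `three_param_hill1` (h ≡ 1, for noisier assays such as
surface-receptor-loss ELISAs). The curve bottom is fixed at 0 by default,
matching background-subtracted assay data; pass
`bottom_fixed_at_zero=False` for data with a genuine floor. Model choice
is always explicit — there is no silent fallback from four to three
parameters, because automatic switching hides analyst intent.

Two summaries are produced. The *primary* path fits each biological
replicate separately and reports the mean ± SEM of the per-replicate
parameters, which is how replicate-resolved potency tables are usually
built; a *pooled* fit over all points is also returned and is the curve
used by stages that need a single invertible function (equieffective
pairing, reserve summaries). Optimisation is deterministic multi-start
least squares: a data-driven logEC50 start (concentration nearest
half-maximal response) plus a coarse grid, refined by bounded
Levenberg–Marquardt/TRF; no randomness, so fits reproduce without a seed.

**Outlier rule.** At each concentration, a replicate value is flagged when
it differs from the mean of the *other* values at that concentration by
more than 3× their sample SD. Per-concentration grouping is the only one
at which "the other values" is well defined for plate data. The rule
needs ≥3 values; with fewer it is skipped and logged. Flagged points are
retained in the record but ignored by fits.

## Operational model and bias factors

The operational model treats response as a saturable transduction of
occupancy: τ bundles receptor density, intrinsic efficacy and coupling
efficiency; K_A is the functional affinity; n the transducer slope. For
a full agonist, τ and K_A ride a ridge (the observable curve has only a
top and an EC50), but the composite Log(τ/K_A) stays well determined and
is the quantity used for bias.

**Identifiability constraint.** With n = 1 and the system maximum free,
the model's ridge is one-dimensional *and Log(τ/K_A) varies along it* —
an E_max→∞, τ→0 family reproduces any hyperbolic curve. The system
maximum is therefore treated as a property of the transduction system,
not the ligand: `fit_operational_assay` shares E_max (and n) across all
agonists in an assay, pinned by the highest-efficacy agonist, and the
single-dataset `fit_operational` takes `e_max_system` explicitly (its
fallback — the observed plateau — is adequate only for partial
agonists). The transducer slope defaults to fixed n = 1; pass
`n_slope=None` to share a free slope within an assay.

Standard errors for Log(τ/K_A) come from the asymptotic covariance via
the delta method, using a pseudo-inverse of J'J so the ridge direction
(numerically singular) does not contaminate the well-determined ratio
direction; a replicate bootstrap (200 resamples, seeded) is available as
a cross-check. Per-replicate Log(τ/K_A) values — each replicate refit
with the system parameters held — feed the group statistics.

**Bias ledger.** ΔLog(τ/K_A) subtracts the reference agonist within a
pathway (SEs in quadrature); ΔΔLog(τ/K_A) subtracts pathway 2 from
pathway 1. Pathway pairs are ordered arrestin-side first so that
positive ΔΔLog means arrestin bias. The reference agonist's rows are
exactly zero by construction, and group comparisons use the
per-replicate ΔΔLog values (replicate i of each agonist paired with
replicate i of the reference). A pipeline report flags an agonist as
biased when its Dunnett-adjusted p < α *in the primary (first) pathway
pair* with positive ΔΔLog — one pre-declared comparison rather than a
union over all pairs, to keep the family-wise error interpretable.

## Receptor-inactivation (Furchgott) analysis

Equieffective concentrations are read off the *fitted* control and
depleted curves, not raw points — replicate noise would make raw
inversion ill-defined. Twenty levels are spaced evenly in response units
between 5% and 95% of the depleted curve's span, the widest band over
which both curves are reliably invertible; the whole ladder must lie
inside the control curve's open range, otherwise an error reports the
usable range. Each level is inverted analytically through both logistic
curves.

The pair relation is fitted by least squares in log₁₀ concentration
(pairs span orders of magnitude; linear residuals would be dominated by
the largest pair), with a deterministic grid start and bounds
q ∈ (0, 1]. A fitted q > 0.99 raises an error — without meaningful
depletion K_A is unidentifiable. 95% CIs are asymptotic (t-quantile on
the fit covariance); when an interval escapes the parameter bounds, a
profile-likelihood interval (F-threshold on the SSR profile) is
substituted.

Reserve summaries: K_A/EC50 uses the control arm of the *same* paired
experiment (not a potency table from another dataset), and the occupancy
at half-maximal response is the occupancy law evaluated at the control
curve's analytically inverted half-max point. For any logistic curve the
half-max point is the EC50, so this reduces to 100/(1 + K_A/EC50)
percent; empirical occupancy-response curves whose shape is not
logistic would give different values, which is one reason published
occupancy-at-half-max figures can sit slightly off the closed form.

## GIRK-current desensitisation

Traces are baseline-subtracted with the 30 s pre-application mean and
normalised to the same cell's noradrenaline reference peak, removing
cell-to-cell variation in channel expression. The peak is the maximum of
a 5-sample moving average after the application event — a single noisy
sample cannot define it — restricted to candidates followed by at least
600 s of recording, which the 10-min measure needs. The post-peak
segment is fitted to a one-phase decay I(t) = plateau + (y₀ −
plateau)e^(−kt); the amplitude y₀ is a free parameter (pinning it to the
detected sample would push its noise into plateau and k), while the
detected peak only anchors t = 0. Percent desensitisation at 10 min is
100·(y₀ − I(600 s))/y₀ on the fitted curve. A rising post-peak segment
clamps k to 0 and reports 0% with a warning. Group comparisons delegate
to the same ANOVA-gated Dunnett machinery as the bias ledger.

## Statistics

One-way ANOVA gates Dunnett's test: adjusted comparisons against the
reference group run only when the ANOVA reaches P < 0.05; otherwise
every comparison reports "not tested". Dunnett p-values come from the
exact multivariate-t distribution (scipy), with a fixed generator for
the randomised-QMC integration so results are bit-reproducible.
Degenerate input (all values identical) is reported as not tested rather
than an error. Under a null simulation the gate makes the per-comparison
type-I error conservative (≈1–2% at α = 0.05).

## Synthetic data generator

Assay datasets are drawn from the operational model plus additive
Gaussian noise with SD = noise_cv × E_max_system. Additive (not
multiplicative) noise reflects resonance-energy-transfer ratio data,
whose error bars are roughly constant across the response range.
Defaults mirror the emulated experimental design: 5 biological replicates, 5% noise,
and a 9-point half-log concentration ladder centred on the expected EC50
(K_A/(1+τ) for n = 1), spanning 4 decades. Depletion arms model
irreversible antagonism purely as τ → qτ — receptor loss without any
change in agonist affinity, which is exactly the assumption the
inactivation analysis tests. For paired-arm simulations the ladder
should span both arms' EC50s (±2 decades), as the examples do.

The default scenario places six agonists across four pathways with one
agonist's arrestin-side τ/K_A raised 30-fold (ΔΔLog = 1.48) relative to
the reference; everything else is unbiased. GIRK traces rise
exponentially (τ_rise 5 s) after application at 30 s, decay to a plateau
at rate k, and carry Gaussian sample noise; the noradrenaline reference
peak is recorded alongside.

What the generator does *not* emulate: plate-position or day effects,
heteroscedastic or correlated residuals, BRET donor/acceptor channel
arithmetic, cumulative-application history in electrophysiology, or
rundown. Passing tests therefore demonstrate correctness of the
estimators under the stated noise model, not robustness to every
artefact of real plates and recordings.

## Problem sizes and numerical choices

Simulation-based checks use 100 seeded datasets per claim (CI coverage,
round-trip recovery, decay recovery) and 1000 datasets for the null
calibration of the Dunnett procedure; these sizes give Monte-Carlo
standard errors comfortably below the asserted margins. Optimiser
tolerances are set to 1e-14/1e-15 so noiseless self-consistency checks
recover parameters to ≥6 significant figures. All randomness flows
through `numpy.random.default_rng` seeds carried in the truth records;
identical seeds give bit-identical datasets and reports.

## Known limitations

- The K_A from the inactivation analysis inherits the sampling error of
  the depleted-arm EC50 and of the fitted curve tops. At 5% replicate
  noise with 5 replicates this propagates to a ~15% (best case, high-τ
  rows) to ~50% (low-τ rows) coefficient of variation on K_A, even
  though the estimator is unbiased and the optimiser exact; q is far
  better determined (±0.01–0.02). Tight K_A claims need more replicates
  or denser ladders than the emulated design provides.
- Basal is fixed at 0 throughout the operational stage (appropriate for
  background-subtracted readouts); a config flag exposes it, but fitting
  basal and E_max together weakens identifiability further.
- The bias ledger implements the transduction-ratio method only; other
  bias metrics (intrinsic relative activity, σ_lig) are out of scope.
- Desensitisation uses a single-exponential decay; multi-phasic decays
  are fitted by their dominant component.
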