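"""Synthetic assay generator with recorded ground truth.

Concentration-response datasets are drawn from the operational model
(known tau, K_A, basal, system maximum, transducer slope) with additive
Gaussian replicate noise whose SD is a fixed fraction of the system
maximum - resonance-transfer ratio noise is roughly constant across the
response range, not proportional to the signal.  Irreversible-antagonist
arms model receptor depletion purely as tau -> q * tau (the
receptor-density component of tau), leaving K_A untouched.  GIRK traces
rise to a peak after drug application and decay exponentially toward a
plateau, with the noradrenaline reference peak recorded alongside.

Defaults mirror the emulated experimental design: five biological replicates and a
nine-point half-log concentration grid centred on the expected EC50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ConcResponseDataset, CurrentTrace
from .operational import evaluate_operational

DEFAULT_NOISE_CV = 0.05
DEFAULT_REPLICATES = 5
DEFAULT_GRID_POINTS = 9       # half-log steps -> spans 4 decades


@dataclass
class GroundTruth:
    """Generating parameters for one agonist/assay arm."""

    agonist_id: str
    assay_id: str
    tau: float
    k_a: float                        # molar
    basal: float = 0.0
    e_max_system: float = 100.0
    n_slope: float = 1.0
    q: float = 1.0                    # receptor fraction left in depleted arm
    noise_cv: float = DEFAULT_NOISE_CV
    n_replicates: int = DEFAULT_REPLICATES
    conc_grid: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.q <= 1):
            raise ValueError("q must lie in (0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.conc_grid is None:
            self.conc_grid = default_grid(self.tau, self.k_a, self.n_slope)
        self.conc_grid = np.asarray(self.conc_grid, dtype=float)

    @property
    def log_tau_over_ka(self) -> float:
        return float(np.log10(self.tau) - np.log10(self.k_a))


def default_grid(
    tau: float, k_a: float, n_slope: float = 1.0, n_points: int = DEFAULT_GRID_POINTS
) -> np.ndarray:
    """Half-log concentration ladder centred on the expected EC50.

    For a transducer slope of 1 the operational EC50 is K_A / (1 + tau).
    """
    ec50 = k_a / (1.0 + tau ** n_slope) ** (1.0 / n_slope)
    centre = np.log10(ec50)
    offsets = 0.5 * (np.arange(n_points) - (n_points - 1) / 2)
    return 10.0 ** (centre + offsets)


def _draw(
    truth: GroundTruth, tau: float, arm: str, rng: np.random.Generator
) -> ConcResponseDataset:
    rows = []
    for rep in range(1, truth.n_replicates + 1):
        mean = evaluate_operational(
            truth.basal, truth.e_max_system, tau, truth.n_slope,
            truth.k_a, truth.conc_grid,
        )
        noise = rng.normal(
            0.0, truth.noise_cv * truth.e_max_system, size=mean.shape
        )
        for c, r in zip(truth.conc_grid, mean + noise):
            rows.append({"replicate": rep, "conc_M": c, "response": r})
    return ConcResponseDataset(
        assay_id=truth.assay_id,
        agonist_id=truth.agonist_id,
        treatment_arm=arm,
        observations=pd.DataFrame(rows),
    )


def simulate_assay(truth: GroundTruth) -> ConcResponseDataset:
    """One control-arm dataset drawn from the operational model; bitwise
    deterministic given ``truth.seed``."""
    rng = np.random.default_rng(truth.seed)
    return _draw(truth, truth.tau, "control", rng)


def simulate_depletion_arm(truth: GroundTruth):
    """Paired (control, depleted) datasets sharing everything but tau.

    The depleted arm uses tau -> q * tau: irreversible antagonism removes
    receptors without altering agonist affinity.
    """
    rng = np.random.default_rng(truth.seed)
    control = _draw(truth, truth.tau, "control", rng)
    depleted = _draw(truth, truth.q * truth.tau, "depleted", rng)
    return control, depleted


@dataclass
class GirkTruth:
    """Generating parameters for one synthetic GIRK current trace."""

    cell_id: str = "cell-1"
    drug_id: str = "drug"
    peak_fraction_of_na: float = 1.0
    plateau_fraction: float = 0.4
    decay_k: float = 0.01             # 1/s
    sampling_rate: float = 1.0        # Hz
    noise_sd: float = 0.0             # fraction of the NA reference
    na_peak_pA: float = 100.0
    t_application: float = 30.0       # s
    rise_tau: float = 5.0             # s, exponential rise to peak
    duration: float = 700.0           # s; >= 600 s post peak retained
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plateau_fraction > self.peak_fraction_of_na:
            raise ValueError("plateau_fraction must not exceed the peak")
        if self.decay_k < 0:
            raise ValueError("decay_k must be >= 0")


def simulate_girk_trace(truth: GirkTruth) -> CurrentTrace:
    """Baseline, exponential rise to peak, one-phase decay to plateau,
    plus Gaussian sample noise; all amplitudes in pA via the NA peak."""
    rng = np.random.default_rng(truth.seed)
    dt = 1.0 / truth.sampling_rate
    total = truth.t_application + 5.0 * truth.rise_tau + truth.duration
    times = np.arange(0.0, total + dt / 2, dt)
    # rise completes ~5 time constants after application
    t_peak = truth.t_application + 5.0 * truth.rise_tau
    frac = np.zeros_like(times)
    rising = (times >= truth.t_application) & (times < t_peak)
    frac[rising] = truth.peak_fraction_of_na * (
        1.0 - np.exp(-(times[rising] - truth.t_application) / truth.rise_tau)
    )
    decaying = times >= t_peak
    frac[decaying] = truth.plateau_fraction + (
        truth.peak_fraction_of_na - truth.plateau_fraction
    ) * np.exp(-truth.decay_k * (times[decaying] - t_peak))
    if truth.noise_sd > 0:
        frac = frac + rng.normal(0.0, truth.noise_sd, size=frac.shape)
    return CurrentTrace(
        cell_id=truth.cell_id,
        drug_id=truth.drug_id,
        times=times,
        currents=frac * truth.na_peak_pA,
        na_peak_current=truth.na_peak_pA,
        events=[(truth.drug_id, truth.t_application)],
    )


# -- the default fentanyl-panel scenario ----------------------------------

REFERENCE_AGONIST = "DAMGO"

# Log(tau/K_A) offsets from the reference per agonist; the arrestin-biased
# agonist gets an extra +1.48 (30-fold tau/K_A) on the arrestin-side
# pathways only.
_SCENARIO_OFFSETS = {
    "DAMGO": 0.0,
    "morphine": -0.2,
    "fentanyl": 0.3,
    "carfentanil": 1.6,
    "alfentanil": 0.1,
    "sufentanil": 1.3,
}
_ARRESTIN_BIAS = {"carfentanil": np.log10(30.0)}

# assay -> (pathway side, reference Log(tau/K_A), agonists measured there)
_SCENARIO_ASSAYS = {
    "gprotein": ("g", 6.5, list(_SCENARIO_OFFSETS)),
    "girk": ("g", 6.8, ["DAMGO", "morphine", "fentanyl", "carfentanil"]),
    "arrestin": ("arr", 5.7, list(_SCENARIO_OFFSETS)),
    "surface_loss": ("arr", 6.1, ["DAMGO", "fentanyl", "carfentanil"]),
}


def fentanyl_panel_truths(
    seed: int = 0, noise_cv: float = DEFAULT_NOISE_CV
) -> list[GroundTruth]:
    """Ground truths for the default scenario: six agonists across four
    pathways, all unbiased except one arrestin-biased agonist whose
    arrestin-side tau/K_A sits 30-fold above its G-protein-side value
    (relative to the reference)."""
    rng = np.random.default_rng(seed)
    truths = []
    for assay, (side, ref_log_r, agonists) in _SCENARIO_ASSAYS.items():
        for agonist in agonists:
            log_r = ref_log_r + _SCENARIO_OFFSETS[agonist]
            if side == "arr":
                log_r += _ARRESTIN_BIAS.get(agonist, 0.0)
            tau = 5.0
            k_a = 10.0 ** (np.log10(tau) - log_r)
            truths.append(
                GroundTruth(
                    agonist_id=agonist,
                    assay_id=assay,
                    tau=tau,
                    k_a=k_a,
                    noise_cv=noise_cv,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
    return truths


def fentanyl_panel_scenario(seed: int = 0, noise_cv: float = DEFAULT_NOISE_CV):
    """Simulate the default scenario; returns (datasets, truths)."""
    truths = fentanyl_panel_truths(seed=seed, noise_cv=noise_cv)
    return [simulate_assay(t) for t in truths], truths


def truth_table(truths: list[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "assay_id": t.assay_id,
                "agonist_id": t.agonist_id,
                "tau": t.tau,
                "k_a_M": t.k_a,
                "n_slope": t.n_slope,
                "e_max_system": t.e_max_system,
                "q": t.q,
                "noise_cv": t.noise_cv,
                "n_replicates": t.n_replicates,
                "log_tau_over_ka": t.log_tau_over_ka,
                "seed": t.seed,
            }
            for t in truths
        ]
    )
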