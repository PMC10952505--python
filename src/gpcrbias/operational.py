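"""Black-Leff operational-model fitting and transduction-ratio bias factors.

The operational model expresses response as

    E = basal + (E_max - basal) * tau^n [A]^n / (tau^n [A]^n + ([A] + K_A)^n)

with operational efficacy tau (receptor density x intrinsic efficacy x
coupling), functional affinity K_A and transducer slope n.  tau and K_A are
individually ill-determined for full agonists, but their ratio is not: the
transduction ratio Log(tau/K_A) is the identifiable composite used for bias
quantification.  Bias factors are differences of differences:
DeltaLog(tau/K_A) against a reference agonist within a pathway, then
DeltaDeltaLog(tau/K_A) between two pathways for each agonist.

Identifiability note: with n = 1 and the system maximum free, the model has
a one-dimensional ridge along which Log(tau/K_A) itself varies (only the
curve top and EC50 are observable).  The system maximum is therefore
treated as a property of the transduction system - fixed, or shared across
agonists within an assay and pinned by the highest-efficacy agonist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datasets import ConcResponseDataset

logger = logging.getLogger(__name__)


class OperationalFitError(RuntimeError):
    pass


class NoSignalError(OperationalFitError):
    """Dataset shows no concentration dependence."""


@dataclass
class OperationalFit:
    agonist_id: str
    assay_id: str
    basal: float
    e_max_system: float
    tau: float
    k_a: float
    n_slope: float
    log_tau_over_ka: float
    se_log_tau_over_ka: float
    ssr: float = np.nan
    per_replicate_log_tau_over_ka: list | None = None


def evaluate_operational(basal, e_max, tau, n_slope, k_a, conc):
    """Operational-model response at concentration ``conc`` (molar)."""
    a = np.asarray(conc, dtype=float)
    num = (tau * a) ** n_slope
    den = num + (a + k_a) ** n_slope
    return basal + (e_max - basal) * num / den


def _residual_fn(log_a, resp, basal, e_max, n_slope):
    def fn(theta):
        log_tau, log_ka = theta
        pred = evaluate_operational(
            basal, e_max, 10.0 ** log_tau, n_slope, 10.0 ** log_ka, 10.0 ** log_a
        )
        return pred - resp
    return fn


def _grid_start(fn, log_a):
    """Best (log_tau, log_ka) on a coarse deterministic grid."""
    taus = np.arange(-1.5, 3.1, 0.5)
    kas = np.arange(log_a.min() - 3.0, log_a.max() + 3.1, 0.5)
    best, best_ssr = None, np.inf
    for lt in taus:
        for lk in kas:
            ssr = float(np.sum(fn((lt, lk)) ** 2))
            if ssr < best_ssr:
                best, best_ssr = (lt, lk), ssr
    return np.array(best), best_ssr


def fit_operational(
    dataset: ConcResponseDataset,
    e_max_system: float | None = None,
    basal: float = 0.0,
    n_slope: float = 1.0,
    bootstrap_se: bool = False,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> OperationalFit:
    """Least-squares operational-model fit of one agonist/assay dataset.

    ``e_max_system`` is the system maximal response; if None it is
    estimated as the dataset's top plateau inflated by the fitted tau -
    acceptable only for partial agonists, so passing the assay-wide value
    (from :func:`fit_operational_assay`) is preferred.  ``basal`` defaults
    to 0 for background-subtracted data.  The identifiable composite
    Log(tau/K_A) is always reported with a standard error (asymptotic by
    default; replicate bootstrap with ``bootstrap_se=True``).
    """
    obs = dataset.included
    if len(obs) < 4:
        raise OperationalFitError("too few observations")
    log_a = np.log10(obs["conc_M"].to_numpy())
    resp = obs["response"].to_numpy()

    per_conc = obs.groupby("conc_M")["response"].mean()
    span = float(per_conc.max() - per_conc.min())
    scale = max(abs(per_conc).max(), 1.0)
    if span <= 1e-10 * scale:
        raise NoSignalError(
            f"{dataset.assay_id}/{dataset.agonist_id}: no signal "
            "(responses do not depend on concentration)"
        )

    if e_max_system is None:
        # treat observed top as ~ system max; adequate for partial agonists
        e_max_system = float(per_conc.max())
        logger.info(
            "%s/%s: e_max_system not supplied, using observed top %.4g",
            dataset.assay_id, dataset.agonist_id, e_max_system,
        )

    fn = _residual_fn(log_a, resp, basal, e_max_system, n_slope)
    x0, grid_ssr = _grid_start(fn, log_a)
    sol = least_squares(
        fn, x0, bounds=([-6, log_a.min() - 6], [8, log_a.max() + 6]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if not sol.success:
        raise OperationalFitError(
            f"operational fit did not converge; best grid point {tuple(x0)} "
            f"(SSR {grid_ssr:.4g})"
        )
    log_tau, log_ka = sol.x
    log_ratio = log_tau - log_ka

    # asymptotic SE of the identifiable composite via the delta method
    dof = max(len(resp) - 2, 1)
    sigma2 = float(np.sum(sol.fun ** 2)) / dof
    J = sol.jac
    # pseudo-inverse: the tau/K_A ridge can make J'J numerically singular,
    # but the Log(tau/K_A) direction stays well determined
    cov = sigma2 * np.linalg.pinv(J.T @ J)
    se = float(np.sqrt(max(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1], 0.0)))

    if bootstrap_se:
        rng = np.random.default_rng(seed)
        reps = np.sort(obs["replicate"].unique())
        draws = []
        for _ in range(n_bootstrap):
            take = rng.choice(reps, size=len(reps), replace=True)
            parts = [obs[obs["replicate"] == r] for r in take]
            bobs = pd.concat(parts)
            bfn = _residual_fn(
                np.log10(bobs["conc_M"].to_numpy()),
                bobs["response"].to_numpy(),
                basal, e_max_system, n_slope,
            )
            bsol = least_squares(
                bfn, sol.x,
                bounds=([-6, log_a.min() - 6], [8, log_a.max() + 6]),
            )
            if bsol.success:
                draws.append(bsol.x[0] - bsol.x[1])
        if len(draws) >= 10:
            se = float(np.std(draws, ddof=1))

    return OperationalFit(
        agonist_id=dataset.agonist_id,
        assay_id=dataset.assay_id,
        basal=basal,
        e_max_system=float(e_max_system),
        tau=float(10.0 ** log_tau),
        k_a=float(10.0 ** log_ka),
        n_slope=float(n_slope),
        log_tau_over_ka=float(log_ratio),
        se_log_tau_over_ka=se,
        ssr=float(np.sum(sol.fun ** 2)),
    )


def fit_operational_assay(
    datasets: list[ConcResponseDataset],
    basal: float = 0.0,
    n_slope: float | None = 1.0,
    per_replicate: bool = True,
) -> dict[str, OperationalFit]:
    """Joint operational fit of all agonists in one assay.

    The system maximum (and the transducer slope, unless fixed via
    ``n_slope``) is shared across agonists - they are properties of the
    transduction system, not of the ligand - while each agonist gets its
    own (tau, K_A).  With ``per_replicate=True`` each replicate is also
    refit individually (system parameters held at the joint estimates) to
    give per-replicate Log(tau/K_A) values for group statistics.
    """
    if not datasets:
        raise OperationalFitError("no datasets")
    assay = datasets[0].assay_id
    if any(d.assay_id != assay for d in datasets):
        raise OperationalFitError("fit_operational_assay needs a single assay")

    fit_n = n_slope is None
    tops, packs = [], []
    for d in datasets:
        obs = d.included
        log_a = np.log10(obs["conc_M"].to_numpy())
        packs.append((d, log_a, obs["response"].to_numpy()))
        tops.append(obs.groupby("conc_M")["response"].mean().max())
    top0 = float(max(tops))

    n_ag = len(datasets)

    def unpack(theta):
        e_max = theta[0]
        n = theta[1] if fit_n else n_slope
        pairs = theta[1 + fit_n:].reshape(n_ag, 2)
        return e_max, n, pairs

    def fn(theta):
        e_max, n, pairs = unpack(theta)
        out = []
        for (d, log_a, resp), (lt, lk) in zip(packs, pairs):
            pred = evaluate_operational(
                basal, e_max, 10.0 ** lt, n, 10.0 ** lk, 10.0 ** log_a
            )
            out.append(pred - resp)
        return np.concatenate(out)

    # starts: per-agonist grid under the plateau-derived system max
    x0 = [top0 * 1.05] + ([1.0] if fit_n else [])
    lo = [0.0] + ([0.2] if fit_n else [])
    hi = [np.inf] + ([5.0] if fit_n else [])
    for d, log_a, resp in packs:
        sub = _residual_fn(log_a, resp, basal, top0 * 1.05, 1.0)
        start, _ = _grid_start(sub, log_a)
        x0.extend(start)
        lo.extend([-6, log_a.min() - 6])
        hi.extend([8, log_a.max() + 6])
    sol = least_squares(
        fn, np.array(x0), bounds=(np.array(lo), np.array(hi)),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if not sol.success:
        raise OperationalFitError("joint operational fit did not converge")
    e_max, n, pairs = unpack(sol.x)

    dof = max(sum(len(p[2]) for p in packs) - len(sol.x), 1)
    sigma2 = float(np.sum(sol.fun ** 2)) / dof
    cov = sigma2 * np.linalg.pinv(sol.jac.T @ sol.jac)

    fits: dict[str, OperationalFit] = {}
    for i, ((d, log_a, resp), (lt, lk)) in enumerate(zip(packs, pairs)):
        j = 1 + fit_n + 2 * i
        se = float(np.sqrt(max(cov[j, j] + cov[j + 1, j + 1] - 2 * cov[j, j + 1], 0.0)))
        per_rep = None
        if per_replicate:
            per_rep = []
            obs = d.included
            for rep in sorted(obs["replicate"].unique()):
                grp = obs[obs["replicate"] == rep]
                rfn = _residual_fn(
                    np.log10(grp["conc_M"].to_numpy()),
                    grp["response"].to_numpy(),
                    basal, e_max, n,
                )
                rsol = least_squares(
                    rfn, np.array([lt, lk]),
                    bounds=([-6, log_a.min() - 6], [8, log_a.max() + 6]),
                )
                if rsol.success:
                    per_rep.append(float(rsol.x[0] - rsol.x[1]))
                else:
                    logger.warning(
                        "%s/%s replicate %d operational refit failed",
                        d.assay_id, d.agonist_id, rep,
                    )
        fits[d.agonist_id] = OperationalFit(
            agonist_id=d.agonist_id,
            assay_id=assay,
            basal=basal,
            e_max_system=float(e_max),
            tau=float(10.0 ** lt),
            k_a=float(10.0 ** lk),
            n_slope=float(n),
            log_tau_over_ka=float(lt - lk),
            se_log_tau_over_ka=se,
            per_replicate_log_tau_over_ka=per_rep,
        )
    return fits


# -- bias ledger ----------------------------------------------------------


def delta_log(fit_a: OperationalFit, fit_ref: OperationalFit):
    """DeltaLog(tau/K_A) of an agonist against the reference, same assay;
    standard errors propagate in quadrature."""
    if fit_a.assay_id != fit_ref.assay_id:
        raise ValueError(
            f"assay mismatch: {fit_a.assay_id} vs {fit_ref.assay_id}"
        )
    value = fit_a.log_tau_over_ka - fit_ref.log_tau_over_ka
    se = float(np.hypot(fit_a.se_log_tau_over_ka, fit_ref.se_log_tau_over_ka))
    return value, se


def delta_delta_log(dl_p1, dl_p2):
    """DeltaDeltaLog(tau/K_A) between two pathways: (value_p1 - value_p2,
    quadrature SE).  Positive values mean bias toward pathway 1."""
    (v1, s1), (v2, s2) = dl_p1, dl_p2
    return v1 - v2, float(np.hypot(s1, s2))


def bias_table(
    fits_by_assay: dict[str, dict[str, OperationalFit]],
    reference_id: str,
    pathway_pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Assemble the transduction-ratio bias ledger.

    For each pathway pair (p1, p2) and each agonist present in both,
    reports DeltaLog per pathway and DeltaDeltaLog = DeltaLog_p1 -
    DeltaLog_p2 with quadrature SEs.  The reference agonist's rows are
    exactly zero by construction.  Per-replicate DeltaDeltaLog values are
    included (as a list column) when per-replicate transduction ratios are
    available, for reference-comparison statistics.
    """
    rows = []
    for p1, p2 in pathway_pairs:
        for assay in (p1, p2):
            if assay not in fits_by_assay:
                raise KeyError(f"no operational fits for assay {assay!r}")
            if reference_id not in fits_by_assay[assay]:
                raise KeyError(f"reference {reference_id!r} missing in assay {assay!r}")
        ref1, ref2 = fits_by_assay[p1][reference_id], fits_by_assay[p2][reference_id]
        shared = [
            a for a in fits_by_assay[p1]
            if a in fits_by_assay[p2]
        ]
        for agonist in shared:
            dl1 = delta_log(fits_by_assay[p1][agonist], ref1)
            dl2 = delta_log(fits_by_assay[p2][agonist], ref2)
            ddl, se = delta_delta_log(dl1, dl2)
            per_rep = None
            f1, f2 = fits_by_assay[p1][agonist], fits_by_assay[p2][agonist]
            if all(
                f.per_replicate_log_tau_over_ka
                for f in (f1, f2, ref1, ref2)
            ):
                n = min(
                    len(f.per_replicate_log_tau_over_ka)
                    for f in (f1, f2, ref1, ref2)
                )
                per_rep = [
                    (f1.per_replicate_log_tau_over_ka[i]
                     - ref1.per_replicate_log_tau_over_ka[i])
                    - (f2.per_replicate_log_tau_over_ka[i]
                       - ref2.per_replicate_log_tau_over_ka[i])
                    for i in range(n)
                ]
            rows.append(
                {
                    "agonist_id": agonist,
                    "pathway_1": p1,
                    "pathway_2": p2,
                    "log_tau_ka_p1": f1.log_tau_over_ka,
                    "log_tau_ka_p2": f2.log_tau_over_ka,
                    "delta_log_p1": dl1[0],
                    "delta_log_p2": dl2[0],
                    "delta_delta_log": ddl,
                    "se_delta_delta_log": se,
                    "per_replicate_ddl": per_rep,
                }
            )
    return pd.DataFrame(rows)
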