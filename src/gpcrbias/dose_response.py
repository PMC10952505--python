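"""Empirical logistic concentration-response fitting.

Curves are fitted on log10(concentration) with untransformed responses,
either as a four-parameter logistic (bottom, top, log EC50, Hill slope) or
as a three-parameter variant with the Hill slope constrained to 1.  The
primary summary path fits each biological replicate individually and
reports the mean +/- SEM over replicates; a pooled fit over all points is
also returned for stages that need a single curve (operational-model and
receptor-inactivation analyses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .datasets import ConcResponseDataset

logger = logging.getLogger(__name__)

MODEL_KINDS = ("four_param", "three_param_hill1")

_HILL_BOUNDS = (0.05, 10.0)


class FitError(RuntimeError):
    """Curve fitting failed."""


@dataclass
class CurveParams:
    """One logistic curve: response = bottom + (e_max - bottom) /
    (1 + 10**((log_ec50 - x) * hill)) with x = log10([A])."""

    log_ec50: float
    e_max: float
    hill: float
    bottom: float

    def value(self, log_conc):
        x = np.asarray(log_conc, dtype=float)
        return self.bottom + (self.e_max - self.bottom) / (
            1.0 + 10.0 ** ((self.log_ec50 - x) * self.hill)
        )

    def inverse(self, response):
        """Analytic inverse: log10 concentration producing ``response``.

        Valid strictly between bottom and e_max.
        """
        r = np.asarray(response, dtype=float)
        span = self.e_max - self.bottom
        frac = (r - self.bottom) / span
        if np.any(frac <= 0) or np.any(frac >= 1):
            raise ValueError(
                "response outside the open interval (bottom, e_max); "
                f"bottom={self.bottom:.4g}, e_max={self.e_max:.4g}"
            )
        return self.log_ec50 + np.log10(frac / (1.0 - frac)) / self.hill


@dataclass
class LogisticFit:
    """Summary of per-replicate and pooled logistic fits for one dataset.

    ``log_ec50``/``e_max``/``hill``/``bottom`` are means over replicate
    fits (the primary summary); ``pooled`` is a single fit to all points.
    """

    model_kind: str
    log_ec50: float
    e_max: float
    hill: float
    bottom: float
    per_replicate_values: list[CurveParams] = field(default_factory=list)
    sem_log_ec50: float = np.nan
    sem_e_max: float = np.nan
    pooled: CurveParams | None = None
    assay_id: str = ""
    agonist_id: str = ""
    treatment_arm: str = "control"

    @property
    def curve(self) -> CurveParams:
        """The pooled curve (single best-fit curve over all points)."""
        if self.pooled is None:
            raise FitError("no pooled curve available")
        return self.pooled

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log_ec50


@dataclass
class FoldPotency:
    agonist_id: str
    reference_id: str
    fold: float


# -- outlier rule ---------------------------------------------------------


def exclude_outliers(dataset: ConcResponseDataset) -> ConcResponseDataset:
    """Flag replicate values that are >3 standard deviations away from the
    mean of the other replicate values at the same concentration.

    The rule is applied per concentration with a leave-one-out mean and SD
    (sample SD over the remaining values).  It needs at least three
    replicate values at a concentration; with fewer, the rule is skipped
    there and a diagnostic is logged.  Flagged points are retained in the
    record but carry ``excluded=True`` so downstream fits ignore them.
    """
    obs = dataset.observations.copy()
    flags = obs["excluded"].to_numpy().copy()
    for conc, grp in obs.groupby("conc_M"):
        idx = grp.index.to_numpy()
        vals = grp["response"].to_numpy()
        if len(vals) < 3:
            logger.info(
                "%s/%s: outlier rule skipped at %.3g M (only %d values)",
                dataset.assay_id, dataset.agonist_id, conc, len(vals),
            )
            continue
        for j in range(len(vals)):
            others = np.delete(vals, j)
            sd = others.std(ddof=1)
            if sd == 0:
                continue
            if abs(vals[j] - others.mean()) > 3.0 * sd:
                flags[idx[j]] = True
    obs["excluded"] = flags
    return dataset.with_observations(obs)


# -- logistic fitting -----------------------------------------------------


def _fit_points(
    log_conc: np.ndarray,
    response: np.ndarray,
    model_kind: str,
    bottom_fixed_at_zero: bool,
) -> CurveParams:
    """Deterministic multi-start least-squares fit of one curve."""
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    if len(np.unique(log_conc)) < 4:
        raise FitError("need at least 4 distinct concentrations to fit")
    fit_hill = model_kind == "four_param"
    fit_bottom = not bottom_fixed_at_zero

    rmax, rmin = float(response.max()), float(response.min())
    span = rmax - rmin if rmax > rmin else max(abs(rmax), 1.0)

    def model(x, *theta):
        log_ec50, e_max = theta[0], theta[1]
        k = 2
        hill = theta[k] if fit_hill else 1.0
        k += fit_hill
        bottom = theta[k] if fit_bottom else 0.0
        return bottom + (e_max - bottom) / (1.0 + 10.0 ** ((log_ec50 - x) * hill))

    lo = [log_conc.min() - 3, -np.inf]
    hi = [log_conc.max() + 3, np.inf]
    if fit_hill:
        lo.append(_HILL_BOUNDS[0])
        hi.append(_HILL_BOUNDS[1])
    if fit_bottom:
        lo.append(-np.inf)
        hi.append(np.inf)

    best = None
    # deterministic starts: a data-driven log EC50 guess (concentration
    # nearest half-maximal response) plus a coarse fallback grid
    half = rmin + 0.5 * (rmax - rmin)
    guess = float(log_conc[np.argmin(np.abs(response - half))])
    starts = [guess, *np.arange(
        log_conc.min() - 1.0, log_conc.max() + 1.0 + 1e-9, 1.0
    )]
    for s in starts:
        p0 = [s, rmax]
        if fit_hill:
            p0.append(1.0)
        if fit_bottom:
            p0.append(rmin)
        try:
            popt, _ = curve_fit(
                model, log_conc, response, p0=p0, bounds=(lo, hi),
                maxfev=20000, ftol=1e-14, xtol=1e-14, gtol=1e-14,
            )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((model(log_conc, *popt) - response) ** 2))
        if best is None or ssr < best[0] - 1e-12 * span**2:
            best = (ssr, popt)
        if best[0] < 1e-16 * span**2:
            break
    if best is None:
        raise FitError("logistic fit did not converge from any start")
    popt = best[1]
    k = 2
    hill = float(popt[k]) if fit_hill else 1.0
    k += fit_hill
    bottom = float(popt[k]) if fit_bottom else 0.0
    return CurveParams(
        log_ec50=float(popt[0]), e_max=float(popt[1]), hill=hill, bottom=bottom
    )


def fit_logistic(
    dataset: ConcResponseDataset,
    model_kind: str = "four_param",
    bottom_fixed_at_zero: bool = True,
    per_replicate: bool = True,
) -> LogisticFit:
    """Fit logistic curves per replicate, summarise as mean +/- SEM, and
    also return a pooled fit over all included points.

    Replicates whose individual fits fail to converge are dropped from the
    summary with a logged diagnostic; if every replicate fails, a
    :class:`FitError` is raised.  ``per_replicate=False`` skips the
    replicate loop (pooled curve only) for stages that need just one
    curve.
    """
    obs = dataset.included
    if obs.empty:
        raise FitError("no included observations to fit")

    per_rep: list[CurveParams] = []
    reps = sorted(obs["replicate"].unique()) if per_replicate else []
    for rep in reps:
        grp = obs[obs["replicate"] == rep]
        try:
            per_rep.append(
                _fit_points(
                    np.log10(grp["conc_M"].to_numpy()),
                    grp["response"].to_numpy(),
                    model_kind,
                    bottom_fixed_at_zero,
                )
            )
        except FitError as exc:
            logger.warning(
                "%s/%s replicate %d dropped from summary: %s",
                dataset.assay_id, dataset.agonist_id, rep, exc,
            )
    if per_replicate and not per_rep:
        raise FitError(
            f"{dataset.assay_id}/{dataset.agonist_id}: no replicate fit converged"
        )

    pooled = _fit_points(
        np.log10(obs["conc_M"].to_numpy()),
        obs["response"].to_numpy(),
        model_kind,
        bottom_fixed_at_zero,
    )

    summary = per_rep if per_rep else [pooled]
    lec = np.array([c.log_ec50 for c in summary])
    emx = np.array([c.e_max for c in summary])
    n = len(summary)
    sem = lambda v: float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return LogisticFit(
        model_kind=model_kind,
        log_ec50=float(lec.mean()),
        e_max=float(emx.mean()),
        hill=float(np.mean([c.hill for c in summary])),
        bottom=float(np.mean([c.bottom for c in summary])),
        per_replicate_values=per_rep,
        sem_log_ec50=sem(lec),
        sem_e_max=sem(emx),
        pooled=pooled,
        assay_id=dataset.assay_id,
        agonist_id=dataset.agonist_id,
        treatment_arm=dataset.treatment_arm,
    )


def fold_potency(fit_a: LogisticFit, fit_ref: LogisticFit) -> FoldPotency:
    """Potency of ``fit_a`` relative to ``fit_ref`` as a fold ratio,
    fold = 10**(log_ec50_ref - log_ec50_a), from mean log EC50s."""
    if fit_a.assay_id and fit_ref.assay_id and fit_a.assay_id != fit_ref.assay_id:
        raise ValueError(
            f"fold potency across assays ({fit_a.assay_id} vs {fit_ref.assay_id})"
        )
    return FoldPotency(
        agonist_id=fit_a.agonist_id,
        reference_id=fit_ref.agonist_id,
        fold=10.0 ** (fit_ref.log_ec50 - fit_a.log_ec50),
    )


def potency_table(fits: list[LogisticFit]) -> pd.DataFrame:
    """Agonist x assay summary of log EC50 +/- SEM and E_max +/- SEM."""
    rows = [
        {
            "assay_id": f.assay_id,
            "agonist_id": f.agonist_id,
            "treatment_arm": f.treatment_arm,
            "model_kind": f.model_kind,
            "log_ec50": f.log_ec50,
            "sem_log_ec50": f.sem_log_ec50,
            "e_max": f.e_max,
            "sem_e_max": f.sem_e_max,
            "hill": f.hill,
            "n_replicates": len(f.per_replicate_values),
        }
        for f in fits
    ]
    return pd.DataFrame(rows)
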