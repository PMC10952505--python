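"""Furchgott receptor-inactivation analysis of agonist affinity and efficacy.

Comparing concentration-response curves before and after partial
irreversible receptor inactivation (here by beta-funaltrexamine) lets the
functional affinity K_A be separated from potency.  Equieffective
concentration pairs ([A] on the control curve, [A'] on the depleted curve)
obey

    [A] = [A'] q K_A / (K_A + (1 - q) [A'])

where q is the fraction of receptors left functional.  Fitting this
relation over a ladder of response levels yields K_A and q; fractional
occupancy then follows the hyperbolic law p = [A]/([A] + K_A), and the
receptor reserve is indexed by K_A/EC50 and by the occupancy needed for
half-maximal response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq, least_squares

from .dose_response import CurveParams, LogisticFit

logger = logging.getLogger(__name__)


class FurchgottError(RuntimeError):
    pass


class DepletionInsufficientError(FurchgottError):
    """q is ~1, so K_A is unidentifiable from the pairing."""


@dataclass
class EquieffectivePairs:
    agonist_id: str
    assay_id: str
    response_levels: np.ndarray     # assay units, strictly increasing
    a_control: np.ndarray           # molar
    a_depleted: np.ndarray          # molar

    @property
    def n_levels(self) -> int:
        return len(self.response_levels)


@dataclass
class FurchgottResult:
    k_a: float                      # molar
    k_a_ci: tuple                   # 95% CI, molar
    q_functional: float
    q_ci: tuple
    ssr: float
    agonist_id: str = ""
    assay_id: str = ""


def _as_curve(fit) -> CurveParams:
    if isinstance(fit, LogisticFit):
        return fit.curve
    return fit


def equieffective_pairs(
    fit_control,
    fit_depleted,
    n_levels: int = 20,
    agonist_id: str = "",
    assay_id: str = "",
) -> EquieffectivePairs:
    """Read equieffective concentration pairs off two fitted curves.

    ``n_levels`` response levels are spaced evenly between 5% and 95% of
    the depleted curve's span (the widest band over which both fitted
    curves can be inverted), and each level is inverted analytically
    through both curves.  Fits may be :class:`LogisticFit` (the pooled
    curve is used - the horizontal lines are drawn on the fitted curves,
    not the raw points) or bare :class:`CurveParams`.
    """
    ctrl = _as_curve(fit_control)
    depl = _as_curve(fit_depleted)
    if isinstance(fit_control, LogisticFit) and isinstance(fit_depleted, LogisticFit):
        if (fit_control.agonist_id, fit_control.assay_id) != (
            fit_depleted.agonist_id, fit_depleted.assay_id
        ):
            raise FurchgottError("control and depleted fits are for different curves")
        agonist_id = agonist_id or fit_control.agonist_id
        assay_id = assay_id or fit_control.assay_id

    span = depl.e_max - depl.bottom
    lo = depl.bottom + 0.05 * span
    hi = depl.bottom + 0.95 * span
    # the whole ladder must be invertible on the control curve too
    if span <= 0 or hi >= ctrl.e_max or lo <= ctrl.bottom:
        raise FurchgottError(
            "curves do not overlap across the level ladder; usable range is "
            f"({max(lo, ctrl.bottom):.4g}, {min(hi, ctrl.e_max):.4g})"
        )
    levels = np.linspace(lo, hi, n_levels)
    a_ctrl = 10.0 ** ctrl.inverse(levels)
    a_depl = 10.0 ** depl.inverse(levels)
    return EquieffectivePairs(
        agonist_id=agonist_id,
        assay_id=assay_id,
        response_levels=levels,
        a_control=a_ctrl,
        a_depleted=a_depl,
    )


def _pair_model(a_depleted, log_ka, q):
    ka = 10.0 ** log_ka
    return a_depleted * q * ka / (ka + (1.0 - q) * a_depleted)


def _profile_ci_1d(ssr_at, x_hat, ssr_min, dof, lo, hi, n_grid=400):
    """Profile-likelihood 95% CI for one parameter: the set where
    SSR(x) <= SSR_min * (1 + F_{0.95}(1, dof) / dof)."""
    thresh = ssr_min * (1.0 + sps.f.ppf(0.95, 1, dof) / dof)
    g = lambda x: ssr_at(x) - thresh
    xs = np.linspace(lo, hi, n_grid)
    below = np.array([g(x) <= 0 for x in xs])
    if not below.any():
        return (x_hat, x_hat)
    first, last = np.argmax(below), len(below) - 1 - np.argmax(below[::-1])
    lo_ci = xs[first] if first == 0 else brentq(g, xs[first - 1], xs[first])
    hi_ci = xs[last] if last == len(xs) - 1 else brentq(g, xs[last], xs[last + 1])
    return (float(lo_ci), float(hi_ci))


def fit_furchgott(pairs: EquieffectivePairs) -> FurchgottResult:
    """Fit the inactivation relation over equieffective pairs for K_A and q.

    Residuals are taken in log10 concentration (pairs span orders of
    magnitude, and log residuals weight every level comparably).  95%
    confidence intervals come from the asymptotic covariance; when an
    asymptotic interval escapes the parameter bounds (q near 0 or 1), a
    profile-likelihood interval is substituted.
    """
    if pairs.n_levels < 5:
        raise FurchgottError("need at least 5 equieffective pairs")
    a_c, a_d = pairs.a_control, pairs.a_depleted

    def resid(theta):
        return np.log10(_pair_model(a_d, *theta)) - np.log10(a_c)

    # grid start, then bounded refinement
    lka_grid = np.arange(np.log10(a_d.min()) - 4, np.log10(a_d.max()) + 2.1, 0.25)
    q_grid = np.linspace(0.02, 1.0, 50)
    ssrs = np.array([[np.sum(resid((lk, q)) ** 2) for q in q_grid] for lk in lka_grid])
    i, j = np.unravel_index(np.argmin(ssrs), ssrs.shape)
    lo = [np.log10(a_c.min()) - 6, 1e-6]
    hi = [np.log10(a_d.max()) + 6, 1.0]
    sol = least_squares(
        resid, [lka_grid[i], q_grid[j]], bounds=(lo, hi),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if not sol.success:
        raise FurchgottError("inactivation-relation fit did not converge")
    log_ka, q = sol.x
    ssr = float(np.sum(sol.fun ** 2))
    if q > 0.99:
        raise DepletionInsufficientError(
            f"fitted q = {q:.3f} ~ 1: depletion insufficient to identify K_A"
        )

    dof = max(pairs.n_levels - 2, 1)
    sigma2 = ssr / dof
    try:
        cov = sigma2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se_lka, se_q = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se_lka = se_q = np.nan

    z = sps.t.ppf(0.975, dof)
    ka_ci = (10.0 ** (log_ka - z * se_lka), 10.0 ** (log_ka + z * se_lka))
    q_ci = (q - z * se_q, q + z * se_q)

    if not np.isfinite(se_q) or q_ci[0] <= 0 or q_ci[1] > 1:
        def ssr_q(qv):
            s = least_squares(
                lambda t: resid((t[0], qv)), [log_ka],
                bounds=([lo[0]], [hi[0]]),
            )
            return float(np.sum(s.fun ** 2))
        q_ci = _profile_ci_1d(ssr_q, q, ssr, dof, 1e-6, 1.0)
    if not np.isfinite(se_lka):
        def ssr_lka(lk):
            s = least_squares(
                lambda t: resid((lk, t[0])), [q], bounds=([1e-6], [1.0])
            )
            return float(np.sum(s.fun ** 2))
        lk_ci = _profile_ci_1d(ssr_lka, log_ka, ssr, dof, lo[0], hi[0])
        ka_ci = (10.0 ** lk_ci[0], 10.0 ** lk_ci[1])

    return FurchgottResult(
        k_a=float(10.0 ** log_ka),
        k_a_ci=tuple(float(v) for v in ka_ci),
        q_functional=float(q),
        q_ci=tuple(float(v) for v in q_ci),
        ssr=ssr,
        agonist_id=pairs.agonist_id,
        assay_id=pairs.assay_id,
    )


def occupancy(conc, k_a):
    """Fractional receptor occupancy p = [A] / ([A] + K_A)."""
    if k_a <= 0:
        raise ValueError("k_a must be positive")
    c = np.asarray(conc, dtype=float)
    return c / (c + k_a)


def occupancy_curve(k_a, conc_grid) -> list:
    return [(float(c), float(occupancy(c, k_a))) for c in np.asarray(conc_grid)]


def reserve_summary(fit_control, furch: FurchgottResult):
    """Receptor-reserve indices from the control curve and the fitted K_A.

    Returns ``(ka_over_ec50, occupancy_at_half_max_percent)``.  The
    occupancy at half-maximal response is read off the occupancy-vs-
    response relation implied by the fitted control curve: the control
    curve is inverted at 50% of its own maximum and the occupancy law is
    evaluated there.  For a Hill-slope-1 curve this reduces to
    100 / (1 + K_A/EC50).
    """
    ctrl = _as_curve(fit_control)
    ka_over_ec50 = furch.k_a / 10.0 ** ctrl.log_ec50
    half = ctrl.bottom + 0.5 * (ctrl.e_max - ctrl.bottom)
    try:
        log_a_half = float(ctrl.inverse(half))
    except ValueError as exc:
        raise FurchgottError(
            "response never reaches 50% of maximum within the curve range"
        ) from exc
    occ = float(occupancy(10.0 ** log_a_half, furch.k_a))
    return float(ka_over_ec50), 100.0 * occ
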