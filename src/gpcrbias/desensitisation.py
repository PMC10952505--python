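"""Desensitisation of agonist-evoked GIRK currents.

Traces are baseline-subtracted (30 s pre-application mean), normalised to
the noradrenaline reference current recorded in the same cell, and the
post-peak decline is fitted to a one-phase exponential decay

    I(t) = plateau + (peak - plateau) * exp(-k t),   t from the peak,

from which the percent desensitisation at 10 min post peak is read off the
fitted curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .datasets import CurrentTrace

logger = logging.getLogger(__name__)

PRE_APPLICATION_BASELINE_S = 30.0
TEN_MINUTES_S = 600.0
PEAK_SMOOTH_SAMPLES = 5


class DesensError(RuntimeError):
    pass


@dataclass
class DesensResult:
    cell_id: str
    drug_id: str
    normalised_peak: float      # fraction of the NA reference current
    plateau: float              # same units
    rate_k: float               # 1/s, >= 0
    percent_desens_10min: float
    peak_time: float            # s, in trace time


def normalise_to_na(trace: CurrentTrace) -> CurrentTrace:
    """Divide every sample by the cell's noradrenaline reference peak."""
    return replace(
        trace,
        currents=trace.currents / trace.na_peak_current,
        na_peak_current=1.0,
    )


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if len(x) < w:
        return x.copy()
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def find_peak(trace: CurrentTrace):
    """Peak of the smoothed post-application current.

    Uses a 5-sample moving average after the application event so a single
    noisy sample cannot define the peak, and only considers candidates
    followed by at least 600 s of recording (the decay window).  Returns
    (peak_time, peak_value_raw_units) from the smoothed signal.
    """
    t_app = trace.application_time()
    mask = (trace.times >= t_app) & (
        trace.times <= trace.times[-1] - TEN_MINUTES_S
    )
    if not mask.any():
        raise DesensError(
            f"no candidate peak with >= {TEN_MINUTES_S:.0f} s of post-peak "
            "recording after it"
        )
    smoothed = _moving_average(trace.currents, PEAK_SMOOTH_SAMPLES)
    idx = np.flatnonzero(mask)
    k = idx[np.argmax(smoothed[idx])]
    return float(trace.times[k]), float(smoothed[k])


def fit_decay(trace: CurrentTrace) -> DesensResult:
    """Quantify desensitisation of one trace.

    The trace is baseline-subtracted using the 30 s pre-application mean,
    normalised to the NA reference, its peak located, and the post-peak
    segment (>= 600 s required) fitted to a one-phase decay.  A post-peak
    segment that trends upward fits to k = 0 and reports 0%
    desensitisation with a warning.
    """
    t_app = trace.application_time()
    pre = (trace.times >= t_app - PRE_APPLICATION_BASELINE_S) & (
        trace.times < t_app
    )
    baseline = float(trace.currents[pre].mean()) if pre.any() else 0.0
    work = replace(trace, currents=trace.currents - baseline)
    work = normalise_to_na(work)

    t_peak, peak = find_peak(work)
    seg = work.times >= t_peak
    t = work.times[seg] - t_peak
    i = work.currents[seg]
    if t[-1] < TEN_MINUTES_S:
        raise DesensError(
            f"only {t[-1]:.0f} s of post-peak recording; need >= {TEN_MINUTES_S:.0f} s"
        )

    if peak <= 0:
        raise DesensError("non-positive peak after baseline subtraction")

    # the detected peak sets where the decay starts; its amplitude is a
    # free parameter of the decay fit (a noisy single sample would
    # otherwise bias plateau and k)
    def model(tt, y0, plateau, k):
        return plateau + (y0 - plateau) * np.exp(-k * tt)

    try:
        popt, _ = curve_fit(
            model, t, i,
            p0=[peak, max(float(i[-1]), 1e-6), 1e-3],
            bounds=([0.0, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000, ftol=1e-14, xtol=1e-14,
        )
        peak, plateau, k = float(popt[0]), float(popt[1]), float(popt[2])
    except (RuntimeError, ValueError):
        plateau, k = peak, 0.0

    # an upward-trending segment pins the fit to the k=0 boundary
    if k <= 0 or plateau >= peak:
        if np.polyfit(t, i, 1)[0] > 0:
            logger.warning(
                "%s/%s: post-peak current increases; desensitisation set to 0",
                trace.cell_id, trace.drug_id,
            )
        plateau, k = peak, 0.0

    fitted_600 = plateau + (peak - plateau) * np.exp(-k * TEN_MINUTES_S)
    pct = 100.0 * (peak - fitted_600) / peak
    return DesensResult(
        cell_id=trace.cell_id,
        drug_id=trace.drug_id,
        normalised_peak=peak,
        plateau=plateau,
        rate_k=k,
        percent_desens_10min=float(np.clip(pct, 0.0, 100.0)),
        peak_time=t_peak,
    )


def compare_desens(groups, reference_id, alpha: float = 0.05):
    """ANOVA-gated Dunnett comparison of per-cell percent-desensitisation
    values against the reference drug (delegates to
    :func:`gpcrbias.stats.compare_to_reference`)."""
    from .stats import compare_to_reference

    return compare_to_reference(groups, reference_id, alpha=alpha)
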