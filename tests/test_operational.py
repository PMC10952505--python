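"""Operational-model fitting and the transduction-ratio bias ledger."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from gpcrbias import (
    GroundTruth,
    OperationalFit,
    bias_table,
    delta_delta_log,
    delta_log,
    evaluate_operational,
    fit_operational,
    fit_operational_assay,
    simulate_assay,
)
from gpcrbias.operational import NoSignalError


class TestEvaluate:
    @pytest.mark.parametrize(
        "basal, e_max, tau, n, conc_over_ka, expected",
        [
            (0, 100, 1, 1, 1, 100 / 3),      # [A]=K_A: numerator K_A of 3K_A
            (10, 110, 2, 1, 1, 60.0),        # 10 + 100*2K/(2K+2K)
            (0, 100, 3, 2, 1, 100 * 9 / 13),
        ],
    )
    def test_point_values(self, basal, e_max, tau, n, conc_over_ka, expected):
        ka = 1e-6
        got = evaluate_operational(basal, e_max, tau, n, ka, conc_over_ka * ka)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_saturating_asymptote(self):
        # conc >> K_A with n=1: basal + span * tau/(tau+1)
        got = evaluate_operational(0, 100, 1, 1, 1e-6, 1e3)
        assert got == pytest.approx(50.0, rel=1e-6)

    def test_zero_concentration_gives_basal(self):
        assert evaluate_operational(7.0, 100, 5, 1, 1e-6, 0.0) == 7.0


class TestFitOperational:
    def test_noiseless_transduction_ratio_recovery(self):
        ds = simulate_assay(
            GroundTruth("a", "x", tau=10.0, k_a=1e-6, noise_cv=0.0, seed=0)
        )
        fit = fit_operational(ds, e_max_system=100.0)
        assert fit.log_tau_over_ka == pytest.approx(7.0, abs=1e-6)

    def test_matches_ratio_reparameterised_fit(self):
        """Fitting (log tau, log K_A) or (log ratio, log tau) must land on
        the same Log(tau/K_A)."""
        ds = simulate_assay(
            GroundTruth("a", "x", tau=5.0, k_a=1e-7, noise_cv=0.05, seed=11)
        )
        fit = fit_operational(ds, e_max_system=100.0)

        obs = ds.included
        log_a = np.log10(obs["conc_M"].to_numpy())
        resp = obs["response"].to_numpy()

        def resid(theta):
            log_ratio, log_tau = theta
            tau, ka = 10.0 ** log_tau, 10.0 ** (log_tau - log_ratio)
            return evaluate_operational(0, 100.0, tau, 1.0, ka, 10.0 ** log_a) - resp

        alt = least_squares(resid, [7.0, 1.0], xtol=1e-15, ftol=1e-15, gtol=1e-15)
        assert fit.log_tau_over_ka == pytest.approx(alt.x[0], abs=1e-4)

    def test_full_agonist_ratio_se_finite(self):
        # tau >> 1: tau itself rides a flat ridge but the composite does not
        ds = simulate_assay(
            GroundTruth("a", "x", tau=100.0, k_a=1e-6, noise_cv=0.05, seed=2)
        )
        fit = fit_operational(
            ds, e_max_system=100.0, bootstrap_se=True, n_bootstrap=50, seed=0
        )
        assert np.isfinite(fit.se_log_tau_over_ka)
        assert 0 < fit.se_log_tau_over_ka < 1.0

    def test_agrees_with_exhaustive_grid_oracle(self):
        truth = GroundTruth("a", "x", tau=3.0, k_a=1e-6, noise_cv=0.05, seed=4,
                            n_replicates=1,
                            conc_grid=10.0 ** np.array([-8.0, -7.0, -6.5, -6.0, -5.0]))
        ds = simulate_assay(truth)
        fit = fit_operational(ds, e_max_system=100.0)

        obs = ds.included
        log_a = np.log10(obs["conc_M"].to_numpy())
        resp = obs["response"].to_numpy()
        lts = np.arange(-0.5, 1.51, 0.01)
        lks = np.arange(-7.5, -4.49, 0.01)
        pred = evaluate_operational(
            0, 100.0, 10.0 ** lts[:, None, None], 1.0,
            10.0 ** lks[None, :, None], 10.0 ** log_a[None, None, :],
        )
        ssr = ((pred - resp) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(ssr), ssr.shape)
        assert fit.ssr <= ssr[i, j] + 1e-9
        assert fit.log_tau_over_ka == pytest.approx(lts[i] - lks[j], abs=0.02)

    def test_flat_data_raises_no_signal(self):
        ds = simulate_assay(
            GroundTruth("a", "x", tau=10.0, k_a=1e-6, noise_cv=0.0, seed=0)
        )
        flat = ds.with_observations(ds.observations.assign(response=42.0))
        with pytest.raises(NoSignalError):
            fit_operational(flat, e_max_system=100.0)

    def test_delta_log_ci_calibration_two_agonists(self):
        """Known 100-fold tau/K_A ratio: DeltaLog = 2 and its 95% CI should
        cover the truth in most seeded simulations."""
        hits = 0
        n = 30
        for s in range(n):
            d1 = simulate_assay(GroundTruth("ref", "x", tau=3, k_a=1e-6,
                                            noise_cv=0.05, seed=2 * s))
            d2 = simulate_assay(GroundTruth("a", "x", tau=3, k_a=1e-8,
                                            noise_cv=0.05, seed=2 * s + 1))
            f1 = fit_operational(d1, e_max_system=100.0)
            f2 = fit_operational(d2, e_max_system=100.0)
            v, se = delta_log(f2, f1)
            hits += abs(v - 2.0) <= 1.96 * se
        assert hits >= int(0.8 * n)


def _ofit(log_ratio, se=0.1, agonist="a", assay="x", per_rep=None):
    return OperationalFit(
        agonist_id=agonist, assay_id=assay, basal=0.0, e_max_system=100.0,
        tau=1.0, k_a=10.0 ** -log_ratio, n_slope=1.0,
        log_tau_over_ka=log_ratio, se_log_tau_over_ka=se,
        per_replicate_log_tau_over_ka=per_rep,
    )


class TestBiasLedger:
    def test_delta_log_self_is_zero_with_quadrature_se(self):
        f = _ofit(7.0, se=0.1)
        v, se = delta_log(f, f)
        assert v == 0.0
        assert se == pytest.approx(0.1 * np.sqrt(2))

    def test_delta_log_quadrature(self):
        v, se = delta_log(_ofit(7.0, 0.1), _ofit(6.0, 0.1, agonist="ref"))
        assert (v, se) == (pytest.approx(1.0), pytest.approx(0.1414, abs=1e-3))

    def test_delta_log_assay_mismatch_raises(self):
        with pytest.raises(ValueError):
            delta_log(_ofit(7.0, assay="x"), _ofit(6.0, assay="y"))

    def test_delta_delta_log_arithmetic_and_antisymmetry(self):
        dl1, dl2 = (1.0, 0.1), (-0.5, 0.1)
        v, se = delta_delta_log(dl1, dl2)
        assert (v, se) == (pytest.approx(1.5), pytest.approx(0.1414, abs=1e-3))
        v_swapped, se_swapped = delta_delta_log(dl2, dl1)
        assert v_swapped == -v
        assert se_swapped == se

    def test_reference_rows_exactly_zero(self):
        fits = {
            "p1": {"ref": _ofit(6.0, assay="p1", agonist="ref"),
                   "a": _ofit(7.0, assay="p1")},
            "p2": {"ref": _ofit(5.0, assay="p2", agonist="ref"),
                   "a": _ofit(5.5, assay="p2")},
        }
        table = bias_table(fits, "ref", [("p1", "p2")])
        ref_row = table[table.agonist_id == "ref"].iloc[0]
        assert ref_row.delta_delta_log == 0.0
        a_row = table[table.agonist_id == "a"].iloc[0]
        assert a_row.delta_delta_log == pytest.approx(0.5)

    def test_shift_invariance_of_differences(self):
        """Adding a constant to every Log(tau/K_A) within an assay leaves
        DeltaLog and DeltaDeltaLog unchanged."""
        base = {
            "p1": {"ref": _ofit(6.0, assay="p1", agonist="ref"),
                   "a": _ofit(7.3, assay="p1")},
            "p2": {"ref": _ofit(5.1, assay="p2", agonist="ref"),
                   "a": _ofit(5.9, assay="p2")},
        }
        shifted = {
            assay: {
                ag: _ofit(f.log_tau_over_ka + 2.5, f.se_log_tau_over_ka,
                          agonist=ag, assay=assay)
                for ag, f in fits.items()
            }
            for assay, fits in base.items()
        }
        t0 = bias_table(base, "ref", [("p1", "p2")])
        t1 = bias_table(shifted, "ref", [("p1", "p2")])
        assert np.allclose(t0.delta_delta_log, t1.delta_delta_log)
        assert np.allclose(t0.delta_log_p1, t1.delta_log_p1)


class TestAssayLevelFit:
    def test_shared_system_max_recovers_partial_agonist_ratio(self):
        # full agonist pins the system max; partial agonist tau = 0.5
        full = simulate_assay(GroundTruth("full", "x", tau=50, k_a=1e-6,
                                          noise_cv=0.0, seed=0))
        part = simulate_assay(GroundTruth("part", "x", tau=0.5, k_a=1e-7,
                                          noise_cv=0.0, seed=1))
        fits = fit_operational_assay([full, part], per_replicate=False)
        assert fits["part"].log_tau_over_ka == pytest.approx(
            np.log10(0.5) + 7.0, abs=2e-2
        )
        assert fits["full"].e_max_system == fits["part"].e_max_system

    def test_per_replicate_ratios_returned(self):
        ds = simulate_assay(GroundTruth("a", "x", tau=3, k_a=1e-6,
                                        noise_cv=0.05, seed=9))
        fits = fit_operational_assay([ds])
        per_rep = fits["a"].per_replicate_log_tau_over_ka
        assert len(per_rep) == 5
        assert np.std(per_rep) < 0.3
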