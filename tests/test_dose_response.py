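"""Logistic fitting, the leave-one-out outlier rule and fold potency."""

import numpy as np
import pandas as pd
import pytest

from gpcrbias import (
    ConcResponseDataset,
    CurveParams,
    LogisticFit,
    exclude_outliers,
    fit_logistic,
    fold_potency,
)

GRID = 10.0 ** np.arange(-9.0, -4.9, 0.5)


def make_dataset(curve: CurveParams, n_replicates=1, noise_sd=0.0, seed=0,
                 grid=GRID, **kw):
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        resp = curve.value(np.log10(grid)) + rng.normal(0, noise_sd, len(grid))
        rows += [
            {"replicate": rep, "conc_M": c, "response": r}
            for c, r in zip(grid, resp)
        ]
    return ConcResponseDataset("assay", "drug", pd.DataFrame(rows), **kw)


def from_values(values_by_conc):
    rows = [
        {"replicate": i + 1, "conc_M": conc, "response": v}
        for conc, values in values_by_conc.items()
        for i, v in enumerate(values)
    ]
    return ConcResponseDataset("assay", "drug", pd.DataFrame(rows))


class TestOutlierRule:
    def test_gross_outlier_flagged_leave_one_out(self):
        # mean of the others is 10, their SD 0.816; 500 is far outside 3 SD
        ds = from_values({1e-6: [10, 11, 9, 10, 500]})
        out = exclude_outliers(ds)
        flagged = out.observations[out.observations.excluded]
        assert list(flagged.response) == [500]

    def test_identical_values_not_flagged(self):
        out = exclude_outliers(from_values({1e-6: [10, 10, 10, 10, 10]}))
        assert not out.observations.excluded.any()

    def test_rule_skipped_below_three_replicates(self, caplog):
        with caplog.at_level("INFO", logger="gpcrbias.dose_response"):
            out = exclude_outliers(from_values({1e-6: [10, 500]}))
        assert not out.observations.excluded.any()
        assert "skipped" in caplog.text

    def test_clean_scatter_untouched(self):
        out = exclude_outliers(from_values({1e-6: [9.0, 10.0, 11.0, 10.5, 9.5]}))
        assert not out.observations.excluded.any()


class TestLogisticFit:
    def test_noiseless_recovery(self):
        truth = CurveParams(log_ec50=-7.0, e_max=100.0, hill=1.0, bottom=0.0)
        fit = fit_logistic(make_dataset(truth))
        assert fit.log_ec50 == pytest.approx(-7.0, abs=1e-6)
        assert fit.e_max == pytest.approx(100.0, rel=1e-6)
        assert fit.pooled.log_ec50 == pytest.approx(-7.0, abs=1e-6)

    def test_hill_constrained_to_one(self):
        truth = CurveParams(log_ec50=-7.0, e_max=100.0, hill=1.0, bottom=0.0)
        fit = fit_logistic(make_dataset(truth), model_kind="three_param_hill1")
        assert fit.hill == 1.0
        assert fit.pooled.hill == 1.0

    def test_free_bottom_recovered(self):
        truth = CurveParams(log_ec50=-7.0, e_max=100.0, hill=1.5, bottom=12.0)
        fit = fit_logistic(make_dataset(truth), bottom_fixed_at_zero=False)
        assert fit.bottom == pytest.approx(12.0, rel=1e-5)
        assert fit.hill == pytest.approx(1.5, rel=1e-5)

    def test_agrees_with_grid_search_oracle_hill2(self):
        truth = CurveParams(log_ec50=-7.2, e_max=80.0, hill=2.0, bottom=0.0)
        ds = make_dataset(truth, noise_sd=1.0, seed=3)
        fit = fit_logistic(ds).pooled

        # coarse-to-fine exhaustive search over (log EC50, E_max, Hill)
        x = np.log10(ds.included["conc_M"].to_numpy())
        y = ds.included["response"].to_numpy()
        centre = np.array([-7.0, 75.0, 1.5])
        width = np.array([1.5, 30.0, 1.4])
        for _ in range(8):
            lec, emx, hil = (
                np.linspace(c - w, c + w, 11) for c, w in zip(centre, width)
            )
            best, best_ssr = None, np.inf
            for a in lec:
                for b in emx:
                    for h in hil:
                        pred = b / (1 + 10.0 ** ((a - x) * h))
                        ssr = np.sum((pred - y) ** 2)
                        if ssr < best_ssr:
                            best, best_ssr = (a, b, h), ssr
            centre, width = np.array(best), width / 4
        assert fit.log_ec50 == pytest.approx(best[0], abs=1e-3)
        assert fit.e_max == pytest.approx(best[1], rel=1e-3)
        assert fit.hill == pytest.approx(best[2], abs=1e-3)

    @pytest.mark.parametrize("c", [0.5, 3.0, 17.3])
    def test_response_scale_equivariance(self, c):
        truth = CurveParams(log_ec50=-7.0, e_max=100.0, hill=1.3, bottom=0.0)
        ds = make_dataset(truth, n_replicates=2, noise_sd=2.0, seed=5)
        scaled = ds.with_observations(
            ds.observations.assign(response=ds.observations.response * c)
        )
        f, fs = fit_logistic(ds), fit_logistic(scaled)
        assert fs.log_ec50 == pytest.approx(f.log_ec50, abs=1e-6)
        assert fs.hill == pytest.approx(f.hill, rel=1e-6)
        assert fs.e_max == pytest.approx(c * f.e_max, rel=1e-6)

    def test_concentration_shift_equivariance(self):
        truth = CurveParams(log_ec50=-7.0, e_max=100.0, hill=1.0, bottom=0.0)
        ds = make_dataset(truth, n_replicates=2, noise_sd=2.0, seed=6)
        shifted = ds.with_observations(
            ds.observations.assign(conc_M=ds.observations.conc_M * 10.0)
        )
        f, fs = fit_logistic(ds), fit_logistic(shifted)
        assert fs.log_ec50 - f.log_ec50 == pytest.approx(1.0, abs=1e-6)

    def test_pooled_matches_replicate_mean_for_identical_replicates(self):
        truth = CurveParams(log_ec50=-6.5, e_max=90.0, hill=1.0, bottom=0.0)
        ds = make_dataset(truth, n_replicates=3)
        fit = fit_logistic(ds)
        assert fit.pooled.log_ec50 == pytest.approx(fit.log_ec50, abs=1e-6)
        assert fit.sem_log_ec50 == pytest.approx(0.0, abs=1e-9)

    def test_too_few_concentrations_raises(self):
        from gpcrbias import FitError
        truth = CurveParams(log_ec50=-7.0, e_max=100.0, hill=1.0, bottom=0.0)
        with pytest.raises(FitError):
            fit_logistic(make_dataset(truth, grid=GRID[:3]))

    def test_curve_inverse_round_trip(self):
        curve = CurveParams(log_ec50=-7.0, e_max=100.0, hill=1.7, bottom=5.0)
        levels = np.linspace(10, 95, 9)
        assert curve.value(curve.inverse(levels)) == pytest.approx(levels)


def _fit_with(log_ec50, agonist="a", assay="assay"):
    return LogisticFit(
        model_kind="four_param", log_ec50=log_ec50, e_max=100.0, hill=1.0,
        bottom=0.0, agonist_id=agonist, assay_id=assay,
    )


class TestFoldPotency:
    @pytest.mark.parametrize(
        "lec_a, lec_ref, expected",
        [
            # published mean log EC50s: carfentanil vs the reference peptide
            (-8.11, -6.48, 42.66),   # G-protein activation
            (-9.56, -6.14, 2630.3),  # surface receptor loss
            (-7.0, -7.0, 1.0),
        ],
    )
    def test_fold_from_log_ec50_difference(self, lec_a, lec_ref, expected):
        fp = fold_potency(_fit_with(lec_a), _fit_with(lec_ref, "ref"))
        assert fp.fold == pytest.approx(expected, rel=1e-3)

    def test_cross_assay_rejected(self):
        with pytest.raises(ValueError):
            fold_potency(_fit_with(-7, assay="x"), _fit_with(-7, assay="y"))
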