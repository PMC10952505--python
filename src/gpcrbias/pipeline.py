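"""End-to-end analysis pipeline and report rendering.

Chains outlier exclusion -> logistic fitting -> operational-model
transduction ratios -> bias ledger (with reference-comparison statistics)
-> optional receptor-inactivation (two-arm) analysis -> optional
desensitisation analysis, writing delimited-text report tables plus a run
log recording the seed and package versions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import ConcResponseDataset, read_datasets, read_trace
from .desensitisation import compare_desens, fit_decay
from .dose_response import exclude_outliers, fit_logistic, potency_table
from .furchgott import equieffective_pairs, fit_furchgott, reserve_summary
from .operational import bias_table, fit_operational_assay
from .stats import compare_to_reference

logger = logging.getLogger(__name__)

# beta-arrestin-side pathway listed first in each pair so that positive
# DeltaDeltaLog means arrestin bias
DEFAULT_PAIRS = [
    ("arrestin", "gprotein"),
    ("surface_loss", "gprotein"),
    ("arrestin", "girk"),
    ("surface_loss", "girk"),
    ("surface_loss", "arrestin"),
    ("gprotein", "girk"),
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    input: str | None = None
    traces_dir: str | None = None
    reference: str = "DAMGO"
    pathway_pairs: list = field(default_factory=lambda: list(DEFAULT_PAIRS))
    model_kinds: dict = field(default_factory=dict)   # assay -> model kind
    fix_bottom_zero: bool = True
    furchgott_levels: int = 20
    alpha: float = 0.05
    seed: int = 0
    out: str = "gpcrbias-out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.pathway_pairs = [tuple(p) for p in cfg.pathway_pairs]
        return cfg


@dataclass
class ReportBundle:
    potency: pd.DataFrame
    transduction: pd.DataFrame
    bias: pd.DataFrame | None
    furchgott: pd.DataFrame | None
    desens: pd.DataFrame | None
    biased_agonists: list
    out_dir: Path | None


def _bias_with_stats(fits_by_assay, reference, pairs, alpha):
    table = bias_table(fits_by_assay, reference, pairs)
    p_adj = []
    for (p1, p2), grp in table.groupby(["pathway_1", "pathway_2"], sort=False):
        groups = {
            row.agonist_id: np.asarray(row.per_replicate_ddl)
            for row in grp.itertuples()
            if row.per_replicate_ddl is not None
        }
        pvals = {}
        if len(groups) >= 3 and reference in groups:
            cmp = compare_to_reference(groups, reference, alpha=alpha)
            pvals = cmp.p_adjusted
        for row in grp.itertuples():
            p_adj.append(
                {
                    "agonist_id": row.agonist_id,
                    "pathway_1": p1,
                    "pathway_2": p2,
                    "p_adjusted": pvals.get(row.agonist_id),
                }
            )
    return table.merge(
        pd.DataFrame(p_adj), on=["agonist_id", "pathway_1", "pathway_2"]
    )


def run_pipeline(
    config: PipelineConfig,
    datasets: list[ConcResponseDataset] | None = None,
) -> ReportBundle:
    """Run every applicable stage and write report tables under
    ``config.out`` (pass ``out=None``/empty to skip writing).

    Stage failures are re-raised as :class:`PipelineError` carrying the
    stage name; tables already produced are still written.
    """
    out_dir = Path(config.out) if config.out else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    if datasets is None:
        if not config.input:
            raise PipelineError("read", ValueError("no input file or datasets"))
        try:
            datasets = read_datasets(config.input)
        except Exception as exc:
            raise PipelineError("read", exc) from exc

    written: dict[str, pd.DataFrame] = {}

    def emit(name: str, frame: pd.DataFrame):
        written[name] = frame
        if out_dir is not None:
            frame.to_csv(out_dir / f"{name}.csv", index=False)

    try:
        clean = [exclude_outliers(d) for d in datasets]
        logistic_fits = {}
        for d in clean:
            kind = config.model_kinds.get(d.assay_id, "four_param")
            logistic_fits[d.key()] = fit_logistic(
                d, model_kind=kind,
                bottom_fixed_at_zero=config.fix_bottom_zero,
            )
        emit("potency_table", potency_table(list(logistic_fits.values())))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("fit_logistic", exc) from exc

    try:
        control = [d for d in clean if d.treatment_arm == "control"]
        fits_by_assay = {}
        for assay in sorted({d.assay_id for d in control}):
            fits_by_assay[assay] = fit_operational_assay(
                [d for d in control if d.assay_id == assay]
            )
        trans_rows = [
            {
                "assay_id": f.assay_id,
                "agonist_id": f.agonist_id,
                "log_tau_over_ka": f.log_tau_over_ka,
                "se_log_tau_over_ka": f.se_log_tau_over_ka,
                "tau": f.tau,
                "k_a_M": f.k_a,
                "e_max_system": f.e_max_system,
                "n_slope": f.n_slope,
            }
            for fits in fits_by_assay.values()
            for f in fits.values()
        ]
        emit("transduction_ratios", pd.DataFrame(trans_rows))
    except Exception as exc:
        raise PipelineError("fit_operational", exc) from exc

    bias = None
    biased: list = []
    pairs = [
        (p1, p2) for p1, p2 in config.pathway_pairs
        if p1 in fits_by_assay and p2 in fits_by_assay
    ]
    if pairs:
        try:
            bias = _bias_with_stats(
                fits_by_assay, config.reference, pairs, config.alpha
            )
            emit("bias_table", bias.drop(columns=["per_replicate_ddl"]))
            # biased = significant positive DeltaDeltaLog in the primary
            # (first) pathway pair
            p1, p2 = pairs[0]
            prim = bias[(bias.pathway_1 == p1) & (bias.pathway_2 == p2)]
            biased = sorted(
                row.agonist_id
                for row in prim.itertuples()
                if row.p_adjusted is not None
                and row.p_adjusted < config.alpha
                and row.delta_delta_log > 0
            )
        except Exception as exc:
            raise PipelineError("bias", exc) from exc
    else:
        logger.info("bias stage skipped: no applicable pathway pairs")

    furch = None
    two_arm = sorted(
        {
            (d.assay_id, d.agonist_id)
            for d in clean
            if d.treatment_arm == "depleted"
        }
    )
    if two_arm:
        try:
            rows = []
            for assay, agonist in two_arm:
                fc = logistic_fits.get((assay, agonist, "control"))
                fd = logistic_fits.get((assay, agonist, "depleted"))
                if fc is None or fd is None:
                    logger.warning(
                        "skipping inactivation analysis for %s/%s: missing arm",
                        assay, agonist,
                    )
                    continue
                pairs_ee = equieffective_pairs(
                    fc, fd, n_levels=config.furchgott_levels
                )
                res = fit_furchgott(pairs_ee)
                r, occ50 = reserve_summary(fc, res)
                rows.append(
                    {
                        "assay_id": assay,
                        "agonist_id": agonist,
                        "k_a_nM": res.k_a * 1e9,
                        "k_a_ci_lo_nM": res.k_a_ci[0] * 1e9,
                        "k_a_ci_hi_nM": res.k_a_ci[1] * 1e9,
                        "q_functional": res.q_functional,
                        "q_ci_lo": res.q_ci[0],
                        "q_ci_hi": res.q_ci[1],
                        "ka_over_ec50": r,
                        "occupancy_at_half_max_pct": occ50,
                    }
                )
            furch = pd.DataFrame(rows)
            emit("furchgott_table", furch)
        except Exception as exc:
            raise PipelineError("furchgott", exc) from exc

    desens = None
    if config.traces_dir:
        try:
            results = [
                fit_decay(read_trace(p))
                for p in sorted(Path(config.traces_dir).glob("*.csv"))
            ]
            desens = pd.DataFrame(
                [
                    {
                        "cell_id": r.cell_id,
                        "drug_id": r.drug_id,
                        "normalised_peak": r.normalised_peak,
                        "plateau": r.plateau,
                        "rate_k_per_s": r.rate_k,
                        "percent_desens_10min": r.percent_desens_10min,
                    }
                    for r in results
                ]
            )
            groups = {
                drug: grp["percent_desens_10min"].to_numpy()
                for drug, grp in desens.groupby("drug_id")
            }
            if len(groups) >= 3 and config.reference in groups:
                cmp = compare_desens(groups, config.reference, alpha=config.alpha)
                desens["p_adjusted"] = desens["drug_id"].map(
                    lambda d: cmp.p_adjusted.get(d)
                )
            emit("desens_table", desens)
        except Exception as exc:
            raise PipelineError("desens", exc) from exc

    if out_dir is not None:
        log = {
            "gpcrbias_version": __version__,
            "seed": config.seed,
            "reference": config.reference,
            "pathway_pairs": [list(p) for p in pairs],
            "biased_agonists": biased,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "tables": sorted(written),
        }
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")

    return ReportBundle(
        potency=written.get("potency_table"),
        transduction=written.get("transduction_ratios"),
        bias=bias,
        furchgott=furch,
        desens=desens,
        biased_agonists=biased,
        out_dir=out_dir,
    )
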