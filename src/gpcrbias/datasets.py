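"""Typed containers and delimited-text IO for concentration-response data.

The interchange format is long-format comma-separated text with a mandatory
header row and columns::

    assay_id, agonist_id, treatment_arm, replicate, conc_M, response

Concentrations are molar (scientific notation welcome); ``treatment_arm`` is
``control`` or ``depleted`` (the latter for irreversible-antagonist
pretreated arms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENT_ARMS = ("control", "depleted")

REQUIRED_COLUMNS = [
    "assay_id",
    "agonist_id",
    "treatment_arm",
    "replicate",
    "conc_M",
    "response",
]


class DatasetError(ValueError):
    """Malformed concentration-response input."""


@dataclass
class ConcResponseDataset:
    """Replicate-resolved concentration-response observations for one
    agonist in one assay under one treatment arm.

    ``observations`` holds columns ``replicate`` (int, contiguous from 1),
    ``conc_M`` (molar, strictly positive), ``response`` (assay units) and
    ``excluded`` (bool; flagged points are retained but ignored by fits).
    """

    assay_id: str
    agonist_id: str
    observations: pd.DataFrame
    treatment_arm: str = "control"

    def __post_init__(self) -> None:
        obs = self.observations
        if not isinstance(obs, pd.DataFrame):
            obs = pd.DataFrame(
                obs, columns=["replicate", "conc_M", "response"]
            )
        obs = obs.copy()
        if "excluded" not in obs.columns:
            obs["excluded"] = False
        missing = {"replicate", "conc_M", "response"} - set(obs.columns)
        if missing:
            raise DatasetError(f"observations missing columns: {sorted(missing)}")
        if self.treatment_arm not in TREATMENT_ARMS:
            raise DatasetError(
                f"treatment_arm must be one of {TREATMENT_ARMS}, "
                f"got {self.treatment_arm!r}"
            )
        obs["replicate"] = obs["replicate"].astype(int)
        obs["conc_M"] = obs["conc_M"].astype(float)
        obs["response"] = obs["response"].astype(float)
        obs["excluded"] = obs["excluded"].astype(bool)
        if (obs["conc_M"] <= 0).any():
            bad = obs.index[obs["conc_M"] <= 0].tolist()
            raise DatasetError(f"non-positive concentrations at rows {bad}")
        reps = np.sort(obs["replicate"].unique())
        if len(reps) and not np.array_equal(reps, np.arange(1, len(reps) + 1)):
            raise DatasetError(
                f"replicate indices must be contiguous from 1, got {reps.tolist()}"
            )
        self.observations = obs.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------

    @property
    def n_replicates(self) -> int:
        return int(self.observations["replicate"].max()) if len(self.observations) else 0

    @property
    def included(self) -> pd.DataFrame:
        """Observations not flagged as outliers."""
        return self.observations[~self.observations["excluded"]]

    def replicate(self, index: int) -> pd.DataFrame:
        return self.included[self.included["replicate"] == index]

    def log_conc(self) -> np.ndarray:
        return np.log10(self.included["conc_M"].to_numpy())

    def key(self) -> tuple[str, str, str]:
        return (self.assay_id, self.agonist_id, self.treatment_arm)

    def with_observations(self, obs: pd.DataFrame) -> "ConcResponseDataset":
        return replace(self, observations=obs)

    def to_frame(self) -> pd.DataFrame:
        out = self.observations.copy()
        out.insert(0, "assay_id", self.assay_id)
        out.insert(1, "agonist_id", self.agonist_id)
        out.insert(2, "treatment_arm", self.treatment_arm)
        return out


@dataclass
class CurrentTrace:
    """A whole-cell current recording with its noradrenaline reference peak.

    ``times`` are seconds (strictly increasing); ``currents`` are pA.
    ``events`` mark drug applications as (label, time) pairs.
    """

    cell_id: str
    drug_id: str
    times: np.ndarray
    currents: np.ndarray
    na_peak_current: float
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.times.shape != self.currents.shape:
            raise DatasetError("times and currents must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise DatasetError("times must be strictly increasing")
        if not (self.na_peak_current > 0):
            raise DatasetError("na_peak_current must be positive")

    def application_time(self) -> float:
        """Time of the first drug-application event."""
        if not self.events:
            raise DatasetError(f"trace {self.cell_id}: no application events recorded")
        return min(t for _, t in self.events)


# -- delimited-text IO ----------------------------------------------------


def read_datasets(path) -> list[ConcResponseDataset]:
    """Read a long-format CSV into one dataset per (assay, agonist, arm).

    Raises :class:`DatasetError` naming the offending line for missing
    columns, non-positive concentrations, or duplicate
    (assay, agonist, arm, replicate, concentration) rows.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing required columns {missing}")
    # +2: header line plus 1-based numbering
    lines = df.index.to_numpy() + 2
    bad = lines[(df["conc_M"].astype(float) <= 0).to_numpy()]
    if bad.size:
        raise DatasetError(
            f"{path}: non-positive concentration on line(s) {bad.tolist()}"
        )
    key_cols = ["assay_id", "agonist_id", "treatment_arm", "replicate", "conc_M"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        raise DatasetError(
            f"{path}: duplicate (assay, agonist, arm, replicate, conc) rows "
            f"on line(s) {lines[dup.to_numpy()].tolist()}"
        )
    out = []
    for (assay, agonist, arm), grp in df.groupby(
        ["assay_id", "agonist_id", "treatment_arm"], sort=True
    ):
        obs = grp[["replicate", "conc_M", "response"]].reset_index(drop=True)
        if "excluded" in grp.columns:
            obs["excluded"] = grp["excluded"].reset_index(drop=True)
        out.append(
            ConcResponseDataset(
                assay_id=str(assay),
                agonist_id=str(agonist),
                treatment_arm=str(arm),
                observations=obs,
            )
        )
    return out


def write_datasets(datasets, path) -> None:
    """Write datasets back to the long-format CSV schema."""
    frames = [d.to_frame() for d in datasets]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace(path) -> CurrentTrace:
    """Read a per-cell trace file: ``# key: value`` header block, then a
    ``time_s,current_pA`` CSV body.  Application events are ``# application:
    LABEL TIME`` lines."""
    meta: dict[str, str] = {}
    events = []
    header_len = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_len += 1
            body = line[1:].strip()
            if ":" not in body:
                continue
            key, value = body.split(":", 1)
            key, value = key.strip(), value.strip()
            if key == "application":
                label, t = value.rsplit(None, 1)
                events.append((label, float(t)))
            else:
                meta[key] = value
    for key in ("cell_id", "drug", "na_peak_pA"):
        if key not in meta:
            raise DatasetError(f"{path}: trace header missing '{key}'")
    body_df = pd.read_csv(path, skiprows=header_len)
    if not {"time_s", "current_pA"} <= set(body_df.columns):
        raise DatasetError(f"{path}: trace body needs time_s and current_pA columns")
    return CurrentTrace(
        cell_id=meta["cell_id"],
        drug_id=meta["drug"],
        times=body_df["time_s"].to_numpy(),
        currents=body_df["current_pA"].to_numpy(),
        na_peak_current=float(meta["na_peak_pA"]),
        events=events,
    )


def write_trace(trace: CurrentTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cell_id: {trace.cell_id}\n")
        fh.write(f"# drug: {trace.drug_id}\n")
        fh.write(f"# na_peak_pA: {trace.na_peak_current:g}\n")
        for label, t in trace.events:
            fh.write(f"# application: {label} {t:g}\n")
        fh.write("time_s,current_pA\n")
        for t, i in zip(trace.times, trace.currents):
            fh.write(f"{t:.6g},{i:.8g}\n")
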