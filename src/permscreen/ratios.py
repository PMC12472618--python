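"""Permeability ratios and log-scale sufficient statistics.

The effect of an excipient on a drug's permeability is parameterized as the
permeability ratio PR = Papp' / Papp (treated over control). To control for
assay-level effects, the PR can be normalized by the PR of a co-dosed
high-permeability marker (minoxidil): nPR = PR_drug / PR_minoxidil.

Group-level inference runs on the log scale (geometric-mean-ratio
semantics), so each group is reduced to log-scale sufficient statistics
(n, mean of ln Papp, sample sd of ln Papp). When only printed summaries
(arithmetic mean, SEM, n) are available, the log-scale statistics are
reconstructed by lognormal moment matching:

    sd = SEM * sqrt(n);  CV = sd / mean
    sd_log  = sqrt(ln(1 + CV^2))
    mean_log = ln(mean) - sd_log^2 / 2

which is exact when the underlying replicates are lognormal with those
first two moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from permscreen.transport import InvalidInputError, PermeabilityRecord

__all__ = [
    "GroupSummary",
    "GroupLogStats",
    "RatioSample",
    "point_pr",
    "point_npr",
    "log_stats_from_replicates",
    "log_stats_from_summary",
    "npr_samples",
    "load_reference_summaries",
    "read_summary_csv",
]


@dataclass(frozen=True)
class GroupSummary:
    """Printed arithmetic summary for one (drug, treatment) group."""

    drug_id: str
    treatment_id: str
    n: int
    mean_papp: float
    sem_papp: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidInputError(f"n must be >= 2, got {self.n}")
        if not self.mean_papp > 0:
            raise InvalidInputError(f"mean_papp must be > 0, got {self.mean_papp}")
        if self.sem_papp < 0:
            raise InvalidInputError(f"sem_papp must be >= 0, got {self.sem_papp}")


@dataclass(frozen=True)
class GroupLogStats:
    """Log-scale sufficient statistics for one group.

    ``source`` records whether the statistics came from raw replicates or
    were reconstructed from an arithmetic summary by moment matching.
    """

    drug_id: str
    treatment_id: str
    n: int
    mean_log: float
    sd_log: float
    source: Literal["replicates", "reconstructed"] = "replicates"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidInputError(f"n must be >= 2, got {self.n}")
        if self.sd_log < 0:
            raise InvalidInputError(f"sd_log must be >= 0, got {self.sd_log}")


@dataclass(frozen=True)
class RatioSample:
    """Per-insert log-scale observation feeding the ratio CI.

    For the PR path the component is ln(papp); for the nPR path it is
    ln(papp_drug) - ln(papp_minoxidil) of the co-dosed pair on one insert.
    """

    drug_id: str
    treatment_id: str
    insert_id: str
    kind: Literal["PR", "nPR"]
    log_ratio_component: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_ratio_component):
            raise InvalidInputError("log_ratio_component must be finite")


def point_pr(treated: float, control: float) -> float:
    """Permeability ratio: treated mean (or geometric mean) over control."""
    if not treated > 0 or not control > 0:
        raise InvalidInputError(
            f"point_pr requires positive inputs, got treated={treated}, "
            f"control={control}"
        )
    return treated / control


def point_npr(pr_drug: float, pr_minoxidil: float) -> float:
    """Normalized permeability ratio: drug PR over the marker's PR."""
    if not pr_drug > 0 or not pr_minoxidil > 0:
        raise InvalidInputError(
            f"point_npr requires positive inputs, got pr_drug={pr_drug}, "
            f"pr_minoxidil={pr_minoxidil}"
        )
    return pr_drug / pr_minoxidil


def log_stats_from_replicates(
    values: Sequence[float],
    drug_id: str = "",
    treatment_id: str = "",
) -> GroupLogStats:
    """Log-scale mean and sample sd (divisor n-1) of positive replicates."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InvalidInputError(f"need at least 2 replicates, got {arr.size}")
    if not np.all(arr > 0):
        raise InvalidInputError("all replicate Papp values must be > 0 (log scale)")
    logs = np.log(arr)
    return GroupLogStats(
        drug_id=drug_id,
        treatment_id=treatment_id,
        n=int(arr.size),
        mean_log=float(logs.mean()),
        sd_log=float(logs.std(ddof=1)),
        source="replicates",
    )


def log_stats_from_summary(s: GroupSummary) -> GroupLogStats:
    """Reconstruct log-scale statistics from (mean, SEM, n) by lognormal
    moment matching.

    Exact when the replicates are lognormal with the stated arithmetic
    mean and standard deviation; SEM 0 degenerates to a point mass at the
    mean.
    """
    sd = s.sem_papp * math.sqrt(s.n)
    cv = sd / s.mean_papp
    sd_log = math.sqrt(math.log1p(cv * cv))
    mean_log = math.log(s.mean_papp) - 0.5 * sd_log * sd_log
    return GroupLogStats(
        drug_id=s.drug_id,
        treatment_id=s.treatment_id,
        n=s.n,
        mean_log=mean_log,
        sd_log=sd_log,
        source="reconstructed",
    )


def npr_samples(
    drug_records: Sequence[PermeabilityRecord],
    minoxidil_records: Sequence[PermeabilityRecord],
) -> list[RatioSample]:
    """Per-insert drug/marker log-ratios for the nPR path.

    The drug and the minoxidil marker are co-dosed on each insert, so the
    natural pairing is by insert id: each insert contributes one
    observation ln(papp_drug) - ln(papp_minoxidil). Downstream CIs treat
    these as the log-scale data.
    """
    drug_by_insert = {r.insert_id: r for r in drug_records}
    mino_by_insert = {r.insert_id: r for r in minoxidil_records}
    if len(drug_by_insert) != len(drug_records):
        raise InvalidInputError("duplicate insert ids among drug records")
    unpaired = sorted(
        set(drug_by_insert) ^ set(mino_by_insert)
    )
    if unpaired:
        raise InvalidInputError(f"unpaired inserts for nPR: {unpaired}")
    samples = []
    for insert_id in sorted(drug_by_insert):
        d, m = drug_by_insert[insert_id], mino_by_insert[insert_id]
        if not d.papp > 0 or not m.papp > 0:
            raise InvalidInputError(
                f"insert {insert_id}: non-positive papp in nPR pairing"
            )
        samples.append(
            RatioSample(
                drug_id=d.drug_id,
                treatment_id=d.treatment_id,
                insert_id=insert_id,
                kind="nPR",
                log_ratio_component=math.log(d.papp) - math.log(m.papp),
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Reference summary data

def read_summary_csv(path: str | Path) -> list[GroupSummary]:
    """Read a summary table: drug_id, treatment_id, mean_papp_1e6_cm_s,
    sem_1e6_cm_s, n. Values are in units of 1e-6 cm/s and converted to cm/s.
    """
    df = pd.read_csv(path)
    required = {"drug_id", "treatment_id", "mean_papp_1e6_cm_s", "sem_1e6_cm_s", "n"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    return [
        GroupSummary(
            drug_id=str(row.drug_id),
            treatment_id=str(row.treatment_id),
            n=int(row.n),
            mean_papp=float(row.mean_papp_1e6_cm_s) * 1e-6,
            sem_papp=float(row.sem_1e6_cm_s) * 1e-6,
        )
        for row in df.itertuples()
    ]


def load_reference_summaries() -> list[GroupSummary]:
    """The package's embedded MDCK-wt reference dataset: group mean Papp,
    SEM and n for six low-permeability drugs under a no-excipient control
    and nine common excipients (n = 3 inserts per group)."""
    with resources.as_file(
        resources.files("permscreen.data").joinpath("mdck_papp_summary.csv")
    ) as path:
        return read_summary_csv(path)
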