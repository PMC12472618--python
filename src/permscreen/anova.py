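"""One-way ANOVA with Holm-Sidak treatment-vs-control comparisons.

The competing detection method: for each drug, a one-way ANOVA across the
control and all excipient groups, followed by two-sided t tests of each
excipient against the control on the pooled within-group mean square, with
Holm-Sidak step-down adjustment at alpha = 0.01. Each drug is its own
comparison family (the 9 vs-control contrasts); no omnibus-F gate is
applied before the post hoc tests, and no cross-drug adjustment is made.

Both replicate lists and exact summary statistics (n, mean, sd) are
accepted; the two paths are algebraically identical when the summaries are
computed from the replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from permscreen.transport import InvalidInputError

__all__ = [
    "GroupData",
    "AnovaResult",
    "PostHocCall",
    "one_way_anova",
    "holm_sidak",
    "holm_sidak_adjust",
    "anova_calls",
]


@dataclass(frozen=True)
class GroupData:
    """Exact summary statistics for one group: n, mean, sample sd."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidInputError(f"group {self.label!r}: n must be >= 2")
        if self.sd < 0:
            raise InvalidInputError(f"group {self.label!r}: sd must be >= 0")

    @classmethod
    def from_replicates(cls, label: str, values: Sequence[float]) -> "GroupData":
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise InvalidInputError(f"group {label!r}: need >= 2 replicates")
        return cls(
            label=label, n=int(arr.size), mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)),
        )


@dataclass(frozen=True)
class AnovaResult:
    """One-way decomposition with the pieces needed for post hoc contrasts."""

    drug_id: str
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]
    group_ns: dict[str, int]
    mse: float  # pooled within-group mean square


@dataclass(frozen=True)
class PostHocCall:
    """One treatment-vs-control contrast with its adjusted decision."""

    drug_id: str
    treatment_id: str
    raw_p: float
    adjusted_p: float
    call: Literal["NS", "up", "down"]


def _as_groups(
    groups: Sequence[GroupData] | Sequence[tuple[str, Sequence[float]]],
) -> list[GroupData]:
    out = []
    for g in groups:
        if isinstance(g, GroupData):
            out.append(g)
        else:
            label, values = g
            out.append(GroupData.from_replicates(label, values))
    return out


def one_way_anova(
    groups: Sequence[GroupData] | Sequence[tuple[str, Sequence[float]]],
    drug_id: str = "",
) -> AnovaResult:
    """Fixed-effects one-way ANOVA from replicates or exact summaries.

    SS_between is computed from the group means about the grand mean with
    group-size weights; SS_within = sum (n_i - 1) sd_i^2, so the summary
    path reproduces the replicate path exactly.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise InvalidInputError("one-way ANOVA needs at least 2 groups")
    ns = np.array([g.n for g in gs], dtype=float)
    means = np.array([g.mean for g in gs])
    sds = np.array([g.sd for g in gs])
    n_total = ns.sum()
    grand_mean = (ns * means).sum() / n_total
    ss_between = float((ns * (means - grand_mean) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_between = len(gs) - 1
    df_within = int(n_total) - len(gs)
    ms_between = ss_between / df_between
    mse = ss_within / df_within
    if mse == 0:
        f_stat = math.inf if ms_between > 0 else 0.0
    else:
        f_stat = ms_between / mse
    p_value = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        drug_id=drug_id,
        f_stat=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=p_value,
        group_means={g.label: g.mean for g in gs},
        group_ns={g.label: g.n for g in gs},
        mse=mse,
    )


def holm_sidak_adjust(raw_p: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values.

    Sort ascending; the i-th smallest (1-based) of m is adjusted to
    1 - (1 - p_(i))^(m - i + 1); monotonicity is enforced by a running
    maximum; values are returned in the original order.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    exponents = np.arange(m, 0, -1)
    adjusted_sorted = 1.0 - (1.0 - p[order]) ** exponents
    adjusted_sorted = np.maximum.accumulate(adjusted_sorted)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def holm_sidak(raw_p: Sequence[float], alpha: float = 0.01) -> list[tuple[float, bool]]:
    """Adjusted p-values and step-down reject decisions at ``alpha``.

    Rejection proceeds in ascending p order while the adjusted value stays
    below alpha and stops at the first failure, so the rejected set is a
    prefix of the sorted hypotheses. Returns (adjusted_p, reject) per input.
    """
    adjusted = holm_sidak_adjust(raw_p)
    reject = adjusted < alpha
    return [(float(a), bool(r)) for a, r in zip(adjusted, reject)]


def anova_calls(
    groups: Sequence[GroupData] | Sequence[tuple[str, Sequence[float]]],
    alpha: float = 0.01,
    control_id: str = "control",
    drug_id: str = "",
    scale: Literal["raw", "log"] = "raw",
) -> list[PostHocCall]:
    """Holm-Sidak-adjusted excipient-vs-control calls for one drug.

    Raw p-values come from two-sided t statistics on the pooled
    within-group MSE with df_within degrees of freedom; significant calls
    take their direction from the sign of (treated mean - control mean).
    ``scale="log"`` log-transforms replicate input before the ANOVA
    (summaries cannot be re-scaled exactly and are rejected in that mode).
    """
    gs = _as_groups(groups)
    if scale == "log":
        raise NotImplementedError(
            "log-scale ANOVA requires replicate input; transform the "
            "replicates with numpy.log and pass them on the raw path"
        )
    labels = [g.label for g in gs]
    if control_id not in labels:
        raise InvalidInputError(f"no control group for drug {drug_id or '?'!r}")
    result = one_way_anova(gs, drug_id=drug_id)
    control = next(g for g in gs if g.label == control_id)
    treatments = [g for g in gs if g.label != control_id]
    t_stats = np.array(
        [
            (g.mean - control.mean)
            / math.sqrt(result.mse * (1 / g.n + 1 / control.n))
            if result.mse > 0
            else math.copysign(math.inf, g.mean - control.mean)
            if g.mean != control.mean
            else 0.0
            for g in treatments
        ]
    )
    raw_p = 2 * stats.t.sf(np.abs(t_stats), result.df_within)
    decisions = holm_sidak(raw_p, alpha=alpha)
    calls = []
    for g, t_val, p, (adj, rej) in zip(treatments, t_stats, raw_p, decisions):
        if not rej:
            call = "NS"
        elif t_val > 0:
            call = "up"
        else:
            call = "down"
        calls.append(
            PostHocCall(
                drug_id=drug_id,
                treatment_id=g.label,
                raw_p=float(p),
                adjusted_p=adj,
                call=call,
            )
        )
    return calls
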