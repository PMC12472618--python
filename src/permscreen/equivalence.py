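"""Parallel-design CI90 on the geometric mean ratio and effect calls.

Bioequivalence-style inference for a two-group (treated vs control)
comparison of lognormal permeability data. With log-scale group statistics
(n', mean', sd') and (n, mean, sd), the two-sided 90% confidence interval
for the geometric mean ratio is the classical pooled-variance t interval
on the difference of log means, exponentiated:

    df        = n' + n - 2
    sigma^2   = ((n'-1) sd'^2 + (n-1) sd^2) / df
    halfwidth = t_{1-alpha/2, df} * sqrt(A * sigma^2 * (1/n' + 1/n))
    CI        = exp(mean' - mean -/+ halfwidth)

A is a design constant: 1 for a parallel design (independent groups, the
default here), 0.5 for a cross-over design. The interval is compared to
the regulatory limits [0.80, 1.25]:

    NE  (no effect)       CI entirely within the limits
    R   (repressive)      CI extends below 0.8 only
    E   (enhancer)        CI extends above 1.25 only
    NC  (non-conclusive)  CI extends beyond both limits

A bound lying exactly on a limit counts as within: "extends below/above"
means strict crossing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from scipy import stats

from permscreen.ratios import GroupLogStats, GroupSummary, log_stats_from_summary
from permscreen.transport import InvalidInputError

__all__ = [
    "EquivalenceConfig",
    "RatioEstimate",
    "EffectCall",
    "DegenerateVarianceError",
    "hauschke_ci",
    "classify_effect",
    "classify_all",
    "call_counts",
]


class DegenerateVarianceError(ValueError):
    """Both groups have zero log-scale variance; the CI collapses to a point."""


@dataclass(frozen=True)
class EquivalenceConfig:
    """Settings for the GMR confidence interval and its classification.

    ``alpha`` is the two-sided error (0.10 gives a CI90); ``design_constant``
    is 1 for parallel and 0.5 for cross-over designs; ``lower_limit`` and
    ``upper_limit`` are the equivalence limits (0.80-1.25 by default);
    ``allow_degenerate`` permits a zero-width point interval when both
    groups have zero log-variance instead of raising.
    """

    alpha: float = 0.10
    design_constant: float = 1.0
    lower_limit: float = 0.8
    upper_limit: float = 1.25
    allow_degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InvalidInputError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 < self.lower_limit < 1 < self.upper_limit:
            raise InvalidInputError(
                "limits must satisfy 0 < lower < 1 < upper, got "
                f"[{self.lower_limit}, {self.upper_limit}]"
            )
        if self.design_constant <= 0:
            raise InvalidInputError("design_constant must be > 0")


@dataclass(frozen=True)
class RatioEstimate:
    """A geometric mean ratio with its CI90 and provenance."""

    drug_id: str
    treatment_id: str
    kind: Literal["PR", "nPR"]
    gmr: float
    ci_low: float
    ci_high: float
    df: int
    source: Literal["replicates", "reconstructed"]

    def __post_init__(self) -> None:
        if not 0 < self.ci_low <= self.gmr <= self.ci_high:
            raise InvalidInputError(
                f"require 0 < ci_low <= gmr <= ci_high, got "
                f"({self.ci_low}, {self.gmr}, {self.ci_high})"
            )


@dataclass(frozen=True)
class EffectCall:
    """Four-way classification of one excipient-drug comparison."""

    call: Literal["NE", "R", "E", "NC"]
    basis: RatioEstimate


def hauschke_ci(
    treated: GroupLogStats,
    control: GroupLogStats,
    cfg: EquivalenceConfig = EquivalenceConfig(),
    kind: Literal["PR", "nPR"] = "PR",
) -> RatioEstimate:
    """Pooled-variance t interval for the GMR of two independent groups.

    The one-sided t quantile at level 1 - alpha/2 and df = n' + n - 2 is
    computed from scipy, never hard-coded (for the default CI90 with
    n = 3 per arm this is t(0.95, 4) ~ 2.13185).
    """
    df = treated.n + control.n - 2
    if df <= 0:
        raise InvalidInputError(f"df must be > 0, got {df}")
    pooled_var = (
        (treated.n - 1) * treated.sd_log**2 + (control.n - 1) * control.sd_log**2
    ) / df
    if pooled_var == 0 and not cfg.allow_degenerate:
        raise DegenerateVarianceError(
            "both groups have zero log-scale variance; pass "
            "allow_degenerate=True for a point interval"
        )
    t_quantile = stats.t.ppf(1 - cfg.alpha / 2, df)
    log_diff = treated.mean_log - control.mean_log
    halfwidth = t_quantile * math.sqrt(
        cfg.design_constant * pooled_var * (1 / treated.n + 1 / control.n)
    )
    source = (
        "reconstructed"
        if "reconstructed" in (treated.source, control.source)
        else "replicates"
    )
    return RatioEstimate(
        drug_id=treated.drug_id or control.drug_id,
        treatment_id=treated.treatment_id,
        kind=kind,
        gmr=math.exp(log_diff),
        ci_low=math.exp(log_diff - halfwidth),
        ci_high=math.exp(log_diff + halfwidth),
        df=df,
        source=source,
    )


def classify_effect(
    r: RatioEstimate, cfg: EquivalenceConfig = EquivalenceConfig()
) -> EffectCall:
    """Classify a ratio estimate against the equivalence limits.

    Exactly one of NE / R / E / NC is returned; bounds exactly on a limit
    count as within the limits.
    """
    below = r.ci_low < cfg.lower_limit
    above = r.ci_high > cfg.upper_limit
    if below and above:
        call = "NC"
    elif below:
        call = "R"
    elif above:
        call = "E"
    else:
        call = "NE"
    return EffectCall(call=call, basis=r)


def classify_all(
    groups: Sequence[GroupLogStats | GroupSummary],
    cfg: EquivalenceConfig = EquivalenceConfig(),
    control_id: str = "control",
    kind: Literal["PR", "nPR"] = "PR",
) -> list[EffectCall]:
    """CI90 effect calls for every excipient of one drug versus its control.

    Accepts log-scale statistics or arithmetic summaries (reconstructed on
    the fly); the control group is never compared to itself. Raises when
    the drug has no control group or the groups span several drugs.
    """
    stats_list = [
        log_stats_from_summary(g) if isinstance(g, GroupSummary) else g
        for g in groups
    ]
    drug_ids = {g.drug_id for g in stats_list}
    if len(drug_ids) > 1:
        raise InvalidInputError(f"groups span several drugs: {sorted(drug_ids)}")
    control = [g for g in stats_list if g.treatment_id == control_id]
    if not control:
        drug = next(iter(drug_ids), "?")
        raise InvalidInputError(f"no control group for drug {drug!r}")
    (control_stats,) = control
    calls = []
    for g in stats_list:
        if g.treatment_id == control_id:
            continue
        estimate = hauschke_ci(g, control_stats, cfg, kind=kind)
        calls.append(classify_effect(estimate, cfg))
    return calls


def call_counts(calls: Sequence[EffectCall]) -> Mapping[str, int]:
    """Tally of {E, R, NE, NC} over a list of effect calls."""
    out = {"E": 0, "R": 0, "NE": 0, "NC": 0}
    for c in calls:
        out[c.call] += 1
    return out
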