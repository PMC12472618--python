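"""Seeded synthetic permeability experiments and Monte-Carlo studies.

The generator emulates the statistical structure the analysis assumes: for
each (drug, treatment) group, replicate Papp values are lognormal,

    papp = exp( N( ln(geomean * multiplier), sd_log^2 ) ),

with n = 3 inserts per group by default, a co-dosed high-permeability
marker (minoxidil, control geometric mean inside 0.92-4.58 x 10^-6 cm/s)
and a low-permeability integrity marker (atenolol, geometric mean below
0.5 x 10^-6 cm/s) sharing each insert. True excipient effect sizes are the
per-drug multipliers (true GMRs); marker multipliers default to 1 so the
nPR and PR paths coincide as a pipeline identity.

The Monte-Carlo operations (CI coverage, per-method sensitivity,
familywise error of the ANOVA screen) use vectorised numpy internals for
speed; their agreement with the per-experiment pipeline path is asserted
in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from permscreen.transport import InvalidInputError

__all__ = [
    "DrugSpec",
    "ExcipientSpec",
    "SyntheticDesign",
    "generate_experiment",
    "experiment_to_transport_frame",
    "coverage_sim",
    "sensitivity_sim",
    "familywise_error_sim",
    "default_design",
]

MINOXIDIL_RANGE = (0.92e-6, 4.58e-6)


@dataclass(frozen=True)
class DrugSpec:
    """Control-arm law for one model drug: geometric mean Papp and log-sd."""

    drug_id: str
    control_geomean: float
    sd_log: float

    def __post_init__(self) -> None:
        if not self.control_geomean > 0:
            raise InvalidInputError(f"{self.drug_id}: control_geomean must be > 0")
        if self.sd_log < 0:
            raise InvalidInputError(f"{self.drug_id}: sd_log must be >= 0")


@dataclass(frozen=True)
class ExcipientSpec:
    """True multiplicative effects of one excipient.

    ``drug_multipliers`` maps drug_id -> true GMR on that drug's Papp
    (missing drugs default to 1, i.e. no effect); ``minoxidil_multiplier``
    and ``atenolol_multiplier`` act on the markers, the latter as an
    optional integrity-breach dial to exercise the QC flags.
    """

    excipient_id: str
    drug_multipliers: Mapping[str, float] = field(default_factory=dict)
    minoxidil_multiplier: float = 1.0
    atenolol_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for v in (
            *self.drug_multipliers.values(),
            self.minoxidil_multiplier,
            self.atenolol_multiplier,
        ):
            if not v > 0:
                raise InvalidInputError(
                    f"{self.excipient_id}: multipliers must be > 0"
                )

    def multiplier_for(self, drug_id: str) -> float:
        return float(self.drug_multipliers.get(drug_id, 1.0))


@dataclass(frozen=True)
class SyntheticDesign:
    """Full factorial design: drugs x (control + excipients), co-dosed markers."""

    drugs: Sequence[DrugSpec]
    excipients: Sequence[ExcipientSpec]
    n_replicates: int = 3
    minoxidil_geomean: float = 2.0e-6
    minoxidil_sd_log: float = 0.3
    atenolol_geomean: float = 0.3e-6
    atenolol_sd_log: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise InvalidInputError("n_replicates must be >= 2")
        lo, hi = MINOXIDIL_RANGE
        if not lo <= self.minoxidil_geomean <= hi:
            raise InvalidInputError(
                f"minoxidil_geomean must lie in [{lo}, {hi}] cm/s"
            )
        if not 0 < self.atenolol_geomean < 0.5e-6:
            raise InvalidInputError("atenolol_geomean must lie in (0, 0.5e-6) cm/s")
        if min(self.minoxidil_sd_log, self.atenolol_sd_log) < 0:
            raise InvalidInputError("marker sd_log values must be >= 0")


def generate_experiment(d: SyntheticDesign) -> pd.DataFrame:
    """Sample one full experiment as a tidy replicate table.

    Returns one row per (drug, treatment, insert, analyte) with columns
    ``drug_id, treatment_id, insert_id, analyte, papp``; the drug, the
    minoxidil marker and the atenolol marker share each insert id.
    Identical designs (including seed) give identical tables.
    """
    rng = np.random.default_rng(d.seed)
    treatments: list[tuple[str, ExcipientSpec | None]] = [("control", None)]
    treatments += [(e.excipient_id, e) for e in d.excipients]
    rows = []
    for drug in d.drugs:
        for treatment_id, exc in treatments:
            drug_mult = exc.multiplier_for(drug.drug_id) if exc else 1.0
            mino_mult = exc.minoxidil_multiplier if exc else 1.0
            aten_mult = exc.atenolol_multiplier if exc else 1.0
            for rep in range(1, d.n_replicates + 1):
                insert_id = f"{drug.drug_id}:{treatment_id}:{rep}"
                specs = (
                    ("drug", drug.control_geomean * drug_mult, drug.sd_log),
                    ("minoxidil", d.minoxidil_geomean * mino_mult, d.minoxidil_sd_log),
                    ("atenolol", d.atenolol_geomean * aten_mult, d.atenolol_sd_log),
                )
                for analyte, geomean, sd_log in specs:
                    papp = float(
                        np.exp(rng.normal(math.log(geomean), sd_log))
                    )
                    rows.append(
                        {
                            "drug_id": drug.drug_id,
                            "treatment_id": treatment_id,
                            "insert_id": insert_id,
                            "analyte": analyte,
                            "papp": papp,
                        }
                    )
    return pd.DataFrame(rows)


def experiment_to_transport_frame(
    experiment: pd.DataFrame,
    donor_conc_uM: float = 100.0,
    marker_donor_conc_uM: float = 10.0,
    receiver_volume_mL: float = 1.5,
    area_cm2: float = 1.12,
    duration_s: float = 7200.0,
) -> pd.DataFrame:
    """Express a simulated experiment as raw transwell measurements.

    Inverts the endpoint Papp formula to back out the receiver
    concentration each Papp implies under the standard assay geometry
    (donor 100 uM for the drug, 10 uM for the co-dosed markers), producing
    the replicate CSV schema the transport reader consumes.
    """
    donor = np.where(
        experiment["analyte"].to_numpy() == "drug", donor_conc_uM, marker_donor_conc_uM
    )
    receiver = (
        experiment["papp"].to_numpy()
        * duration_s
        * area_cm2
        * donor
        / receiver_volume_mL
    )
    return pd.DataFrame(
        {
            "drug_id": experiment["drug_id"],
            "treatment_id": experiment["treatment_id"],
            "insert_id": experiment["insert_id"],
            "analyte": experiment["analyte"],
            "receiver_conc_uM": receiver,
            "donor_conc_uM": donor,
            "receiver_volume_mL": receiver_volume_mL,
            "area_cm2": area_cm2,
            "duration_s": duration_s,
        }
    )


# ---------------------------------------------------------------------------
# Monte-Carlo studies


def _log_group_draws(
    rng: np.random.Generator, shape: tuple[int, ...], mu: float, sd_log: float
) -> np.ndarray:
    return rng.normal(mu, sd_log, size=shape)


def coverage_sim(
    n_sims: int = 10_000,
    n_per_arm: int = 3,
    sd_log: float = 0.3,
    true_gmr: float = 1.0,
    alpha: float = 0.10,
    seed: int = 0,
) -> tuple[float, float]:
    """Empirical coverage of the parallel-design GMR confidence interval.

    Simulates two-arm lognormal experiments with the given true geometric
    mean ratio and common log-scale sd, computes the pooled-variance t
    interval per experiment, and returns the fraction of intervals
    containing the true GMR together with its Monte-Carlo standard error.
    """
    if n_sims < 1:
        raise InvalidInputError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    mu_t = math.log(true_gmr)
    treated = _log_group_draws(rng, (n_sims, n_per_arm), mu_t, sd_log)
    control = _log_group_draws(rng, (n_sims, n_per_arm), 0.0, sd_log)
    df = 2 * n_per_arm - 2
    t_q = stats.t.ppf(1 - alpha / 2, df)
    diff = treated.mean(axis=1) - control.mean(axis=1)
    pooled = (treated.var(axis=1, ddof=1) + control.var(axis=1, ddof=1)) / 2
    half = t_q * np.sqrt(pooled * (2 / n_per_arm))
    covered = (diff - half <= mu_t) & (mu_t <= diff + half)
    coverage = float(covered.mean())
    mc_se = math.sqrt(coverage * (1 - coverage) / n_sims) if n_sims > 1 else 0.0
    return coverage, mc_se


def _family_draws(
    rng: np.random.Generator,
    n_sims: int,
    n_excipients: int,
    n_per_arm: int,
    sd_log: float,
    log_gmr: float,
) -> np.ndarray:
    """Log-Papp draws, shape (n_sims, 1 + n_excipients, n): control first."""
    mus = np.full(1 + n_excipients, log_gmr)
    mus[0] = 0.0
    return rng.normal(mus[None, :, None], sd_log, size=(n_sims, 1 + n_excipients, n_per_arm))


def _holm_sidak_reject_matrix(raw_p: np.ndarray, alpha: float) -> np.ndarray:
    """Row-wise Holm-Sidak step-down rejections for a (sims, m) p matrix."""
    m = raw_p.shape[1]
    order = np.argsort(raw_p, axis=1, kind="stable")
    sorted_p = np.take_along_axis(raw_p, order, axis=1)
    exponents = np.arange(m, 0, -1)[None, :]
    adjusted = np.maximum.accumulate(1.0 - (1.0 - sorted_p) ** exponents, axis=1)
    reject_sorted = adjusted < alpha
    reject = np.empty_like(reject_sorted)
    np.put_along_axis(reject, order, reject_sorted, axis=1)
    return reject


def _family_decisions(
    logs: np.ndarray,
    alpha_ci: float,
    alpha_anova: float,
    limits: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-excipient CI E/R calls and ANOVA rejections for family draws.

    ``logs`` has shape (n_sims, 1 + m, n) with the control group first.
    The CI path compares each excipient to the control with the
    two-group pooled-variance interval (df = 2n - 2) on the log scale and
    flags E or R (interval strictly past one limit, inside the other).
    The ANOVA path pools the within-group MSE over all groups on the raw
    scale, forms the m vs-control t contrasts (df = (1+m)(n-1)) and
    applies Holm-Sidak at ``alpha_anova``.
    """
    n_sims, n_groups, n = logs.shape
    m = n_groups - 1
    lower, upper = limits
    # --- CI path (log scale, pairwise vs control)
    means = logs.mean(axis=2)
    vars_ = logs.var(axis=2, ddof=1)
    diff = means[:, 1:] - means[:, [0]]
    pooled = (vars_[:, 1:] + vars_[:, [0]]) / 2
    df_pair = 2 * n - 2
    t_q = stats.t.ppf(1 - alpha_ci / 2, df_pair)
    half = t_q * np.sqrt(pooled * (2 / n))
    lo, hi = np.exp(diff - half), np.exp(diff + half)
    below, above = lo < lower, hi > upper
    ci_detect = (below & ~above) | (above & ~below)  # R or E, not NC/NE
    # --- ANOVA path (raw scale, pooled MSE over all groups)
    raw = np.exp(logs)
    raw_means = raw.mean(axis=2)
    raw_vars = raw.var(axis=2, ddof=1)
    df_within = n_groups * (n - 1)
    mse = raw_vars.mean(axis=1)
    se = np.sqrt(mse[:, None] * (2 / n))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = (raw_means[:, 1:] - raw_means[:, [0]]) / se
    t_stats = np.nan_to_num(t_stats, nan=0.0)
    raw_p = 2 * stats.t.sf(np.abs(t_stats), df_within)
    anova_detect = _holm_sidak_reject_matrix(raw_p, alpha_anova)
    return ci_detect, anova_detect


def sensitivity_sim(
    effect_grid: Sequence[float],
    sd_log_grid: Sequence[float] = (0.3,),
    n_per_arm: int = 3,
    n_excipients: int = 9,
    n_sims: int = 2_000,
    alpha_ci: float = 0.10,
    alpha_anova: float = 0.01,
    limits: tuple[float, float] = (0.8, 1.25),
    seed: int = 0,
) -> pd.DataFrame:
    """Detection rate of each method over a grid of true effect sizes.

    For each (true GMR, sd_log) cell, simulates experiments with a control
    arm and ``n_excipients`` excipient arms all carrying that true GMR
    (preserving the 9-contrast family structure of the screen), and
    reports the probability that the CI90 path calls E or R and that the
    Holm-Sidak-adjusted vs-control test rejects. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sd_log in sd_log_grid:
        for gmr in effect_grid:
            logs = _family_draws(
                rng, n_sims, n_excipients, n_per_arm, sd_log, math.log(gmr)
            )
            ci_detect, anova_detect = _family_decisions(
                logs, alpha_ci, alpha_anova, limits
            )
            rows.append(
                {
                    "true_gmr": gmr,
                    "sd_log": sd_log,
                    "ci_rate": float(ci_detect.mean()),
                    "anova_rate": float(anova_detect.mean()),
                    "n_sims": n_sims,
                }
            )
    return pd.DataFrame(rows)


def familywise_error_sim(
    n_sims: int = 10_000,
    n_excipients: int = 9,
    n_per_arm: int = 3,
    sd_log: float = 0.3,
    alpha: float = 0.01,
    seed: int = 0,
) -> tuple[float, float]:
    """Familywise error of the ANOVA/Holm-Sidak screen under the null.

    All groups share one lognormal law; returns the fraction of simulated
    families with at least one rejection, and its Monte-Carlo SE.
    """
    rng = np.random.default_rng(seed)
    logs = _family_draws(rng, n_sims, n_excipients, n_per_arm, sd_log, 0.0)
    _, anova_detect = _family_decisions(logs, 0.10, alpha, (0.8, 1.25))
    fwer = float(anova_detect.any(axis=1).mean())
    mc_se = math.sqrt(max(fwer * (1 - fwer), alpha * (1 - alpha)) / n_sims)
    return fwer, mc_se


def default_design(seed: int = 0) -> SyntheticDesign:
    """A design calibrated to the package's embedded reference dataset.

    Control geometric means and log-scale sds per drug, and per-cell true
    GMRs, are taken from lognormal moment matching of the reference
    summary table (six drugs, nine excipients, n = 3), so the simulated
    experiments reproduce the study conditions the analysis was built for.
    Marker multipliers default to 1 (no marker effect).
    """
    from permscreen.ratios import load_reference_summaries, log_stats_from_summary

    summaries = load_reference_summaries()
    stats_by = {(s.drug_id, s.treatment_id): log_stats_from_summary(s) for s in summaries}
    drug_ids = sorted({s.drug_id for s in summaries})
    excipient_ids = sorted(
        {s.treatment_id for s in summaries if s.treatment_id != "control"}
    )
    drugs = [
        DrugSpec(
            drug_id=d,
            control_geomean=math.exp(stats_by[(d, "control")].mean_log),
            sd_log=stats_by[(d, "control")].sd_log,
        )
        for d in drug_ids
    ]
    excipients = [
        ExcipientSpec(
            excipient_id=e,
            drug_multipliers={
                d: math.exp(
                    stats_by[(d, e)].mean_log - stats_by[(d, "control")].mean_log
                )
                for d in drug_ids
            },
        )
        for e in excipient_ids
    ]
    return SyntheticDesign(drugs=drugs, excipients=excipients, seed=seed)
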