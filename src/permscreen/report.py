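"""Effect matrices, frequency tallies, consensus counts and the pipeline.

Assembles the per-drug CI90 and ANOVA calls into the screening report: an
excipient x drug grid of paired calls, per-drug absolute frequencies of
each effect type per method, and a per-excipient consensus count (the
number of drugs on which the two methods agree, with E matching "up", R
matching "down", and NE or NC matching "not significant").
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from permscreen import anova as _anova
from permscreen import equivalence as _eq
from permscreen import ratios as _ratios
from permscreen import transport as _transport
from permscreen.transport import InvalidInputError

__all__ = [
    "EffectMatrix",
    "PipelineConfig",
    "build_effect_matrix",
    "tally_frequencies",
    "consensus_count",
    "run_pipeline",
]

REPORT_SCHEMA_VERSION = 1

#: CI-call / ANOVA-call pairs counted as agreement.
_AGREEMENT = {
    ("E", "up"),
    ("R", "down"),
    ("NE", "NS"),
    ("NC", "NS"),
}


@dataclass
class EffectMatrix:
    """Excipient x drug grid of paired (CI90 call, ANOVA call)."""

    metric: Literal["PR", "nPR"]
    drugs: list[str]
    excipients: list[str]
    ci_grid: dict[tuple[str, str], str] = field(default_factory=dict)
    anova_grid: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for grid in (self.ci_grid, self.anova_grid):
            for (exc, drug) in grid:
                if exc not in self.excipients or drug not in self.drugs:
                    raise InvalidInputError(
                        f"grid cell ({exc}, {drug}) outside the declared axes"
                    )

    def consensus(self) -> dict[str, int]:
        """Per-excipient count of drugs on which the two methods agree."""
        return {
            exc: consensus_count(
                [self.ci_grid[(exc, d)] for d in self.drugs],
                [self.anova_grid[(exc, d)] for d in self.drugs],
            )
            for exc in self.excipients
        }


def build_effect_matrix(
    ci_calls: Mapping[str, Sequence[_eq.EffectCall]],
    anova_calls: Mapping[str, Sequence[_anova.PostHocCall]],
    metric: Literal["PR", "nPR"] = "PR",
) -> EffectMatrix:
    """Assemble the grid from per-drug call lists (keyed by drug id)."""
    drugs = sorted(ci_calls)
    if sorted(anova_calls) != drugs:
        raise InvalidInputError("CI and ANOVA call sets cover different drugs")
    excipients = sorted({c.basis.treatment_id for d in drugs for c in ci_calls[d]})
    matrix = EffectMatrix(metric=metric, drugs=drugs, excipients=excipients)
    for d in drugs:
        for c in ci_calls[d]:
            matrix.ci_grid[(c.basis.treatment_id, d)] = c.call
        for a in anova_calls[d]:
            matrix.anova_grid[(a.treatment_id, d)] = a.call
    missing = [
        (e, d)
        for e in excipients
        for d in drugs
        if (e, d) not in matrix.ci_grid or (e, d) not in matrix.anova_grid
    ]
    if missing:
        raise InvalidInputError(f"incomplete effect grid, missing cells: {missing}")
    return matrix


def tally_frequencies(matrix: EffectMatrix) -> pd.DataFrame:
    """Absolute frequency of each effect type per drug and method.

    Rows are (method, effect) with effects "up", "down", "none"; columns
    are the drugs plus a "total" column (the grand per-method tallies).
    CI90 calls map E -> up, R -> down, NE/NC -> none; ANOVA calls map
    up/down/NS accordingly.
    """
    ci_map = {"E": "up", "R": "down", "NE": "none", "NC": "none"}
    anova_map = {"up": "up", "down": "down", "NS": "none"}
    rows = {}
    for method, grid, mapping in (
        ("CI90", matrix.ci_grid, ci_map),
        ("ANOVA", matrix.anova_grid, anova_map),
    ):
        for effect in ("up", "down", "none"):
            counts = {
                d: sum(
                    1
                    for e in matrix.excipients
                    if mapping[grid[(e, d)]] == effect
                )
                for d in matrix.drugs
            }
            counts["total"] = sum(counts.values())
            rows[(method, effect)] = counts
    df = pd.DataFrame(rows).T
    df.index.names = ["method", "effect"]
    return df


def consensus_count(ci_calls: Sequence[str], anova_calls: Sequence[str]) -> int:
    """Number of positions where the CI90 and ANOVA calls agree.

    Accepts raw call labels; a CI call agrees with "up"/"down" only as
    E/R, while both NE and NC agree with NS (all three render as "no
    called effect"). CI-vs-CI or ANOVA-vs-ANOVA vectors are also accepted
    (identity agreement), so a method always fully agrees with itself.
    """
    if len(ci_calls) != len(anova_calls):
        raise InvalidInputError(
            f"call vectors differ in length: {len(ci_calls)} vs {len(anova_calls)}"
        )
    count = 0
    for c, a in zip(ci_calls, anova_calls):
        if c == a or (c, a) in _AGREEMENT:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run settings.

    ``input_mode`` selects replicate-level transport CSV input (Papp is
    computed and QC-screened first) or a summary CSV of (mean, SEM, n)
    whose log-scale statistics are reconstructed by moment matching. The
    nPR metric needs per-insert minoxidil data and is therefore only
    available in replicate mode.
    """

    input_path: str | Path | None = None
    input_mode: Literal["replicates", "summary"] = "summary"
    metric: Literal["PR", "nPR"] = "PR"
    alpha: float = 0.10
    lower_limit: float = 0.8
    upper_limit: float = 1.25
    design: Literal["parallel", "crossover"] = "parallel"
    alpha_anova: float = 0.01
    control_id: str = "control"
    out_dir: str | Path | None = None


def _equivalence_config(cfg: PipelineConfig) -> _eq.EquivalenceConfig:
    return _eq.EquivalenceConfig(
        alpha=cfg.alpha,
        design_constant=1.0 if cfg.design == "parallel" else 0.5,
        lower_limit=cfg.lower_limit,
        upper_limit=cfg.upper_limit,
    )


def _calls_from_summaries(
    summaries: Sequence[_ratios.GroupSummary], cfg: PipelineConfig
) -> tuple[dict, dict]:
    eq_cfg = _equivalence_config(cfg)
    by_drug: dict[str, list[_ratios.GroupSummary]] = {}
    for s in summaries:
        by_drug.setdefault(s.drug_id, []).append(s)
    ci_calls, anova_calls = {}, {}
    for drug, groups in by_drug.items():
        ci_calls[drug] = _eq.classify_all(
            groups, eq_cfg, control_id=cfg.control_id, kind=cfg.metric
        )
        anova_groups = [
            _anova.GroupData(
                label=g.treatment_id,
                n=g.n,
                mean=g.mean_papp,
                sd=g.sem_papp * g.n**0.5,
            )
            for g in groups
        ]
        anova_calls[drug] = _anova.anova_calls(
            anova_groups,
            alpha=cfg.alpha_anova,
            control_id=cfg.control_id,
            drug_id=drug,
        )
    return ci_calls, anova_calls


def _calls_from_replicates(
    groups: Mapping[str, list[_transport.TransportMeasurement]],
    cfg: PipelineConfig,
) -> tuple[dict, dict]:
    eq_cfg = _equivalence_config(cfg)
    records = {
        analyte: [_transport.compute_papp(m) for m in ms]
        for analyte, ms in groups.items()
    }
    atenolol_by_insert = {r.insert_id: r.papp for r in records["atenolol"]}
    records["drug"] = _transport.qc_screen(records["drug"], atenolol_by_insert)

    def group_key(r: _transport.PermeabilityRecord) -> tuple[str, str]:
        return (r.drug_id, r.treatment_id)

    drug_groups: dict[tuple[str, str], list[_transport.PermeabilityRecord]] = {}
    for r in records["drug"]:
        drug_groups.setdefault(group_key(r), []).append(r)
    mino_groups: dict[tuple[str, str], list[_transport.PermeabilityRecord]] = {}
    for r in records["minoxidil"]:
        mino_groups.setdefault(group_key(r), []).append(r)

    if cfg.metric == "nPR":
        if not records["minoxidil"]:
            raise InvalidInputError(
                "nPR metric requested but no minoxidil records present"
            )
        values_by_group = {
            key: [
                s.log_ratio_component
                for s in _ratios.npr_samples(recs, mino_groups.get(key, []))
            ]
            for key, recs in drug_groups.items()
        }
        # log-ratio observations; exponentiate for the raw-scale ANOVA path
        log_stats = {
            key: _ratios.GroupLogStats(
                drug_id=key[0],
                treatment_id=key[1],
                n=len(vals),
                mean_log=float(pd.Series(vals).mean()),
                sd_log=float(pd.Series(vals).std(ddof=1)),
            )
            for key, vals in values_by_group.items()
        }
        raw_values = {
            key: [math.exp(v) for v in vals]
            for key, vals in values_by_group.items()
        }
    else:
        raw_values = {
            key: [r.papp for r in recs] for key, recs in drug_groups.items()
        }
        log_stats = {
            key: _ratios.log_stats_from_replicates(
                vals, drug_id=key[0], treatment_id=key[1]
            )
            for key, vals in raw_values.items()
        }

    drugs = sorted({d for d, _ in log_stats})
    ci_calls, anova_calls = {}, {}
    for drug in drugs:
        stats_list = [s for (d, _), s in log_stats.items() if d == drug]
        ci_calls[drug] = _eq.classify_all(
            stats_list, eq_cfg, control_id=cfg.control_id, kind=cfg.metric
        )
        anova_groups = [
            _anova.GroupData.from_replicates(t, raw_values[(d, t)])
            for (d, t) in raw_values
            if d == drug
        ]
        anova_calls[drug] = _anova.anova_calls(
            anova_groups,
            alpha=cfg.alpha_anova,
            control_id=cfg.control_id,
            drug_id=drug,
        )
    return ci_calls, anova_calls


def run_pipeline(
    cfg: PipelineConfig,
    summaries: Sequence[_ratios.GroupSummary] | None = None,
) -> dict:
    """Execute the full screen and (optionally) write the report bundle.

    Input precedence: explicit ``summaries``, else ``cfg.input_path``
    (transport CSV in replicate mode, summary CSV in summary mode), else
    the embedded reference dataset in summary mode. Outputs, when
    ``cfg.out_dir`` is set: ``effect_matrix.tsv`` (excipients as rows),
    ``estimates.tsv`` (per-comparison GMR and CI bounds), ``anova.tsv``
    and ``report.json``. All outputs are computed before any file is
    written, so a failure never leaves partial outputs. Deterministic for
    fixed inputs.
    """
    if cfg.input_mode == "summary":
        if summaries is None:
            if cfg.input_path is not None:
                summaries = _ratios.read_summary_csv(cfg.input_path)
            else:
                summaries = _ratios.load_reference_summaries()
        if cfg.metric == "nPR":
            raise InvalidInputError(
                "nPR metric requires replicate input with minoxidil records; "
                "summary tables carry no marker data"
            )
        ci_calls, anova_calls = _calls_from_summaries(summaries, cfg)
    else:
        if cfg.input_path is None:
            raise InvalidInputError("replicate mode requires input_path")
        groups = _transport.read_transport_csv(cfg.input_path)
        ci_calls, anova_calls = _calls_from_replicates(groups, cfg)

    matrix = build_effect_matrix(ci_calls, anova_calls, metric=cfg.metric)
    frequencies = tally_frequencies(matrix)
    consensus = matrix.consensus()

    estimates = pd.DataFrame(
        {
            "drug_id": c.basis.drug_id,
            "treatment_id": c.basis.treatment_id,
            "metric": c.basis.kind,
            "gmr": c.basis.gmr,
            "ci_low": c.basis.ci_low,
            "ci_high": c.basis.ci_high,
            "df": c.basis.df,
            "source": c.basis.source,
            "call": c.call,
        }
        for d in sorted(ci_calls)
        for c in ci_calls[d]
    )
    anova_table = pd.DataFrame(
        {
            "drug_id": a.drug_id,
            "treatment_id": a.treatment_id,
            "raw_p": a.raw_p,
            "adjusted_p": a.adjusted_p,
            "call": a.call,
        }
        for d in sorted(anova_calls)
        for a in anova_calls[d]
    )
    matrix_frame = pd.DataFrame(
        {
            drug: {
                exc: f"{matrix.ci_grid[(exc, drug)]}/{matrix.anova_grid[(exc, drug)]}"
                for exc in matrix.excipients
            }
            for drug in matrix.drugs
        }
    )
    matrix_frame.index.name = "excipient"
    matrix_frame["consensus"] = pd.Series(consensus)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "metric": cfg.metric,
        "config": {
            "alpha": cfg.alpha,
            "limits": [cfg.lower_limit, cfg.upper_limit],
            "design": cfg.design,
            "alpha_anova": cfg.alpha_anova,
            "input_mode": cfg.input_mode,
        },
        "estimates": estimates.to_dict(orient="records"),
        "anova": anova_table.to_dict(orient="records"),
        "consensus": consensus,
        "frequencies": {
            f"{method}:{effect}": counts
            for (method, effect), counts in frequencies.to_dict(orient="index").items()
        },
    }

    if cfg.out_dir is not None:
        out_dir = Path(cfg.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        matrix_frame.to_csv(out_dir / "effect_matrix.tsv", sep="\t")
        estimates.to_csv(out_dir / "estimates.tsv", sep="\t", index=False)
        anova_table.to_csv(out_dir / "anova.tsv", sep="\t", index=False)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    return {
        "matrix": matrix,
        "frequencies": frequencies,
        "consensus": consensus,
        "estimates": estimates,
        "anova": anova_table,
        "report": report,
    }
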