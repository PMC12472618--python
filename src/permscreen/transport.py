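"""Apparent permeability from transwell transport records, with QC gates.

A transwell assay measures solute transfer across a cell monolayer grown on
a semiporous insert. Under sink conditions (receiver concentration kept
small relative to donor) the apparent permeability follows from Fick's
first law applied to endpoint sampling:

    Papp = (C_R * V_R) / (dt * A * C_D)        [cm/s]

with C_R the receiver concentration at the end of the incubation (uM),
V_R the receiver volume (mL = cm^3), dt the incubation time (s), A the
monolayer area (cm^2) and C_D the donor concentration at t=0 (uM).

Experiment-level quality control is advisory, never a filter: each record
carries flags for monolayer integrity (the co-dosed low-permeability marker
atenolol), mass balance, and sink-condition violations, but no record is
dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TransportMeasurement",
    "PermeabilityRecord",
    "QcThresholds",
    "QC_VOCABULARY",
    "compute_papp",
    "integrity_flag",
    "qc_screen",
    "read_transport_csv",
    "records_to_frame",
]

#: Fixed vocabulary of advisory QC flags.
QC_VOCABULARY = frozenset(
    {
        "integrity_pass",
        "integrity_moderate",
        "integrity_major",
        "integrity_unknown",
        "mass_balance_fail",
        "sink_violation",
    }
)


class InvalidInputError(ValueError):
    """A measurement field violates its physical domain."""


@dataclass(frozen=True)
class TransportMeasurement:
    """One insert's donor/receiver record for a single analyte.

    Concentrations are in uM (= nmol/mL), volume in mL, area in cm^2 and
    duration in seconds, so that the derived permeability is in cm/s.
    """

    drug_id: str
    treatment_id: str
    insert_id: str
    receiver_conc: float
    donor_conc_t0: float
    receiver_volume: float = 1.5
    area: float = 1.12
    duration: float = 7200.0
    donor_recovery_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.receiver_conc < 0:
            raise InvalidInputError(
                f"receiver_conc must be >= 0, got {self.receiver_conc}"
            )
        for name in ("donor_conc_t0", "receiver_volume", "area", "duration"):
            value = getattr(self, name)
            if not value > 0:
                raise InvalidInputError(f"{name} must be > 0, got {value}")
        if self.donor_recovery_fraction is not None and not (
            0 <= self.donor_recovery_fraction <= 1
        ):
            raise InvalidInputError(
                "donor_recovery_fraction must lie in [0, 1], got "
                f"{self.donor_recovery_fraction}"
            )


@dataclass
class PermeabilityRecord:
    """A computed Papp for one (insert, analyte) with advisory QC flags."""

    drug_id: str
    treatment_id: str
    insert_id: str
    papp: float
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.papp < 0:
            raise InvalidInputError(f"papp must be >= 0, got {self.papp}")
        unknown = self.qc_flags - QC_VOCABULARY
        if unknown:
            raise InvalidInputError(f"unknown QC flags: {sorted(unknown)}")


@dataclass(frozen=True)
class QcThresholds:
    """Gate values for the advisory QC screen.

    ``atenolol_pass_max`` / ``atenolol_major_min`` bound the integrity bands
    of the co-dosed atenolol marker: strictly below the first is a pass,
    strictly above the second is a major breach, anything else (including
    both boundaries and the 1.0-1.1 gap) is moderate. ``mass_balance_min``
    is the minimum acceptable donor recovery fraction and
    ``sink_max_receiver_fraction`` the largest receiver amount (as a
    fraction of the initial donor amount) still compatible with sink
    conditions. ``aqueous_papp_min`` is the expected cell-free insert
    permeability floor, exposed for completeness.
    """

    atenolol_pass_max: float = 0.5e-6
    atenolol_major_min: float = 1.1e-6
    mass_balance_min: float = 0.84
    sink_max_receiver_fraction: float = 0.10
    aqueous_papp_min: float = 150e-6

    def __post_init__(self) -> None:
        if not 0 < self.atenolol_pass_max < self.atenolol_major_min:
            raise InvalidInputError(
                "require 0 < atenolol_pass_max < atenolol_major_min"
            )
        if not 0 < self.mass_balance_min <= 1:
            raise InvalidInputError("mass_balance_min must lie in (0, 1]")


def compute_papp(m: TransportMeasurement) -> PermeabilityRecord:
    """Apparent permeability (cm/s) from a single endpoint measurement.

    ``Papp = (receiver_conc * receiver_volume) / (duration * area * donor_conc_t0)``.
    With concentrations in uM, volume in mL (1 mL = 1 cm^3), area in cm^2
    and time in s, the units reduce to cm/s. Zero receiver concentration
    gives Papp = 0 (no mass transferred).
    """
    papp = (m.receiver_conc * m.receiver_volume) / (
        m.duration * m.area * m.donor_conc_t0
    )
    return PermeabilityRecord(
        drug_id=m.drug_id,
        treatment_id=m.treatment_id,
        insert_id=m.insert_id,
        papp=papp,
    )


def integrity_flag(atenolol_papp: float, t: QcThresholds = QcThresholds()) -> str:
    """Classify monolayer integrity from the atenolol marker's Papp.

    Strictly below ``atenolol_pass_max`` -> ``integrity_pass``; strictly
    above ``atenolol_major_min`` -> ``integrity_major``; the closed band in
    between (boundaries included) -> ``integrity_moderate``.
    """
    if atenolol_papp < 0:
        raise InvalidInputError(f"atenolol_papp must be >= 0, got {atenolol_papp}")
    if atenolol_papp < t.atenolol_pass_max:
        return "integrity_pass"
    if atenolol_papp > t.atenolol_major_min:
        return "integrity_major"
    return "integrity_moderate"


def qc_screen(
    records: Sequence[PermeabilityRecord],
    atenolol_by_insert: Mapping[str, float],
    t: QcThresholds = QcThresholds(),
    measurements: Mapping[str, TransportMeasurement] | None = None,
) -> list[PermeabilityRecord]:
    """Annotate permeability records with advisory QC flags.

    Each record receives the integrity flag of its insert's atenolol
    measurement (``integrity_unknown`` when the insert has no atenolol
    record); ``mass_balance_fail`` when the donor recovery fraction of the
    originating measurement falls below ``mass_balance_min``; and
    ``sink_violation`` when the receiver amount exceeds
    ``sink_max_receiver_fraction`` of the initial donor amount. Flags are
    advisory: Papp values are never altered and no record is dropped.

    Parameters
    ----------
    records
        Permeability records to annotate (returned as new objects).
    atenolol_by_insert
        Atenolol Papp (cm/s) keyed by insert id.
    measurements
        Optional originating measurements keyed by
        ``f"{drug_id}|{treatment_id}|{insert_id}"``; needed for the
        mass-balance and sink checks.
    """
    out: list[PermeabilityRecord] = []
    for r in records:
        flags = set(r.qc_flags)
        if r.insert_id in atenolol_by_insert:
            flags.add(integrity_flag(atenolol_by_insert[r.insert_id], t))
        else:
            flags.add("integrity_unknown")
        if measurements is not None:
            key = f"{r.drug_id}|{r.treatment_id}|{r.insert_id}"
            m = measurements.get(key)
            if m is not None:
                if (
                    m.donor_recovery_fraction is not None
                    and m.donor_recovery_fraction < t.mass_balance_min
                ):
                    flags.add("mass_balance_fail")
                # receiver amount / initial donor amount; donor volume is
                # taken equal to receiver volume (symmetric compartments)
                receiver_fraction = m.receiver_conc / m.donor_conc_t0
                if receiver_fraction > t.sink_max_receiver_fraction:
                    flags.add("sink_violation")
        out.append(
            PermeabilityRecord(
                drug_id=r.drug_id,
                treatment_id=r.treatment_id,
                insert_id=r.insert_id,
                papp=r.papp,
                qc_flags=flags,
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O

_REQUIRED_COLUMNS = (
    "drug_id",
    "treatment_id",
    "insert_id",
    "analyte",
    "receiver_conc_uM",
    "donor_conc_uM",
    "receiver_volume_mL",
    "area_cm2",
    "duration_s",
)


def read_transport_csv(path: str | Path) -> dict[str, list[TransportMeasurement]]:
    """Read replicate-level transport data, one row per (insert, analyte).

    Returns measurements grouped by analyte role: ``"drug"``,
    ``"minoxidil"`` (high-permeability marker) and ``"atenolol"``
    (integrity marker). Schema violations are reported with row numbers.
    """
    path = Path(path)
    groups: dict[str, list[TransportMeasurement]] = {
        "drug": [],
        "minoxidil": [],
        "atenolol": [],
    }
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _REQUIRED_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise InvalidInputError(f"{path}: missing columns {missing}")
        for i, row in enumerate(reader, start=2):
            analyte = row["analyte"].strip().lower()
            if analyte not in groups:
                raise InvalidInputError(
                    f"{path} row {i}: analyte must be drug|minoxidil|atenolol, "
                    f"got {row['analyte']!r}"
                )
            recovery = row.get("donor_recovery_fraction", "")
            try:
                m = TransportMeasurement(
                    drug_id=row["drug_id"].strip(),
                    treatment_id=row["treatment_id"].strip(),
                    insert_id=row["insert_id"].strip(),
                    receiver_conc=float(row["receiver_conc_uM"]),
                    donor_conc_t0=float(row["donor_conc_uM"]),
                    receiver_volume=float(row["receiver_volume_mL"]),
                    area=float(row["area_cm2"]),
                    duration=float(row["duration_s"]),
                    donor_recovery_fraction=(
                        float(recovery) if recovery not in ("", None) else None
                    ),
                )
            except (InvalidInputError, ValueError) as exc:
                raise InvalidInputError(f"{path} row {i}: {exc}") from exc
            groups[analyte].append(m)
    return groups


def records_to_frame(records: Iterable[PermeabilityRecord]) -> pd.DataFrame:
    """Per-record table with papp_cm_per_s and semicolon-joined qc_flags."""
    return pd.DataFrame(
        {
            "drug_id": r.drug_id,
            "treatment_id": r.treatment_id,
            "insert_id": r.insert_id,
            "papp_cm_per_s": r.papp,
            "qc_flags": ";".join(sorted(r.qc_flags)),
        }
        for r in records
    )
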