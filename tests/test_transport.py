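"""Apparent-permeability arithmetic and QC gating."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from permscreen.transport import (
    InvalidInputError,
    PermeabilityRecord,
    QcThresholds,
    TransportMeasurement,
    compute_papp,
    integrity_flag,
    qc_screen,
    read_transport_csv,
    records_to_frame,
)


def _measurement(**overrides):
    base = dict(
        drug_id="drug",
        treatment_id="control",
        insert_id="i1",
        receiver_conc=1.0,
        donor_conc_t0=100.0,
        receiver_volume=1.5,
        area=1.12,
        duration=7200.0,
    )
    base.update(overrides)
    return TransportMeasurement(**base)


class TestComputePapp:
    def test_reference_geometry(self):
        # 1 uM into 1.5 mL over 2 h across 1.12 cm2 from a 100 uM donor
        record = compute_papp(_measurement())
        assert record.papp == pytest.approx(1.5 / 806400, rel=1e-12)
        assert record.papp == pytest.approx(1.860e-6, rel=1e-3)

    def test_zero_receiver_gives_zero(self):
        assert compute_papp(_measurement(receiver_conc=0.0)).papp == 0.0

    def test_linear_in_inverse_duration(self):
        p1 = compute_papp(_measurement()).papp
        p2 = compute_papp(_measurement(duration=14400.0)).papp
        assert p2 == pytest.approx(p1 / 2, rel=1e-12)

    @pytest.mark.parametrize(
        "field", ["donor_conc_t0", "receiver_volume", "area", "duration"]
    )
    def test_nonpositive_inputs_name_the_field(self, field):
        with pytest.raises(InvalidInputError, match=field):
            _measurement(**{field: 0.0})

    @given(
        receiver=st.floats(1e-3, 1e3),
        donor=st.floats(1e-2, 1e4),
        volume=st.floats(0.1, 10),
        area=st.floats(0.1, 10),
        duration=st.floats(60, 1e5),
        k=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_homogeneity(self, receiver, donor, volume, area, duration, k):
        """Degree 1 in receiver conc; degree -1 in donor, duration and area."""
        base = compute_papp(
            _measurement(
                receiver_conc=receiver,
                donor_conc_t0=donor,
                receiver_volume=volume,
                area=area,
                duration=duration,
            )
        ).papp
        scaled_up = compute_papp(
            _measurement(
                receiver_conc=receiver * k,
                donor_conc_t0=donor,
                receiver_volume=volume,
                area=area,
                duration=duration,
            )
        ).papp
        assert scaled_up == pytest.approx(k * base, rel=1e-9)
        for field, value in (
            ("donor_conc_t0", donor),
            ("duration", duration),
            ("area", area),
        ):
            kwargs = dict(
                receiver_conc=receiver,
                donor_conc_t0=donor,
                receiver_volume=volume,
                area=area,
                duration=duration,
            )
            kwargs[field] = value * k
            scaled_down = compute_papp(_measurement(**kwargs)).papp
            assert scaled_down == pytest.approx(base / k, rel=1e-9)

    @given(receiver=st.floats(1e-3, 1e3))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_fixed_geometry_ratio_is_drug_independent(self, receiver):
        """papp / receiver_conc is one constant under the standard geometry."""
        record = compute_papp(_measurement(receiver_conc=receiver))
        assert record.papp / receiver == pytest.approx(
            1.5 / (7200 * 1.12 * 100), rel=1e-12
        )


class TestIntegrityFlag:
    @pytest.mark.parametrize(
        "papp, expected",
        [
            (0.3e-6, "integrity_pass"),
            (3.7e-6, "integrity_major"),
            (0.7e-6, "integrity_moderate"),
            # boundary values fall into the moderate band
            (0.5e-6, "integrity_moderate"),
            (1.1e-6, "integrity_moderate"),
            (1.05e-6, "integrity_moderate"),
        ],
    )
    def test_bands(self, papp, expected):
        assert integrity_flag(papp) == expected

    def test_negative_input(self):
        with pytest.raises(InvalidInputError):
            integrity_flag(-1e-7)


class TestQcScreen:
    def _record(self, insert="i1"):
        return PermeabilityRecord("drug", "control", insert, 1e-6)

    def test_clean_insert_passes_all_gates(self):
        m = _measurement(donor_recovery_fraction=0.9)
        out = qc_screen(
            [self._record()], {"i1": 0.2e-6}, measurements={"drug|control|i1": m}
        )
        assert out[0].qc_flags == {"integrity_pass"}

    def test_mass_balance_gate(self):
        m = _measurement(donor_recovery_fraction=0.80)
        out = qc_screen(
            [self._record()], {"i1": 0.2e-6}, measurements={"drug|control|i1": m}
        )
        assert "mass_balance_fail" in out[0].qc_flags

    def test_sink_violation_gate(self):
        m = _measurement(receiver_conc=15.0, donor_conc_t0=100.0)
        out = qc_screen(
            [self._record()], {"i1": 0.2e-6}, measurements={"drug|control|i1": m}
        )
        assert "sink_violation" in out[0].qc_flags

    def test_missing_atenolol_is_flag_not_error(self):
        out = qc_screen([self._record()], {})
        assert "integrity_unknown" in out[0].qc_flags

    def test_flags_never_alter_papp(self):
        records = [self._record(), self._record("i2")]
        out = qc_screen(records, {"i1": 0.2e-6, "i2": 4e-6})
        assert [r.papp for r in out] == [r.papp for r in records]
        assert "integrity_major" in out[1].qc_flags


class TestIo:
    def test_roundtrip_csv(self, tmp_path):
        path = tmp_path / "transport.csv"
        path.write_text(
            "drug_id,treatment_id,insert_id,analyte,receiver_conc_uM,"
            "donor_conc_uM,receiver_volume_mL,area_cm2,duration_s,"
            "donor_recovery_fraction\n"
            "acv,control,i1,drug,1.0,100,1.5,1.12,7200,0.95\n"
            "acv,control,i1,minoxidil,2.0,10,1.5,1.12,7200,\n"
            "acv,control,i1,atenolol,0.1,10,1.5,1.12,7200,\n"
        )
        groups = read_transport_csv(path)
        assert len(groups["drug"]) == len(groups["minoxidil"]) == 1
        assert groups["drug"][0].donor_recovery_fraction == 0.95
        assert groups["minoxidil"][0].donor_recovery_fraction is None

    def test_bad_analyte_reports_row(self, tmp_path):
        path = tmp_path / "transport.csv"
        path.write_text(
            "drug_id,treatment_id,insert_id,analyte,receiver_conc_uM,"
            "donor_conc_uM,receiver_volume_mL,area_cm2,duration_s\n"
            "acv,control,i1,unknown,1.0,100,1.5,1.12,7200\n"
        )
        with pytest.raises(InvalidInputError, match="row 2"):
            read_transport_csv(path)

    def test_records_frame_joins_flags(self):
        frame = records_to_frame(
            [
                PermeabilityRecord(
                    "acv", "control", "i1", 1e-6,
                    {"integrity_pass", "sink_violation"},
                )
            ]
        )
        assert frame.loc[0, "qc_flags"] == "integrity_pass;sink_violation"
        assert frame.loc[0, "papp_cm_per_s"] == 1e-6
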