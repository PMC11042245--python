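import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarscreen.curation import (
    BioactivityRecord,
    CurationConfig,
    CurationError,
    NotConvertibleError,
    canonical_key,
    curate,
    label_active,
    parse_activity_table,
    pchembl_from_molar,
    to_molar,
)

CSV_HEADER = "compound_id,smiles,endpoint_type,qualifier,value,unit\n"


def rec(smiles="CCO", value=100.0, unit="nM", qualifier="=", endpoint="IC50"):
    return BioactivityRecord("X", smiles, endpoint, qualifier, value, unit)


class TestParseActivityTable:
    def test_well_formed_rows_parse_without_rejects(self):
        csv = CSV_HEADER + "a,CCO,IC50,=,5,nM\nb,CCN,Ki,=,1,uM\nc,CCC,EC50,=,2,mM\n"
        records, rejects = parse_activity_table(csv)
        assert len(records) == 3 and not rejects

    def test_blank_smiles_is_rejected_with_reason(self):
        csv = CSV_HEADER + "a,CCO,IC50,=,5,nM\nb,,IC50,=,5,nM\nc,CCC,IC50,=,2,mM\n"
        records, rejects = parse_activity_table(csv)
        assert len(records) == 2
        assert len(rejects) == 1 and rejects[0][1] == "missing structure"

    def test_greek_mu_unit_aliases_to_uM(self):
        csv = CSV_HEADER + "a,CCO,IC50,=,5,uM\nb,CCN,IC50,=,5,μM\n"
        records, _ = parse_activity_table(csv)
        from qsarscreen.curation import normalize_unit

        assert normalize_unit(records[0].unit) == normalize_unit(records[1].unit) == "uM"

    def test_missing_mapped_column_is_fatal(self):
        with pytest.raises(ValueError, match="missing"):
            parse_activity_table("id,smiles\n1,CCO\n")

    def test_empty_file_is_fatal(self):
        with pytest.raises(ValueError, match="empty"):
            parse_activity_table("")

    def test_tsv_autodetected(self):
        tsv = CSV_HEADER.replace(",", "\t") + "a\tCCO\tIC50\t=\t5\tnM\n"
        records, _ = parse_activity_table(tsv)
        assert records[0].smiles == "CCO"


class TestUnitConversion:
    @pytest.mark.parametrize(
        "value,unit,molar",
        [(5, "nM", 5e-9), (1, "μM", 1e-6), (1, "uM", 1e-6), (2, "mM", 2e-3), (3, "M", 3.0)],
    )
    def test_concentration_units_scale_to_molar(self, value, unit, molar):
        assert to_molar(value, unit) == pytest.approx(molar)

    def test_percent_signals_not_convertible(self):
        with pytest.raises(NotConvertibleError):
            to_molar(50, "%")

    def test_nonpositive_value_is_an_error(self):
        with pytest.raises(ValueError):
            to_molar(0, "nM")


class TestPchembl:
    @pytest.mark.parametrize(
        "ic50_nm,expected",
        # printed IC50 -> pChEMBL pairs for documented inhibitors
        [(5, 8.30), (21, 7.68), (15, 7.82), (56, 7.25), (106, 6.97), (9300, 5.03)],
    )
    def test_known_inhibitor_ic50_conversions(self, ic50_nm, expected):
        assert round(pchembl_from_molar(to_molar(ic50_nm, "nM")), 2) == expected

    def test_one_molar_gives_zero(self):
        assert pchembl_from_molar(1.0) == 0.0

    def test_nonpositive_molar_is_an_error(self):
        with pytest.raises(ValueError):
            pchembl_from_molar(0.0)

    @given(st.floats(min_value=0.0, max_value=12.0))
    @settings(max_examples=200, derandomize=True)
    def test_log_roundtrip_identity(self, x):
        assert pchembl_from_molar(10.0 ** (-x)) == pytest.approx(x, abs=1e-10)


class TestCanonicalKey:
    @pytest.mark.parametrize(
        "a,b", [("C1=CC=CC=C1", "c1ccccc1"), ("CCO", "OCC"), ("N(C)C", "CN(C)")]
    )
    def test_same_molecule_same_key(self, a, b):
        assert canonical_key(a) == canonical_key(b)

    def test_unclosed_ring_raises_with_offender(self):
        with pytest.raises(ValueError, match="C1CC"):
            canonical_key("C1CC")

    def test_empty_smiles_raises(self):
        with pytest.raises(ValueError):
            canonical_key("  ")


class TestLabelActive:
    @pytest.mark.parametrize(
        "pchembl,threshold,expected",
        [(7.00, 7, True), (6.99, 7, False), (6.5, 6, True), (8.3, 7, True)],
    )
    def test_threshold_is_inclusive(self, pchembl, threshold, expected):
        assert label_active(pchembl, threshold) is expected


class TestCurate:
    def test_mean_aggregation_on_log_scale(self):
        # pChEMBL 6.0 (1 uM) and 8.0 (10 nM) of the same molecule average to 7.0
        records = [rec(value=1.0, unit="uM"), rec(smiles="OCC", value=10.0, unit="nM")]
        compounds, log = curate(records)
        assert len(compounds) == 1
        assert compounds[0].pchembl == pytest.approx(7.0)
        assert compounds[0].n_source_records == 2

    def test_single_record_passes_through(self):
        compounds, _ = curate([rec(value=100.0, unit="nM")])
        assert compounds[0].n_source_records == 1
        assert compounds[0].pchembl == pytest.approx(7.0)
        assert compounds[0].active  # threshold 7 inclusive

    def test_censored_qualifier_rejected_under_default_config(self):
        compounds, log = curate([rec(), rec(smiles="CCN", qualifier=">")])
        assert len(compounds) == 1
        assert any("qualifier" in reason for _, reason in log.rejects)

    def test_non_concentration_endpoint_rejected(self):
        _, log = curate([rec(), rec(smiles="CCN", endpoint="Emax", unit="%")])
        assert log.reject_counts().get("endpoint not convertible") == 1

    def test_unknown_unit_rejected(self):
        _, log = curate([rec(), rec(smiles="CCN", unit="mg/mL")])
        assert log.reject_counts().get("unknown unit") == 1

    def test_input_conservation(self):
        records = [rec(), rec(qualifier="<"), rec(smiles="not-a-smiles"), rec(unit="%")]
        _, log = curate(records)
        assert log.n_records == log.n_contributing + len(log.rejects) == 4

    def test_zero_convertible_records_is_fatal_with_summary(self):
        with pytest.raises(CurationError, match="qualifier"):
            curate([rec(qualifier=">")])

    def test_idempotent_on_its_own_output(self):
        records = [
            rec(value=1.0, unit="uM"),
            rec(smiles="OCC", value=10.0, unit="nM"),
            rec(smiles="CCN", value=50.0, unit="nM"),
        ]
        first, _ = curate(records)
        re_expressed = [
            rec(smiles=c.structure_key, value=10.0 ** (9 - c.pchembl), unit="nM")
            for c in first
        ]
        second, _ = curate(re_expressed)
        assert {c.structure_key for c in first} == {c.structure_key for c in second}
        for a, b in zip(
            sorted(first, key=lambda c: c.structure_key),
            sorted(second, key=lambda c: c.structure_key),
        ):
            assert a.pchembl == pytest.approx(b.pchembl, abs=1e-9)

    @given(st.permutations(range(4)))
    @settings(max_examples=24, derandomize=True)
    def test_aggregation_is_permutation_invariant(self, order):
        base = [
            rec(value=10.0, unit="nM"),
            rec(value=100.0, unit="nM"),
            rec(value=1.0, unit="uM"),
            rec(value=55.0, unit="nM"),
        ]
        shuffled = [base[i] for i in order]
        ref, _ = curate(base)
        got, _ = curate(shuffled)
        assert got[0].pchembl == pytest.approx(ref[0].pchembl, abs=1e-12)

    def test_config_threshold_controls_label(self):
        compounds, _ = curate(
            [rec(value=1.0, unit="uM")], CurationConfig(activity_threshold=6.0)
        )
        assert compounds[0].active
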