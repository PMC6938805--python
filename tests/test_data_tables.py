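"""Table loading, validation, calendar consistency and imputation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sprayrisk.calendar365 import day_of_year, month_of_day, year_index_of_day
from sprayrisk.data_tables import (
    Dialect,
    impute_missing,
    load_compoundtab,
    load_croptab,
    load_maintab,
    write_maintab,
)
from sprayrisk.errors import ImputationError, TableError

from conftest import make_substance

HEADER = ("compound_id,compound_name,cas_nr,chemical_class,chemical_use,"
          "degt50_soil,lc50_earthworm,noec_earthworm,kfoc\n")


def write_compound_csv(tmp_path, rows):
    p = tmp_path / "compoundtab.csv"
    p.write_text(HEADER + "".join(r + "\n" for r in rows))
    return p


class TestCalendar:
    @pytest.mark.parametrize(
        "day,month", [(1, 1), (31, 1), (32, 2), (59, 2), (60, 3), (90, 3),
                      (91, 4), (120, 4), (121, 5), (365, 12), (366, 1), (456, 4)]
    )
    def test_month_of_day_non_leap(self, day, month):
        assert month_of_day(day) == month

    def test_multi_year_recycling(self):
        assert day_of_year(366) == 1
        assert year_index_of_day(365) == 0
        assert year_index_of_day(366) == 1


class TestCompoundtab:
    def test_full_row_reads_complete_record(self, tmp_path):
        p = write_compound_csv(tmp_path, ["0,alpha,1-2-3,cA,fungicide,10,100,5,250"])
        (rec,) = load_compoundtab(p)
        assert rec.is_complete()
        assert rec.name == "alpha" and rec.degt50_soil == 10.0

    def test_blank_cell_becomes_missing(self, tmp_path):
        p = write_compound_csv(tmp_path, ["0,alpha,1-2-3,cA,fungicide,,100,5,250"])
        (rec,) = load_compoundtab(p)
        assert rec.missing_fields() == ("degt50_soil",)

    def test_text_in_numeric_column_names_the_cell(self, tmp_path):
        p = write_compound_csv(tmp_path, ["0,alpha,1-2-3,cA,fungicide,10,n/a,5,250"])
        with pytest.raises(TableError, match="lc50_earthworm.*row 1"):
            load_compoundtab(p)

    def test_duplicate_or_misplaced_id_rejected(self, tmp_path):
        p = write_compound_csv(tmp_path, [
            "0,alpha,1,cA,f,10,100,5,250", "0,beta,2,cA,f,10,100,5,250"])
        with pytest.raises(TableError):
            load_compoundtab(p)
        p2 = write_compound_csv(tmp_path, ["1,alpha,1,cA,f,10,100,5,250"])
        with pytest.raises(TableError, match="row number minus one"):
            load_compoundtab(p2)

    def test_column_order_is_insensitive(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "compound_name,compound_id,cas_nr,chemical_class,chemical_use,"
            "kfoc,degt50_soil,lc50_earthworm,noec_earthworm\n"
            "alpha,0,1-2-3,cA,f,250,10,100,5\n"
        )
        (rec,) = load_compoundtab(p)
        assert rec.kfoc == 250.0 and rec.degt50_soil == 10.0


class TestImputation:
    def test_class_mean_of_two_donors(self):
        target = make_substance(0, "x", dt50=None)
        db = [target, make_substance(1, dt50=10.0), make_substance(2, dt50=20.0)]
        value, tag = impute_missing(target, db, "degt50_soil")
        assert value == pytest.approx(15.0) and tag == "class-mean"
        assert target.degt50_soil == value

    def test_use_mean_fallback_single_donor(self):
        target = make_substance(0, "x", dt50=None, chem_class="only")
        db = [target, make_substance(1, dt50=30.0, chem_class="other")]
        value, tag = impute_missing(target, db, "degt50_soil")
        assert value == 30.0 and tag == "use-mean"

    def test_no_donor_is_an_error(self):
        target = make_substance(0, "x", dt50=None, chem_class="only", chem_use="rare")
        db = [target, make_substance(1, dt50=None)]
        with pytest.raises(ImputationError, match="cannot impute"):
            impute_missing(target, db, "degt50_soil")

    def test_complete_record_refuses_imputation(self):
        target = make_substance(0)
        assert target.is_complete()
        with pytest.raises(ImputationError):
            impute_missing(target, [target, make_substance(1)], "degt50_soil")

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=1, max_size=8))
    def test_imputed_mean_within_donor_bounds(self, donor_values):
        target = make_substance(0, dt50=None)
        db = [target] + [
            make_substance(i + 1, dt50=v) for i, v in enumerate(donor_values)
        ]
        value, _ = impute_missing(target, db, "degt50_soil")
        assert min(donor_values) <= value <= max(donor_values) or math.isclose(
            value, donor_values[0]
        )


class TestCroptab:
    def test_overlapping_bbch_ranges_rejected(self, tmp_path):
        p = tmp_path / "crop.csv"
        p.write_text("crop_id,crop_name,bbch_min,bbch_max,interception_pct\n"
                     "1,apple,0,50,10\n1,apple,40,99,60\n")
        with pytest.raises(TableError, match="overlapping"):
            load_croptab(p)

    def test_interception_outside_percent_range_rejected(self, tmp_path):
        p = tmp_path / "crop.csv"
        p.write_text("crop_id,crop_name,bbch_min,bbch_max,interception_pct\n"
                     "1,apple,0,99,120\n")
        with pytest.raises(TableError):
            load_croptab(p)


class TestMaintab:
    def test_fixture_trio_loads_consistently(self, fixture_trio):
        compounds = load_compoundtab(fixture_trio.compoundtab)
        crops = load_croptab(fixture_trio.croptab)
        scenario = load_maintab(fixture_trio.maintab, compounds, crops)
        assert len(scenario.events) == len(fixture_trio.scenario.events)
        assert scenario.simulation_days == fixture_trio.scenario.simulation_days

    def test_round_trip_is_identity(self, fixture_trio, tmp_path):
        compounds = load_compoundtab(fixture_trio.compoundtab)
        crops = load_croptab(fixture_trio.croptab)
        scenario = load_maintab(fixture_trio.maintab, compounds, crops)
        out = tmp_path / "roundtrip.csv"
        write_maintab(scenario, out)
        again = load_maintab(out, compounds, crops)
        assert again == scenario

    def test_day_month_mismatch_rejected(self, fixture_trio, apple_example, tmp_path):
        # day 91 is April 1 in a non-leap year, so month 3 must be rejected
        compounds = load_compoundtab(fixture_trio.compoundtab)
        crops = load_croptab(fixture_trio.croptab)
        text = fixture_trio.maintab.read_text().splitlines()
        out = []
        for line in text:
            cells = line.split(",")
            if cells[0] == "application_day":
                cells[1] = "91"
            if cells[0] == "application_month":
                cells[1] = "3"
            out.append(",".join(cells))
        bad = tmp_path / "bad.csv"
        bad.write_text("\n".join(out) + "\n")
        with pytest.raises(TableError, match="month"):
            load_maintab(bad, compounds, crops)

    def test_unknown_crop_rejected(self, fixture_trio):
        compounds = load_compoundtab(fixture_trio.compoundtab)
        crops = [c for c in load_croptab(fixture_trio.croptab) if c.crop_id != 1]
        with pytest.raises(TableError, match="crop_id"):
            load_maintab(fixture_trio.maintab, compounds, crops)

    def test_semicolon_dialect(self, fixture_trio, tmp_path):
        dialect = Dialect(delimiter=";")
        out = tmp_path / "semi.csv"
        write_maintab(fixture_trio.scenario, out, dialect)
        compounds = load_compoundtab(fixture_trio.compoundtab)
        crops = load_croptab(fixture_trio.croptab)
        scenario = load_maintab(out, compounds, crops, dialect)
        assert scenario == fixture_trio.scenario
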