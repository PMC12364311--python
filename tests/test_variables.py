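import math
import statistics

import numpy as np
import pandas as pd
import pytest

from aurumkit import (
    extract_bmi,
    extract_cholhdl_ratio,
    extract_diabetes,
    extract_ho,
    extract_smoking,
    extract_test_data,
    extract_test_data_var,
    extract_time_until,
)

IDX = "2010-01-01"


def _cohort(patids=("1", "2"), index=IDX, cens="2010-12-31"):
    return pd.DataFrame(
        {
            "patid": list(patids),
            "indexdt": pd.to_datetime([index] * len(patids)),
            "censdt": pd.to_datetime([cens] * len(patids)),
        }
    )


class TestExtractHo:
    def test_record_on_index_date_counts_as_history(self, make_store):
        h = make_store([("1", "C", IDX, 1, "u")])
        out = extract_ho(_cohort(), codelist_vector=["C"], store=h, varname="ho")
        assert out["ho"].tolist() == [1, 0]

    def test_record_after_index_does_not_count(self, make_store):
        h = make_store([("1", "C", "2010-01-02", 1, "u")])
        out = extract_ho(_cohort(), codelist_vector=["C"], store=h, varname="ho")
        assert out["ho"].tolist() == [0, 0]

    def test_prescription_history_from_drugissue_table(self, make_store):
        h = make_store([], drugissue_rows=[("2", "P", "2009-05-01")])
        out = extract_ho(
            _cohort(), codelist_vector=["P"], store=h, tab="drugissue", varname="ho"
        )
        assert out["ho"].tolist() == [0, 1]

    def test_offset_equals_shifted_cohort(self, make_store):
        """Extracting t days after the index date is the same as shifting
        every index date by t days."""
        rows = [("1", "C", "2010-06-01", 1, "u"), ("2", "C", "2011-06-01", 1, "u")]
        h = make_store(rows)
        coh = _cohort()
        offset = extract_ho(coh, codelist_vector=["C"], store=h, t_offset=365, varname="ho")
        shifted = coh.assign(indexdt=coh["indexdt"] + pd.Timedelta(days=365))
        base = extract_ho(shifted, codelist_vector=["C"], store=h, varname="ho")
        pd.testing.assert_frame_equal(offset, base)

    def test_one_row_per_cohort_patient(self, make_store):
        h = make_store([("1", "C", "2009-01-01", 1, "u")] * 5)
        out = extract_ho(_cohort(), codelist_vector=["C"], store=h, varname="ho")
        assert out["patid"].tolist() == ["1", "2"]


class TestExtractTimeUntil:
    def test_event_before_censoring(self, make_store):
        h = make_store([("1", "C", "2010-04-11", 1, "u")])  # index + 100d
        out = extract_time_until(
            _cohort(cens="2010-07-20"), codelist_vector=["C"], store=h, varname="ev"
        )
        assert out.loc[0, "ev_time"] == 100 and out.loc[0, "ev_indicator"] == 1

    def test_no_event_censored_at_censdt(self, make_store):
        h = make_store([])
        out = extract_time_until(
            _cohort(cens="2010-07-20"), codelist_vector=["C"], store=h, varname="ev"
        )
        assert out["ev_time"].tolist() == [200, 200]
        assert out["ev_indicator"].tolist() == [0, 0]

    def test_event_after_censoring_is_censored(self, make_store):
        h = make_store([("1", "C", "2010-10-28", 1, "u")])  # index + 300d
        out = extract_time_until(
            _cohort(cens="2010-07-20"), codelist_vector=["C"], store=h, varname="ev"
        )
        assert out.loc[0, "ev_time"] == 200 and out.loc[0, "ev_indicator"] == 0

    def test_event_on_index_date_not_counted_time_positive(self, make_store):
        """Events exactly on the index date belong to history, not
        follow-up, so survival times stay positive."""
        h = make_store([("1", "C", IDX, 1, "u"), ("1", "C", "2010-01-02", 1, "u")])
        out = extract_time_until(_cohort(), codelist_vector=["C"], store=h, varname="ev")
        assert out.loc[0, "ev_time"] == 1 and out.loc[0, "ev_indicator"] == 1

    def test_missing_censdt_is_error(self, make_store):
        h = make_store([])
        with pytest.raises(ValueError, match="censdt"):
            extract_time_until(
                _cohort().drop(columns=["censdt"]), codelist_vector=["C"], store=h
            )

    def test_time_bounded_by_follow_up(self, make_store):
        rows = [("1", "C", "2010-03-01", 1, "u"), ("2", "C", "2012-01-01", 1, "u")]
        h = make_store(rows)
        coh = _cohort(cens="2010-12-31")
        out = extract_time_until(coh, codelist_vector=["C"], store=h, varname="ev")
        follow_up = (coh["censdt"] - coh["indexdt"]).dt.days
        assert ((out["ev_time"] >= 0) & (out["ev_time"] <= follow_up)).all()
        assert set(out["ev_indicator"]) <= {0, 1}


class TestExtractTestData:
    def test_most_recent_and_bounds_and_numobs(self, make_store):
        h = make_store(
            [("1", "T", "2009-12-22", 50, "u"), ("1", "T", "2009-12-27", 70, "u")]
        )
        coh = _cohort()
        top = extract_test_data(coh, codelist_vector=["T"], store=h,
                                time_prev=30, varname="v")
        assert top["v"].tolist() == [70]
        bounded = extract_test_data(coh, codelist_vector=["T"], store=h,
                                    time_prev=30, upper_bound=60, varname="v")
        assert bounded["v"].tolist() == [50]
        both = extract_test_data(coh, codelist_vector=["T"], store=h,
                                 time_prev=30, numobs=2, varname="v")
        assert both["v"].tolist() == [70, 50]

    def test_metadata_columns(self, make_store):
        h = make_store([("1", "T", "2009-12-27", 70, "mmol/L")])
        out = extract_test_data(_cohort(), codelist_vector=["T"], store=h,
                                time_prev=30, varname="v", with_metadata=True)
        assert list(out.columns) == ["patid", "obsdate", "medcodeid", "v", "numunitid"]
        assert out.loc[0, "numunitid"] == "mmol/L"


class TestExtractTestDataVar:
    def test_sample_sd_of_three_values(self, make_store):
        h = make_store(
            [("1", "T", "2009-12-01", v, "u") for v in (1, 2, 3)]
        )
        out = extract_test_data_var(_cohort(), codelist_vector=["T"], store=h,
                                    time_prev=60, varname="sd")
        assert out.loc[0, "sd"] == pytest.approx(1.0)

    def test_single_value_is_missing(self, make_store):
        h = make_store([("1", "T", "2009-12-01", 5, "u")])
        out = extract_test_data_var(_cohort(), codelist_vector=["T"], store=h,
                                    time_prev=60, varname="sd")
        assert math.isnan(out.loc[0, "sd"])

    def test_matches_independent_two_pass_sd(self, make_store):
        rng = np.random.default_rng(42)
        rows, expected = [], {}
        for patid in ["1", "2"]:
            values = rng.integers(1, 100, size=rng.integers(2, 12)).tolist()
            rows += [(patid, "T", "2009-10-01", v, "u") for v in values]
            expected[patid] = statistics.stdev(values)  # independent two-pass SD
        h = make_store(rows)
        out = extract_test_data_var(_cohort(), codelist_vector=["T"], store=h,
                                    time_prev=365, varname="sd").set_index("patid")
        for patid, sd in expected.items():
            assert out.loc[patid, "sd"] == pytest.approx(sd)


BMI, HEIGHT, WEIGHT = ["BMI"], ["HGT"], ["WGT"]


class TestExtractBmi:
    def _extract(self, h, **kw):
        return extract_bmi(
            _cohort(), codelist_bmi=BMI, codelist_height=HEIGHT,
            codelist_weight=WEIGHT, store=h, **kw,
        )

    def test_weight_over_height_squared(self, make_store):
        h = make_store(
            [("1", "WGT", "2009-06-01", 80, "kg"), ("1", "HGT", "2009-05-01", 2.0, "m")]
        )
        out = self._extract(h)
        assert out.loc[0, "bmi"] == pytest.approx(20.0)

    def test_centimetre_height_converted(self, make_store):
        h = make_store(
            [("1", "WGT", "2009-06-01", 80, "kg"), ("1", "HGT", "2009-05-01", 180, "cm")]
        )
        out = self._extract(h)
        assert out.loc[0, "bmi"] == pytest.approx(80 / 1.8**2)

    def test_unmapped_unit_heuristic_treats_large_height_as_cm(self, make_store):
        h = make_store(
            [("1", "WGT", "2009-06-01", 80, "47"), ("1", "HGT", "2009-05-01", 180, "47")]
        )
        assert self._extract(h).loc[0, "bmi"] == pytest.approx(80 / 1.8**2)

    def test_direct_bmi_most_recent_wins(self, make_store):
        h = make_store(
            [
                ("1", "WGT", "2009-06-01", 80, "kg"),
                ("1", "HGT", "2009-05-01", 2.0, "m"),
                ("1", "BMI", "2009-07-01", 30, "kg/m2"),  # after both components
            ]
        )
        assert self._extract(h).loc[0, "bmi"] == pytest.approx(30.0)

    def test_later_components_beat_older_direct(self, make_store):
        h = make_store(
            [
                ("1", "BMI", "2009-01-01", 30, "kg/m2"),
                ("1", "WGT", "2009-06-01", 80, "kg"),
                ("1", "HGT", "2009-05-01", 2.0, "m"),
            ]
        )
        assert self._extract(h).loc[0, "bmi"] == pytest.approx(20.0)

    def test_missing_when_no_candidate(self, make_store):
        h = make_store([("1", "WGT", "2009-06-01", 80, "kg")])  # no height, no direct
        out = self._extract(h)
        assert out["bmi"].isna().all()
        assert out["patid"].tolist() == ["1", "2"]


class TestExtractCholHdlRatio:
    def _extract(self, h):
        return extract_cholhdl_ratio(
            _cohort(), codelist_ratio=["RAT"], codelist_chol=["CHL"],
            codelist_hdl=["HDL"], store=h,
        )

    def test_component_ratio(self, make_store):
        h = make_store(
            [("1", "CHL", "2009-06-01", 6.0, "u"), ("1", "HDL", "2009-06-01", 1.5, "u")]
        )
        assert self._extract(h).loc[0, "cholhdl_ratio"] == pytest.approx(4.0)

    def test_direct_ratio_most_recent_wins(self, make_store):
        h = make_store(
            [
                ("1", "CHL", "2009-06-01", 6.0, "u"),
                ("1", "HDL", "2009-06-01", 1.5, "u"),
                ("1", "RAT", "2009-07-01", 3.5, "u"),
            ]
        )
        assert self._extract(h).loc[0, "cholhdl_ratio"] == pytest.approx(3.5)

    def test_zero_hdl_guard(self, make_store):
        h = make_store(
            [("1", "CHL", "2009-06-01", 6.0, "u"), ("1", "HDL", "2009-06-01", 0, "u")]
        )
        assert self._extract(h)["cholhdl_ratio"].isna().all()


class TestExtractDiabetes:
    T1, T2 = ["T1A"], ["T2A", "GEN"]

    def _extract(self, h):
        return extract_diabetes(
            _cohort(), codelist_type1=self.T1, codelist_type2=self.T2, store=h
        ).set_index("patid")["diabetes"]

    def test_codes_from_both_lists_designate_type1(self, make_store):
        h = make_store(
            [("1", "T1A", "2009-01-01", 1, "u"), ("1", "T2A", "2009-06-01", 1, "u")]
        )
        assert self._extract(h)["1"] == "type1"

    def test_generic_codes_read_as_type2(self, make_store):
        h = make_store([("1", "GEN", "2009-01-01", 1, "u")])
        assert self._extract(h)["1"] == "type2"

    def test_no_codes_absent(self, make_store):
        h = make_store([])
        assert (self._extract(h) == "Absent").all()

    def test_post_index_codes_ignored(self, make_store):
        h = make_store([("1", "T1A", "2011-01-01", 1, "u")])
        assert self._extract(h)["1"] == "Absent"


class TestExtractSmoking:
    LISTS = dict(
        codelist_non=["NON"], codelist_ex=["EX"], codelist_light=["LGT"],
        codelist_moderate=["MOD"], codelist_heavy=["HVY"],
    )

    def _extract(self, h):
        return extract_smoking(_cohort(), store=h, **self.LISTS).set_index("patid")["smoking"]

    def test_recent_non_smoker_with_history_is_ex_smoker(self, make_store):
        h = make_store(
            [("1", "HVY", "2005-01-01", 1, "u"), ("1", "NON", "2009-01-01", 1, "u")]
        )
        assert self._extract(h)["1"] == "Ex-smoker"

    def test_only_non_smoker_records(self, make_store):
        h = make_store([("1", "NON", "2009-01-01", 1, "u")])
        assert self._extract(h)["1"] == "Non-smoker"

    def test_most_recent_moderate(self, make_store):
        h = make_store(
            [("1", "NON", "2005-01-01", 1, "u"), ("1", "MOD", "2009-01-01", 1, "u")]
        )
        assert self._extract(h)["1"] == "Moderate smoker"

    def test_no_records_missing(self, make_store):
        h = make_store([])
        assert self._extract(h).isna().all()

    def test_code_in_two_codelists_is_error(self, make_store):
        h = make_store([])
        bad = dict(self.LISTS, codelist_ex=["NON"])
        with pytest.raises(ValueError, match="both"):
            extract_smoking(_cohort(), store=h, **bad)
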