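import math

import pytest

from neolos.cohort import (
    CohortValidationError,
    HealthScore,
    MARKER_NAMES,
    NLR_SENTINEL,
    compute_nlr,
    derive_markers,
    kleene_or,
    panel_frame,
    read_cohort,
    write_cohort,
)


class TestComputeNlr:
    @pytest.mark.parametrize(
        "anc,lymph,expected",
        [(3000, 2500, 1.2), (0, 5000, 0.0), (6000, 1000, 6.0)],
    )
    def test_ratio(self, anc, lymph, expected):
        assert compute_nlr(anc, lymph) == pytest.approx(expected)

    def test_zero_lymphocytes_is_above_any_threshold(self):
        assert compute_nlr(3000, 0) == NLR_SENTINEL
        assert compute_nlr(3000, 0) > 1.5

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            compute_nlr(-1, 100)


class TestThresholds:
    """Every cutoff is strict: a value exactly at the boundary is normal."""

    @pytest.mark.parametrize(
        "marker,field,boundary,abnormal",
        [
            ("crp_high", "crp_max_mgdl", 0.75, 0.76),
            ("nlr_high", "nlr_max", 1.5, 1.51),
            ("lymphopenia", "lymph_min", 2000.0, 1999.0),
            ("abnormal_neutrophils", "anc_min", 1800.0, 1799.0),
            ("abnormal_neutrophils", "anc_max", 5400.0, 5401.0),
            ("abnormal_wbc", "wbc_min", 5000.0, 4999.0),
            ("abnormal_wbc", "wbc_max", 20000.0, 20001.0),
            ("thrombocytopenia", "platelets_min", 150000.0, 149000.0),
            ("hyperglycemia", "glucose_max_mgdl", 108.0, 109.0),
            ("abnormal_temperature", "temp_min_c", 36.0, 35.9),
            ("abnormal_temperature", "temp_max_c", 37.5, 37.6),
            ("tachycardia", "hr_max_bpm", 186.0, 187.0),
        ],
    )
    def test_boundary_is_normal_and_beyond_is_abnormal(
        self, make_record, marker, field, boundary, abnormal
    ):
        at = derive_markers(make_record(**{field: boundary}))
        beyond = derive_markers(make_record(**{field: abnormal}))
        assert getattr(at, marker) is False
        assert getattr(beyond, marker) is True

    def test_sepsis_group_median_crp_is_elevated(self, make_record):
        assert derive_markers(make_record(crp_max_mgdl=7.0)).crp_high is True

    def test_culture_at_24h_uses_time_to_positivity(self, make_record):
        late = make_record(culture_positive=True, time_to_positivity_h=25.9, sepsis=True)
        early = make_record(culture_positive=True, time_to_positivity_h=24.0, sepsis=True)
        assert derive_markers(late).culture_positive_24h is False
        assert derive_markers(early).culture_positive_24h is True

    def test_sick_appearance_uses_worst_in_window(self, make_record):
        sick_at_0h = make_record(health_score_0h=HealthScore.SICK)
        equivocal = make_record(health_score_24h=HealthScore.EQUIVOCAL)
        assert derive_markers(sick_at_0h).sick_appearing is True
        assert derive_markers(equivocal).sick_appearing is False


class TestMissingness:
    def test_missing_lab_gives_missing_marker_not_false(self, make_record):
        panel = derive_markers(make_record(crp_max_mgdl=None))
        assert panel.crp_high is None

    def test_crp_or_nlr_is_kleene_or(self, make_record):
        p = derive_markers(make_record(crp_max_mgdl=None, nlr_max=6.0))
        assert p.crp_or_nlr is True  # True dominates missing
        q = derive_markers(make_record(crp_max_mgdl=None, nlr_max=0.5))
        assert q.crp_or_nlr is None  # False OR missing stays missing
        assert kleene_or(False, False) is False

    def test_or_identity_holds_when_defined(self, make_record, cohort_5000):
        for rec in cohort_5000[:500]:
            p = derive_markers(rec)
            assert p.crp_or_nlr == kleene_or(p.crp_high, p.nlr_high)
            if p.culture_positive_24h:
                assert rec.culture_positive


class TestRecordInvariants:
    def test_sepsis_requires_positive_culture(self, make_record):
        with pytest.raises(ValueError, match="positive blood culture"):
            make_record(sepsis=True, culture_positive=False)

    def test_ttp_present_iff_culture_positive(self, make_record):
        with pytest.raises(ValueError):
            make_record(time_to_positivity_h=20.0)
        with pytest.raises(ValueError):
            make_record(culture_positive=True, time_to_positivity_h=None)

    def test_gestational_age_range(self, make_record):
        with pytest.raises(ValueError):
            make_record(gestational_age_weeks=20.0)


class TestCsvRoundTrip:
    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_cohort([], path)
        assert read_cohort(path) == []

    def test_round_trip_identity(self, tmp_path, cohort_5000, make_record):
        records = list(cohort_5000[:50])
        records.append(make_record(patient_id="missing-labs", crp_max_mgdl=None,
                                   nlr_max=None, wbc_min=None, wbc_max=None))
        path = tmp_path / "cohort.csv"
        write_cohort(records, path)
        assert read_cohort(path) == records

    def test_generated_cohort_has_expected_composition(self, cohort_5000):
        # fixed case-control margins at the configured prevalence
        n_sepsis = sum(r.sepsis for r in cohort_5000)
        assert n_sepsis == round(5000 * 33 / 105)

    def test_error_reports_row_number(self, tmp_path, make_record):
        path = tmp_path / "bad.csv"
        write_cohort([make_record()], path)
        text = path.read_text().replace("false,,false", "true,,false")  # sepsis w/o culture
        path.write_text(text)
        with pytest.raises(CohortValidationError, match="row 1"):
            read_cohort(path)

    def test_unknown_column_rejected(self, tmp_path, make_record):
        path = tmp_path / "extra.csv"
        write_cohort([make_record()], path)
        lines = path.read_text().splitlines()
        lines[0] += ",bogus"
        lines[1] += ",1"
        path.write_text("\n".join(lines))
        with pytest.raises(CohortValidationError, match="unknown columns"):
            read_cohort(path)


def test_panel_frame_permutes_with_records(cohort_5000):
    sub = cohort_5000[:40]
    direct = panel_frame(sub)
    reversed_ = panel_frame(sub[::-1])
    assert list(direct.columns) == list(MARKER_NAMES)
    assert direct.iloc[::-1].reset_index(drop=True).equals(
        reversed_.reset_index(drop=True)
    )
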