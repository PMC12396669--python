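"""Feature table I/O, session selection, covariate engineering, scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atnorm.cohort import SyntheticConfig, generate_cohort
from atnorm.features import (
    COVARIATE_NAMES,
    DIFFUSION_ROIS,
    FEATURE_SCALES,
    INPUT_FEATURES,
    OUTPUT_FEATURES,
    PERFUSION_ROIS,
    DataError,
    DegenerateNormalizerError,
    ModelInput,
    ModelOutput,
    ParseError,
    SchemaError,
    SubjectRecord,
    engineer_covariates,
    fit_normalizer,
    normalize,
    raw_feature_vector,
    read_feature_table,
    select_session,
    signed_physical_errors,
    write_feature_table,
)


def make_record(subject_id="s1", session_id="ses-01", dataset="CATNAP",
                age=10.0, sex=1, adc_value=800.0, cbf_value=50.0):
    # volumes track age so paired records never have degenerate covariates
    return SubjectRecord(
        subject_id=subject_id,
        dataset=dataset,
        group="control",
        session_id=session_id,
        age=age,
        sex=sex,
        cerebral_volume=1000.0 + 8 * age,
        cerebellar_volume=110.0 + 3 * age,
        adc={r: adc_value for r in DIFFUSION_ROIS},
        cbf={r: cbf_value for r in PERFUSION_ROIS},
    )


class TestSchema:
    def test_feature_order_is_consistent(self):
        assert len(INPUT_FEATURES) == 20
        assert len(OUTPUT_FEATURES) == 13
        assert INPUT_FEATURES[:13] == OUTPUT_FEATURES
        assert INPUT_FEATURES[13:] == COVARIATE_NAMES

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"age": -1.0},
            {"sex": 2},
            {"adc_value": -5.0},
        ],
    )
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(SchemaError):
            make_record(**kwargs)

    def test_roi_sets_enforced(self):
        rec = make_record()
        bad_adc = dict(rec.adc)
        del bad_adc["cwm"]
        with pytest.raises(SchemaError):
            SubjectRecord(
                subject_id="x", dataset="CATNAP", group="control",
                session_id="s", age=5, sex=0, cerebral_volume=1000,
                cerebellar_volume=120, adc=bad_adc, cbf=rec.cbf,
            )


class TestIO:
    def test_write_read_round_trip(self, tmp_path):
        records = generate_cohort(SyntheticConfig(n_controls=5, n_at=3, seed=3))
        path = tmp_path / "cohort.csv"
        write_feature_table(records, path)
        back = read_feature_table(path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.subject_id == b.subject_id
            assert np.allclose(raw_feature_vector(a), raw_feature_vector(b), atol=1e-9)
            assert a.age == pytest.approx(b.age, abs=1e-9)
            if a.nest:
                assert b.nest == pytest.approx(a.nest, abs=1e-9)

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        records = [make_record()]
        path = tmp_path / "cohort.csv"
        write_feature_table(records, path)
        import pandas as pd

        df = pd.read_csv(path).drop(columns=["cbf_caudate"])
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="cbf_caudate"):
            read_feature_table(path)

    def test_non_numeric_value_is_parse_error(self, tmp_path):
        path = tmp_path / "cohort.csv"
        write_feature_table([make_record()], path)
        text = path.read_text().replace("800.0", "oops", 1)
        path.write_text(text)
        with pytest.raises(ParseError):
            read_feature_table(path)

    def test_column_map_renames_headers(self, tmp_path):
        path = tmp_path / "cohort.csv"
        write_feature_table([make_record()], path)
        text = path.read_text().replace("age_years", "AgeAtScan")
        path.write_text(text)
        recs = read_feature_table(path, column_map={"AgeAtScan": "age_years"})
        assert recs[0].age == 10.0

    def test_controls_have_no_nest_scores(self, tmp_path):
        path = tmp_path / "cohort.csv"
        write_feature_table([make_record()], path)
        assert read_feature_table(path)[0].nest is None


class TestSelectSession:
    def test_catnap_keeps_youngest(self):
        recs = [
            make_record(session_id="a", age=7.0),
            make_record(session_id="b", age=5.0),
        ]
        (kept,) = select_session(recs)
        assert kept.age == 5.0

    def test_calgary_keeps_oldest(self):
        recs = [
            make_record(dataset="Calgary", session_id="a", age=3.0),
            make_record(dataset="Calgary", session_id="b", age=6.0),
        ]
        (kept,) = select_session(recs)
        assert kept.age == 6.0

    def test_single_session_identity(self):
        recs = [make_record()]
        assert select_session(recs) == recs

    def test_age_tie_breaks_on_session_id(self):
        recs = [
            make_record(session_id="ses-02", age=5.0),
            make_record(session_id="ses-01", age=5.0),
        ]
        (kept,) = select_session(recs)
        assert kept.session_id == "ses-01"

    def test_duplicate_session_pair_rejected(self):
        recs = [make_record(), make_record()]
        with pytest.raises(DataError):
            select_session(recs)

    def test_idempotent_and_order_independent(self):
        recs = [
            make_record(subject_id="a", session_id="1", age=4.0),
            make_record(subject_id="a", session_id="2", age=6.0),
            make_record(subject_id="b", session_id="1", age=9.0),
        ]
        once = select_session(recs)
        assert select_session(once) == once
        reversed_sel = select_session(list(reversed(recs)))
        assert {r.subject_id: r.session_id for r in reversed_sel} == {
            r.subject_id: r.session_id for r in once
        }


class TestCovariates:
    @given(
        age=st.floats(min_value=0.5, max_value=20, allow_nan=False),
        sex=st.integers(min_value=0, max_value=1),
    )
    @settings(max_examples=50, deadline=None)
    def test_interaction_terms(self, age, sex):
        cov = engineer_covariates(make_record(age=age, sex=sex))
        assert cov.age_sq == age**2
        assert cov.age_sex == age * sex
        assert cov.age_sq_sex == age**2 * sex

    def test_young_patient_age_square(self):
        cov = engineer_covariates(make_record(age=4.6))
        assert cov.age_sq == pytest.approx(21.16)

    def test_male_interactions_vanish(self):
        cov = engineer_covariates(make_record(sex=0))
        assert cov.age_sex == 0 and cov.age_sq_sex == 0


class TestNormalizer:
    def test_minmax_endpoints(self):
        recs = [make_record(subject_id="a", age=3.0, sex=0),
                make_record(subject_id="b", age=18.0, sex=1)]
        norm = fit_normalizer(recs)
        age_idx = COVARIATE_NAMES.index("age")
        assert norm.covariate_min[age_idx] == 3.0
        assert norm.covariate_max[age_idx] == 18.0
        lo = normalize(recs[0], norm).values[13 + age_idx]
        hi = normalize(recs[1], norm).values[13 + age_idx]
        assert lo == 0.0 and hi == 1.0

    def test_fixed_imaging_scales(self):
        recs = [make_record(subject_id="a", age=3.0, sex=0),
                make_record(subject_id="b", age=18.0, sex=1)]
        norm = fit_normalizer(recs)
        assert norm.diffusion_scale == 3000.0
        assert norm.perfusion_scale == 100.0

    def test_single_subject_is_degenerate(self):
        with pytest.raises(DegenerateNormalizerError):
            fit_normalizer([make_record()])

    def test_imaging_scaling_constants(self):
        recs = [make_record(subject_id="a", age=3.0, sex=0, adc_value=1500.0, cbf_value=50.0),
                make_record(subject_id="b", age=18.0, sex=1)]
        norm = fit_normalizer(recs)
        inp = normalize(recs[0], norm)
        assert np.allclose(inp.values[6:13], 0.5)  # ADC 1500 / 3000
        assert np.allclose(inp.values[:6], 0.5)  # CBF 50 / 100

    def test_out_of_range_covariates_not_clipped(self):
        recs = [make_record(subject_id="a", age=3.0, sex=0),
                make_record(subject_id="b", age=10.0, sex=1)]
        norm = fit_normalizer(recs)
        older = make_record(subject_id="c", age=17.0)
        val = normalize(older, norm).values[13 + COVARIATE_NAMES.index("age")]
        assert val > 1.0

    def test_scale_round_trip_exact(self):
        recs = generate_cohort(SyntheticConfig(n_controls=10, n_at=2, seed=4))
        norm = fit_normalizer(recs[:8])
        for rec in recs:
            inp = normalize(rec, norm)
            assert np.allclose(
                inp.values[:13] * FEATURE_SCALES,
                raw_feature_vector(rec),
                rtol=1e-15,
                atol=0,
            )


class TestSignedErrors:
    def test_caudate_perfusion_scaling(self):
        recs = [make_record(subject_id="a", age=3.0, sex=0),
                make_record(subject_id="b", age=18.0, sex=1)]
        norm = fit_normalizer(recs)
        inp = normalize(recs[0], norm)
        out_vals = inp.values[:13].copy()
        out_vals[0] += 0.058  # caudate perfusion, normalized
        errs = signed_physical_errors(ModelOutput(values=out_vals), inp)
        assert errs[0] == pytest.approx(5.8)
        assert np.allclose(errs[1:], 0.0)

    def test_cerebellar_diffusion_scaling(self):
        recs = [make_record(subject_id="a", age=3.0, sex=0),
                make_record(subject_id="b", age=18.0, sex=1)]
        norm = fit_normalizer(recs)
        inp = normalize(recs[0], norm)
        out_vals = inp.values[:13].copy()
        cgm = OUTPUT_FEATURES.index("adc_cgm")
        out_vals[cgm] -= 0.1843
        errs = signed_physical_errors(ModelOutput(values=out_vals), inp)
        assert errs[cgm] == pytest.approx(-553, abs=1.0)

    def test_perfect_reconstruction_zero_errors(self):
        recs = [make_record(subject_id="a", age=3.0, sex=0),
                make_record(subject_id="b", age=18.0, sex=1)]
        norm = fit_normalizer(recs)
        inp = normalize(recs[0], norm)
        errs = signed_physical_errors(ModelOutput(values=inp.values[:13].copy()), inp)
        assert np.allclose(errs, 0.0)

    def test_vector_length_contracts(self):
        with pytest.raises(ValueError):
            ModelInput(values=np.zeros(19))
        with pytest.raises(ValueError):
            ModelOutput(values=np.zeros(14))
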