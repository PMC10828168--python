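"""Elastic-net clocks: filtering, fitting, prediction, cross-validation."""

import numpy as np
import pytest

from frogclock.age import AgeTransformSpec, loglinear_forward
from frogclock.clocks import (
    CLOCK_SPECS,
    ClockModel,
    ClockSpec,
    clock_spec,
    cross_validate,
    evaluate,
    filter_detectable,
    fit_clock,
    predict_age,
    read_clock,
    write_clock,
)
from frogclock.io import (
    BetaMatrix,
    MethylationCohort,
    SampleRecord,
    ValidationError,
    default_registry,
)


def make_cohort(values, ages, species="laevis", ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(values.shape[1])]
    bm = BetaMatrix([f"cg{i}" for i in range(values.shape[0])], ids, values)
    samples = [
        SampleRecord(s, species, "skin", float(a)) for s, a in zip(ids, ages)
    ]
    return MethylationCohort(bm, samples)


def signal_cohort(n=24, seed=0, species="laevis"):
    """Noise-free cohort whose first CpG is an exact affine image of the
    clock response (chronological age for the single-species clock);
    remaining CpGs are age-independent filler."""
    rng = np.random.default_rng(seed)
    ages = np.linspace(0.3, 1.5, n)
    signal = (ages - ages.min()) / (ages.max() - ages.min()) * 0.8 + 0.1
    filler = rng.uniform(0.2, 0.8, size=(30, 1)) * np.ones((30, n))
    values = np.vstack([signal[None, :], filler])
    return make_cohort(values, ages, species=species)


class TestFilterDetectable:
    def test_saturated_cpg_removed(self):
        cohort = make_cohort(
            [[0.0, 0.0, 0.0], [0.4, 0.5, 0.6]], [1, 2, 3]
        )
        kept = filter_detectable(cohort, 0.05, 0.95)
        assert kept.beta.cpg_ids == ["cg1"]

    def test_full_bounds_identity(self):
        cohort = make_cohort([[0.0, 1.0], [0.5, 0.6]], [1, 2])
        assert filter_detectable(cohort, 0.0, 1.0).beta.cpg_ids == ["cg0", "cg1"]

    def test_three_cpg_hand_example(self):
        # means 0.02 / 0.5 / 0.97 with bounds (0.05, 0.95): one survivor
        cohort = make_cohort(
            [[0.02, 0.02], [0.4, 0.6], [0.96, 0.98]], [1, 2]
        )
        kept = filter_detectable(cohort, 0.05, 0.95)
        assert kept.beta.cpg_ids == ["cg1"]

    def test_empty_result_advises_bounds(self):
        cohort = make_cohort([[0.0, 0.0]], [1, 2])
        with pytest.raises(ValidationError, match="bounds"):
            filter_detectable(cohort, 0.4, 0.6)

    def test_bad_bounds_rejected(self):
        cohort = make_cohort([[0.5, 0.5]], [1, 2])
        with pytest.raises(ValueError):
            filter_detectable(cohort, 0.9, 0.1)


class TestFitClock:
    def test_perfect_signal_recovered(self, registry):
        """With one CpG an exact affine image of transformed age and no
        noise, in-sample predictions reproduce ages to < 0.01 y."""
        cohort = signal_cohort()
        model = fit_clock(cohort, clock_spec("laevis"), registry, seed=1)
        preds = predict_age(model, cohort, registry)
        np.testing.assert_allclose(preds.to_numpy(), cohort.ages, atol=0.01)

    def test_determinism(self, small_cohort, registry):
        cohort, _, _ = small_cohort
        a = fit_clock(cohort, clock_spec("pan"), registry, seed=3)
        b = fit_clock(cohort, clock_spec("pan"), registry, seed=3)
        assert a.cpg_ids == b.cpg_ids
        np.testing.assert_array_equal(a.coefficients, b.coefficients)
        assert a.intercept == b.intercept

    def test_sample_permutation_invariance(self, small_cohort, registry):
        cohort, _, _ = small_cohort
        rng = np.random.default_rng(0)
        perm = rng.permutation(cohort.n_samples)
        ids = [cohort.samples[i].sample_id for i in perm]
        shuffled = MethylationCohort(
            cohort.beta.subset_samples(ids), [cohort.samples[i] for i in perm]
        )
        base = fit_clock(cohort, clock_spec("pan"), registry, seed=1)
        alt = fit_clock(shuffled, clock_spec("pan"), registry, seed=1)
        # fitting canonicalises sample order, so the model — and hence every
        # per-sample prediction — is identical under permutation
        assert alt.cpg_ids == base.cpg_ids
        np.testing.assert_array_equal(alt.coefficients, base.coefficients)
        p0 = predict_age(base, cohort, registry).sort_index()
        p1 = predict_age(alt, cohort, registry).sort_index()
        np.testing.assert_array_equal(p0.to_numpy(), p1.to_numpy())

    def test_too_few_samples_rejected(self, registry):
        cohort = make_cohort(np.full((5, 6), 0.5), np.arange(1, 7))
        with pytest.raises(ValidationError, match="samples"):
            fit_clock(cohort, clock_spec("laevis"), registry, seed=0)

    def test_unknown_species_rejected(self, registry):
        cohort = signal_cohort(species="laevis")
        spec = ClockSpec("custom", ("martian",), "loglinear")
        with pytest.raises(ValidationError):
            fit_clock(cohort, spec, registry, seed=0)


class TestPredictAge:
    def test_intercept_only_model_predicts_constant(self, registry):
        cohort = signal_cohort()
        transform = AgeTransformSpec.from_registry(
            "loglinear", registry, ["laevis"]
        )
        model = ClockModel(
            name="pan", cpg_ids=[], coefficients=np.array([]),
            intercept=float(transform.forward(5.0, "laevis")),
            transform=transform, n_train=0, species=("laevis",),
            seed=0, penalty=0.0, n_input_cpgs=0,
        )
        preds = predict_age(model, cohort, registry)
        np.testing.assert_allclose(preds.to_numpy(), 5.0, atol=1e-9)

    def test_relative_score_is_species_free(self, registry):
        values = np.full((1, 2), 0.5)
        bm = BetaMatrix(["cg0"], ["f", "h"], values)
        samples = [
            SampleRecord("f", "tropicalis", "skin", 2.0),
            SampleRecord("h", "human", "blood", 50.0),
        ]
        cohort = MethylationCohort(bm, samples)
        transform = AgeTransformSpec.from_registry(
            "relative", registry, ["tropicalis", "human"]
        )
        model = ClockModel(
            name="dual_relative", cpg_ids=[], coefficients=np.array([]),
            intercept=0.5, transform=transform, n_train=0,
            species=("human", "tropicalis"), seed=0, penalty=0.0,
            n_input_cpgs=0,
        )
        preds = predict_age(model, cohort, registry)
        assert preds["f"] == preds["h"] == pytest.approx(0.5)

    def test_missing_model_cpg_rejected(self, registry):
        cohort = signal_cohort()
        transform = AgeTransformSpec.from_registry("loglinear", registry, ["laevis"])
        model = ClockModel(
            name="pan", cpg_ids=["cg_missing"], coefficients=np.array([1.0]),
            intercept=0.0, transform=transform, n_train=0,
            species=("laevis",), seed=0, penalty=0.0, n_input_cpgs=1,
        )
        with pytest.raises(ValidationError, match="cg_missing"):
            predict_age(model, cohort, registry)

    def test_training_predictions_match_fit(self, small_cohort, registry):
        cohort, _, _ = small_cohort
        model = fit_clock(cohort, clock_spec("pan"), registry, seed=1)
        p1 = predict_age(model, cohort, registry)
        p2 = predict_age(model, cohort, registry)
        np.testing.assert_array_equal(p1.to_numpy(), p2.to_numpy())


class TestCrossValidate:
    def test_one_prediction_per_sample(self, small_cohort, registry):
        cohort, _, _ = small_cohort
        cv = cross_validate(cohort, clock_spec("pan"), registry, seed=1)
        assert len(cv.predictions) == cohort.n_samples
        assert not cv.predictions.isna().any()
        assert -1 <= cv.pearson_r <= 1
        assert cv.median_abs_error >= 0

    def test_loo_held_out_independence(self, small_cohort, registry):
        """Corrupting sample i's age label must not move sample i's LOO
        prediction: the model predicting i never saw i."""
        cohort, _, _ = small_cohort
        target = cohort.samples[5].sample_id
        cv = cross_validate(cohort, clock_spec("pan"), registry, seed=1)

        tampered = list(cohort.samples)
        s = tampered[5]
        tampered[5] = SampleRecord(s.sample_id, s.species, s.tissue,
                                   s.age_years + 3.0, s.sex, s.cohort)
        cohort2 = MethylationCohort(cohort.beta, tampered)
        cv2 = cross_validate(cohort2, clock_spec("pan"), registry, seed=1)
        assert cv2.predictions[target] == pytest.approx(
            cv.predictions[target], abs=1e-9
        )

    def test_loo_beats_permuted_ages(self, small_cohort, registry):
        """Permutation null: LOO R on real labels far exceeds the R after
        shuffling ages (which should hover near zero)."""
        cohort, _, _ = small_cohort
        cv = cross_validate(cohort, clock_spec("pan"), registry, seed=1)
        rng = np.random.default_rng(2)
        perm = rng.permutation(cohort.n_samples)
        shuffled = [
            SampleRecord(s.sample_id, s.species, s.tissue,
                         cohort.samples[j].age_years, s.sex, s.cohort)
            for s, j in zip(cohort.samples, perm)
        ]
        cv_null = cross_validate(
            MethylationCohort(cohort.beta, shuffled),
            clock_spec("pan"), registry, seed=1,
        )
        assert cv.pearson_r > 0.8
        assert cv.pearson_r > cv_null.pearson_r + 0.4
        assert abs(cv_null.pearson_r) < 0.45

    def test_kfold_assignment_stratified_and_seeded(self, registry):
        rng = np.random.default_rng(4)
        n_frog, n_human = 24, 40
        values = rng.uniform(0.2, 0.8, size=(60, n_frog + n_human))
        ids = [f"s{i}" for i in range(n_frog + n_human)]
        bm = BetaMatrix([f"cg{i}" for i in range(60)], ids, values)
        samples = [
            SampleRecord(
                ids[i],
                "laevis" if i < n_frog else "human",
                "skin",
                float(rng.uniform(0.1, 15 if i < n_frog else 90)),
            )
            for i in range(n_frog + n_human)
        ]
        cohort = MethylationCohort(bm, samples)
        cv = cross_validate(cohort, clock_spec("dual_chrono"), registry, seed=5)
        folds = cv.folds
        frog_ids = [s.sample_id for s in samples if s.cohort == "frog"]
        for f in sorted(folds.unique()):
            members = folds[folds == f].index
            assert any(m in frog_ids for m in members)
        cv2 = cross_validate(cohort, clock_spec("dual_chrono"), registry, seed=5)
        assert (cv2.folds == folds).all()

    def test_relative_metrics_scale_with_lifespan_single_species(
        self, small_cohort, registry
    ):
        """One species, identity vs relative response: rescaling the
        response by 1/L leaves R essentially unchanged and divides the MAE
        by the lifespan L (up to penalty-grid discreteness in the inner CV;
        the relation breaks entirely once a second species with its own L
        enters)."""
        cohort, _, _ = small_cohort
        laevis = cohort.select_samples(cohort.species == "laevis")
        cv_years = cross_validate(laevis, clock_spec("laevis"), registry, seed=1)
        rel_spec = ClockSpec("laevis_relative", ("laevis",), "relative", "loo")
        cv_rel = cross_validate(laevis, rel_spec, registry, seed=1)
        L = registry["laevis"].max_lifespan_years
        assert cv_rel.pearson_r == pytest.approx(cv_years.pearson_r, abs=0.03)
        assert cv_rel.median_abs_error == pytest.approx(
            cv_years.median_abs_error / L, rel=0.3
        )

    def test_young_spec_filters_by_age(self, small_cohort, registry):
        cohort, _, _ = small_cohort
        cv = cross_validate(cohort, clock_spec("young"), registry, seed=1)
        ages = {s.sample_id: s.age_years for s in cohort.samples}
        assert all(ages[sid] < 2.0 for sid in cv.predictions.index)


class TestEvaluate:
    def test_perfect_prediction(self):
        r, mae = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r, mae) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_offset_shifts_mae_not_r(self):
        r, mae = evaluate([3.0, 4.0, 5.0], [1.0, 2.0, 3.0])
        assert r == pytest.approx(1.0)
        assert mae == pytest.approx(2.0)

    def test_reversed_order(self):
        r, mae = evaluate([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert r == pytest.approx(-1.0)
        assert mae == pytest.approx(2.0)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValidationError):
            evaluate([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])


class TestClockSerialisation:
    def test_round_trip(self, small_cohort, registry, tmp_path):
        cohort, _, _ = small_cohort
        model = fit_clock(cohort, clock_spec("pan"), registry, seed=1)
        path = tmp_path / "clock_pan.tsv"
        write_clock(model, path)
        back = read_clock(path)
        assert back.cpg_ids == model.cpg_ids
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        assert back.intercept == model.intercept
        assert back.transform == model.transform
        p0 = predict_age(model, cohort, registry)
        p1 = predict_age(back, cohort, registry)
        np.testing.assert_array_equal(p0.to_numpy(), p1.to_numpy())

    def test_seven_specs_defined(self):
        assert set(CLOCK_SPECS) == {
            "pan", "relative_pan", "young", "laevis", "tropicalis",
            "dual_chrono", "dual_relative",
        }
        assert CLOCK_SPECS["young"].max_age == 2.0
        for name in ("pan", "relative_pan", "young", "laevis", "tropicalis"):
            assert CLOCK_SPECS[name].cv == "loo"
        for name in ("dual_chrono", "dual_relative"):
            assert CLOCK_SPECS[name].cv == "kfold"
            assert CLOCK_SPECS[name].n_folds == 10
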