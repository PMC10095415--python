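"""Bracket construction, classifier training, and importance extraction."""

import numpy as np
import pytest

from strokeage.features import FeatureDef, FeatureDictionary
from strokeage.io import Label, PatientRecord, Sex
from strokeage.models import (
    Algorithm,
    BracketSpec,
    CVConfig,
    extract_importance,
    make_brackets,
    default_brackets,
    run_model_grid,
    train_bracket_model,
)

FAST_CV = CVConfig(folds=3, repeats=1, grid_size=2)


def _patient(pid, label, sex=Sex.F, age=50.0, **feats):
    return PatientRecord(pid, sex, age, label, 25.0, feats)


def separable_cohort(n=1000, p_case=0.9, p_control=0.1, seed=0, sex=Sex.F):
    """Strongly separable data: three independent informative features
    (case prevalence ``p_case`` vs control ``p_control`` each; a single
    binary feature caps AUROC at 0.90, three push it near 0.99) plus two
    noise features."""
    rng = np.random.default_rng(seed)
    patients = []
    for i in range(n):
        label = Label.case if i < n // 2 else Label.control
        p = p_case if label is Label.case else p_control
        patients.append(
            _patient(
                f"p{i}", label, sex=sex, age=float(rng.uniform(30, 80)),
                signal=int(rng.random() < p),
                signal_b=int(rng.random() < p),
                signal_c=int(rng.random() < p),
                noise_a=int(rng.random() < 0.5),
                noise_b=int(rng.random() < 0.5),
            )
        )
    dictionary = FeatureDictionary.from_defs(
        [FeatureDef("signal", "s"), FeatureDef("signal_b", "sb"),
         FeatureDef("signal_c", "sc"), FeatureDef("noise_a", "na"),
         FeatureDef("noise_b", "nb")]
    )
    return patients, dictionary


class TestMakeBrackets:
    def test_strict_upper_bound(self):
        patients = [
            _patient("a", Label.case, age=54.9),
            _patient("b", Label.case, age=55.0),
            _patient("c", Label.control, age=40.0),
        ]
        cases, controls = make_brackets(patients, BracketSpec(55.0), Sex.F)
        assert [p.patient_id for p in cases] == ["a"]

    def test_controls_age_filtered_by_default(self):
        patients = [
            _patient("a", Label.case, age=45.0),
            _patient("b", Label.control, age=70.0),
            _patient("c", Label.control, age=40.0),
        ]
        _, controls = make_brackets(patients, BracketSpec(55.0), Sex.F)
        assert [p.patient_id for p in controls] == ["c"]
        _, unfiltered = make_brackets(
            patients, BracketSpec(55.0), Sex.F, filter_controls=False
        )
        assert len(unfiltered) == 2

    def test_empty_class_errors(self):
        patients = [_patient("a", Label.case, age=45.0)]
        with pytest.raises(ValueError, match="empty class"):
            make_brackets(patients, BracketSpec(55.0), Sex.F)

    def test_default_grid_has_17_age_limited_brackets(self):
        brackets = default_brackets()
        uppers = [b.upper_age for b in brackets if b.upper_age is not None]
        assert len(uppers) == 17
        assert uppers == sorted(uppers)
        assert sum(1 for b in brackets if b.upper_age is None) == 1


class TestTrainBracketModel:
    @pytest.mark.parametrize("algorithm", list(Algorithm))
    def test_separable_data_high_auroc(self, algorithm):
        patients, dictionary = separable_cohort(seed=1)
        cases = [p for p in patients if p.label is Label.case]
        controls = [p for p in patients if p.label is Label.control]
        res = train_bracket_model(cases, controls, algorithm, dictionary, cv=FAST_CV, seed=1)
        assert res.auroc >= 0.95
        assert max(
            res.importance["signal"], res.importance["signal_b"], res.importance["signal_c"]
        ) == 100.0
        assert max(res.importance["noise_a"], res.importance["noise_b"]) < 50.0

    @pytest.mark.parametrize("algorithm", list(Algorithm))
    def test_label_permutation_is_chance_level(self, algorithm):
        patients, dictionary = separable_cohort(seed=2)
        rng = np.random.default_rng(2)
        order = rng.permutation(len(patients))
        permuted = [
            PatientRecord(p.patient_id, p.sex, p.age_at_index,
                          patients[j].label, p.bmi, p.features)
            for p, j in zip(patients, order)
        ]
        cases = [p for p in permuted if p.label is Label.case]
        controls = [p for p in permuted if p.label is Label.control]
        res = train_bracket_model(cases, controls, algorithm, dictionary, cv=FAST_CV, seed=2)
        assert 0.40 <= res.auroc <= 0.60

    def test_single_class_errors(self):
        patients, dictionary = separable_cohort(n=100, seed=3)
        cases = [p for p in patients if p.label is Label.case]
        with pytest.raises(ValueError, match="nonempty"):
            train_bracket_model(cases, [], Algorithm.GLM, dictionary, seed=3)

    def test_constant_features_error(self):
        dictionary = FeatureDictionary.from_defs([FeatureDef("flat", "f")])
        cases = [_patient(f"c{i}", Label.case, flat=0) for i in range(30)]
        controls = [_patient(f"k{i}", Label.control, flat=0) for i in range(30)]
        with pytest.raises(ValueError, match="constant"):
            train_bracket_model(cases, controls, Algorithm.GLM, dictionary, cv=FAST_CV, seed=0)

    def test_determinism(self):
        patients, dictionary = separable_cohort(n=300, seed=4)
        cases = [p for p in patients if p.label is Label.case]
        controls = [p for p in patients if p.label is Label.control]
        a = train_bracket_model(cases, controls, Algorithm.XGB, dictionary, cv=FAST_CV, seed=9)
        b = train_bracket_model(cases, controls, Algorithm.XGB, dictionary, cv=FAST_CV, seed=9)
        assert a.auroc == b.auroc and a.importance == b.importance


class TestExtractImportance:
    def test_max_normalisation_to_100(self):
        patients, dictionary = separable_cohort(seed=5)
        cases = [p for p in patients if p.label is Label.case]
        controls = [p for p in patients if p.label is Label.control]
        for algorithm in Algorithm:
            res = train_bracket_model(cases, controls, algorithm, dictionary, cv=FAST_CV, seed=5)
            values = np.array(list(res.importance.values()))
            assert values.max() == pytest.approx(100.0)
            assert (values >= 0).all()

    def test_xgb_unused_feature_has_zero_gain(self):
        # one overwhelming feature, one pure-noise feature rarely split on
        rng = np.random.default_rng(6)
        dictionary = FeatureDictionary.from_defs(
            [FeatureDef("signal", "s"), FeatureDef("never", "n")]
        )
        patients = []
        for i in range(400):
            label = Label.case if i < 200 else Label.control
            patients.append(
                _patient(f"p{i}", label, age=float(rng.uniform(30, 80)),
                         signal=int(label is Label.case), never=0)
            )
        # 'never' is constant -> cannot be split on; 'signal' is perfect
        cases = [p for p in patients if p.label is Label.case]
        controls = [p for p in patients if p.label is Label.control]
        res = train_bracket_model(cases, controls, Algorithm.XGB, dictionary, cv=FAST_CV, seed=6)
        assert res.importance["never"] == 0.0

    def test_length_mismatch_rejected(self):
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(0)
        model = RandomForestClassifier(n_estimators=5, random_state=0)
        model.fit(rng.random((40, 3)), rng.integers(0, 2, 40))
        with pytest.raises(ValueError, match="length"):
            extract_importance(model, Algorithm.RF, ["a"])


class TestRunModelGrid:
    def test_small_grid_arithmetic_and_determinism(self):
        patients, dictionary = separable_cohort(n=600, seed=7)
        brackets = [BracketSpec(60.0), BracketSpec(70.0), BracketSpec(None)]
        results, errors = run_model_grid(
            patients, dictionary, algorithms=(Algorithm.GLM,), brackets=brackets,
            sexes=(Sex.F,), cv=FAST_CV, seed=3,
        )
        assert not errors
        assert len(results) == 3
        results2, _ = run_model_grid(
            patients, dictionary, algorithms=(Algorithm.GLM,), brackets=brackets,
            sexes=(Sex.F,), cv=FAST_CV, seed=3,
        )
        assert [r.auroc for r in results] == [r.auroc for r in results2]

    def test_failed_reference_model_aborts(self):
        patients, dictionary = separable_cohort(n=30, seed=8)  # below min class size
        with pytest.raises(RuntimeError, match="reference"):
            run_model_grid(
                patients, dictionary, algorithms=(Algorithm.GLM,),
                brackets=[BracketSpec(None)], sexes=(Sex.F,), cv=FAST_CV, seed=0,
            )

    def test_failed_age_bracket_is_collected_not_fatal(self):
        patients, dictionary = separable_cohort(n=600, seed=9)
        brackets = [BracketSpec(31.0), BracketSpec(None)]  # <31 has too few subjects
        results, errors = run_model_grid(
            patients, dictionary, algorithms=(Algorithm.GLM,), brackets=brackets,
            sexes=(Sex.F,), cv=FAST_CV, seed=0,
        )
        assert len(results) == 1 and len(errors) == 1
        assert "GLM/F/<31" in errors
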