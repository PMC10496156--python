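"""Wrapper-GA fitness arithmetic, subset evaluation and evolution."""

import math

import numpy as np
import pytest

from fhpdetect.errors import EmptySubsetError
from fhpdetect.features import FEATURE_COLUMNS
from fhpdetect.ga_select import (
    Chromosome, FitnessContext, GAConfig, WORST_FITNESS, evaluate_subset,
    fitness, run_ga, select_features_across_models,
)
from fhpdetect.classify import ModelSpec
from fhpdetect.synth_cohort import CohortParams, simulate_feature_table

P = 12


def _chrom(bits):
    mask = np.zeros(P, dtype=bool)
    mask[list(bits)] = True
    return Chromosome(mask)


def _ctx(N, n, m, **kw):
    arr = np.zeros(P)
    arr[: len(N)] = N
    return FitnessContext(P=P, N=arr, n=n, m=m, **kw)


class TestFitnessArithmetic:
    def test_literal_formula_worked_example(self):
        # ((5+3)/12 + (ln 100 - ln 90)) / 2, computed independently
        expected = ((5 + 3) / 12 + (math.log(100) - math.log(90))) / 2
        assert expected == pytest.approx(0.3860135911622467, abs=1e-12)
        got = fitness(_chrom([0, 1]), _ctx([5, 3], 100, 90, orientation="paper_literal"))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_perfect_predictions_cancel_performance_term(self):
        for orientation in ("paper_literal", "accuracy_rewarding"):
            got = fitness(_chrom([0, 1]), _ctx([5, 3], 100, 100, orientation=orientation))
            assert got == pytest.approx(1 / 3, abs=1e-12)

    def test_linearity_in_scale_factor(self):
        base = fitness(_chrom([0, 1]), _ctx([5, 3], 100, 90))
        doubled = fitness(_chrom([0, 1]), _ctx([5, 3], 100, 90, C=2.0))
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_empty_subset_raises(self):
        with pytest.raises(EmptySubsetError):
            fitness(Chromosome(np.zeros(P, dtype=bool)), _ctx([], 10, 5))

    def test_zero_correct_predictions_get_worst_fitness(self):
        assert fitness(_chrom([0]), _ctx([5], 100, 0)) == WORST_FITNESS

    def test_decreasing_in_subset_size_at_fixed_counters(self):
        # adding a zero-count feature holds N and the performance term fixed
        vals = [fitness(_chrom(range(k)), _ctx([6, 0, 0, 0], 100, 100))
                for k in (1, 2, 3, 4)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_accuracy_rewarding_increases_in_m(self):
        vals = [fitness(_chrom([0, 1]), _ctx([5, 3], 100, m)) for m in (50, 70, 90, 100)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_log10_base_option(self):
        got = fitness(_chrom([0, 1]), _ctx([5, 3], 100, 90, log_base="10",
                                           orientation="paper_literal"))
        expected = ((8 / 12) + (math.log10(100) - math.log10(90))) / 2
        assert got == pytest.approx(expected, abs=1e-12)


class TestEvaluateSubset:
    def test_separable_data_recovers_every_reference_sample(self, separable_table, fast_etc):
        mask = np.array([c == "NAH" for c in FEATURE_COLUMNS])
        m = evaluate_subset(separable_table, mask, fast_etc, folds=4, seed=0,
                            reference_class=0)
        assert m == int((separable_table.label == 0).sum())

    def test_permutation_null_recall_equals_predicted_rate(self, small_cohort, fast_etc):
        """With labels shuffled, predictions are independent of the truth,
        so each class's recall must match the overall rate at which that
        class is predicted (and carry no real signal)."""
        from fhpdetect.classify import cross_validate

        rng = np.random.default_rng(0)
        mask = np.ones(P, dtype=bool)
        gaps = []
        for s in range(5):
            shuffled = small_cohort.copy().reset_index(drop=True)
            shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
            res = cross_validate(shuffled, fast_etc, k=5, seed=s)
            y = shuffled["label"].to_numpy()
            m = evaluate_subset(shuffled, mask, fast_etc, folds=5, seed=s,
                                reference_class=0)
            recall0 = m / int((y == 0).sum())
            predicted0 = float(np.mean(res.predictions == 0))
            gaps.append(recall0 - predicted0)
        assert abs(np.mean(gaps)) < 0.05

    def test_informative_mask_beats_noise_mask(self, small_cohort, fast_etc):
        angle_mask = np.array([c in ("NAH", "ENA", "PAH", "EAH") for c in FEATURE_COLUMNS])
        noise_mask = np.array([c in ("age", "height", "weight") for c in FEATURE_COLUMNS])
        wins = 0
        for s in range(5):
            m_angle = evaluate_subset(small_cohort, angle_mask, fast_etc, folds=5, seed=s)
            m_noise = evaluate_subset(small_cohort, noise_mask, fast_etc, folds=5, seed=s)
            wins += m_angle > m_noise
        assert wins >= 4

    def test_deterministic_for_fixed_seed(self, small_cohort, fast_etc):
        mask = np.ones(P, dtype=bool)
        a = evaluate_subset(small_cohort, mask, fast_etc, folds=5, seed=3)
        b = evaluate_subset(small_cohort, mask, fast_etc, folds=5, seed=3)
        assert a == b


@pytest.fixture(scope="module")
def tiny_table():
    return simulate_feature_table(CohortParams(n_subjects=80, seed=5))


@pytest.fixture(scope="module")
def tiny_cfg():
    return GAConfig(seed=1, population_size=8, generations=3, inner_cv_folds=3)


class TestRunGa:
    def test_same_seed_gives_identical_history(self, tiny_table, fast_etc, tiny_cfg):
        m1, r1 = run_ga(tiny_table, fast_etc, tiny_cfg)
        m2, r2 = run_ga(tiny_table, fast_etc, tiny_cfg)
        assert np.array_equal(m1, m2)
        assert r1["history"] == r2["history"]

    def test_zero_generations_returns_best_of_initial_population(self, tiny_table, fast_etc):
        cfg = GAConfig(seed=2, population_size=6, generations=0, inner_cv_folds=3)
        mask, rep = run_ga(tiny_table, fast_etc, cfg)
        assert len(rep["history"]) == 1
        assert mask.any()

    def test_never_returns_empty_mask_and_history_best_monotone(self, tiny_table, fast_etc, tiny_cfg):
        mask, rep = run_ga(tiny_table, fast_etc, tiny_cfg)
        assert mask.any()
        best = [h["best_fitness"] for h in rep["history"]]
        assert all(b >= a - 1e-12 for a, b in zip(best, best[1:]))

    def test_counters_update_even_on_cache_hits(self, tiny_table, fast_etc, tiny_cfg):
        _, rep = run_ga(tiny_table, fast_etc, tiny_cfg)
        assert rep["meta"]["evaluations"] >= rep["meta"]["distinct_subsets"]
        # 8 initial + 3 generations x 6 non-elite children
        assert rep["meta"]["evaluations"] == 8 + 3 * (8 - 2)


class TestSelectAcrossModels:
    def test_single_model_reduces_to_run_ga(self, tiny_table, fast_etc, tiny_cfg):
        mask_direct, _ = run_ga(tiny_table, fast_etc, tiny_cfg)
        spec, mask, report = select_features_across_models(
            tiny_table, [fast_etc], tiny_cfg)
        assert spec == fast_etc
        assert np.array_equal(mask, mask_direct)
        assert report["winner_index"] == 0

    def test_identical_specs_tie_broken_by_list_order(self, tiny_table, fast_etc, tiny_cfg):
        twin = ModelSpec.make("extremely_randomized_trees", 0, name="twin", n_estimators=12)
        cfg = GAConfig(seed=1, population_size=8, generations=2, inner_cv_folds=3)
        # same underlying estimator; per-model GA seeds differ, so force the
        # tie by giving both the same derived seed via a single-generation run
        spec, _, report = select_features_across_models(tiny_table, [fast_etc, fast_etc], cfg)
        assert report["winner_index"] == 0
        assert spec is not twin
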