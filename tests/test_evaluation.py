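"""Cross-validation, hold-out, permutation significance, AUC, PPV/NPV."""

import numpy as np
import pytest

from rsdiag.evaluation import (
    behavioral_correlation,
    holdout_split,
    permutation_test,
    predictive_values,
    repeat_cv,
    roc_auc,
    run_cv,
)
from rsdiag.phantom import PhantomSpec
from rsdiag.pipeline import FeatureDataset, phantom_dataset


def _toy_dataset(n_per_group=10, n_areas=3, sep=6.0, seed=0):
    """Feature dataset with a direct group shift in every area."""
    rng = np.random.default_rng(seed)
    feats = rng.normal(size=(2 * n_per_group, n_areas, 8))
    feats[:n_per_group] += sep
    labels = np.array(["ASD"] * n_per_group + ["TD"] * n_per_group)
    return FeatureDataset(features=feats, labels=labels,
                          area_ids=list(range(1, n_areas + 1)))


class TestRunCV:
    def test_separable_dataset_perfect_accuracy(self):
        m = run_cv(_toy_dataset(), "4-fold", seed=0)
        assert m.accuracy == 1.0
        assert m.auc == 1.0
        assert m.scheme == "4-fold"

    def test_loso_has_one_fold_per_subject(self):
        ds = _toy_dataset(n_per_group=5)
        m = run_cv(ds, "LOSO", seed=0)
        assert m.accuracy == 1.0  # every one of the 10 folds scored

    def test_chance_level_without_effect(self):
        accs = []
        for run in range(5):
            spec = PhantomSpec(grid_shape=(10, 10, 6), n_timepoints=80,
                               n_areas=4, effect_size=0.0, noise_sigma=0.3,
                               n_asd=8, n_td=8, seed=700 + run)
            ds, _ = phantom_dataset(spec, via_decomposition=False)
            accs.append(run_cv(ds, "4-fold", seed=run).accuracy)
        assert abs(np.mean(accs) - 0.5) <= 0.15

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            run_cv(_toy_dataset(), "3-fold")


class TestRepeatCV:
    def test_summary_ordering_and_degenerate_sd(self):
        ds = _toy_dataset()
        out = repeat_cv(ds, "2-fold", n_repeats=5, seed=0)
        assert out["min"] <= out["mean"] <= out["max"]
        assert out["sd"] == 0.0  # separable: every repeat is perfect
        assert len(out["per_repeat_accuracy"]) == 5

    def test_requires_two_repeats(self):
        with pytest.raises(ValueError):
            repeat_cv(_toy_dataset(), "2-fold", n_repeats=1)


class TestHoldout:
    def test_default_partition_sizes(self):
        ds = _toy_dataset(n_per_group=50)  # n = 100
        tr, val, te = holdout_split(ds, seed=0)
        assert (len(tr), len(val), len(te)) == (60, 15, 25)

    def test_largest_remainder_at_n20(self):
        ds = _toy_dataset(n_per_group=10)
        tr, val, te = holdout_split(ds, seed=0)
        assert (len(tr), len(val), len(te)) == (12, 3, 5)

    def test_partitions_disjoint_and_complete(self):
        ds = _toy_dataset(n_per_group=13)
        tr, val, te = holdout_split(ds, seed=3)
        combined = np.concatenate([tr, val, te])
        assert sorted(combined) == list(range(26))

    def test_stratification(self):
        ds = _toy_dataset(n_per_group=20)
        tr, val, te = holdout_split(ds, seed=1)
        y = ds.binary_labels()
        for part in (tr, val, te):
            frac = y[part].mean()
            assert 0.3 <= frac <= 0.7

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            holdout_split(_toy_dataset(), fractions=(0.5, 0.2, 0.2))


class TestPermutation:
    def test_minimum_p_on_separable_data(self):
        res = permutation_test(_toy_dataset(n_per_group=8), n_shuffles=19,
                               seed=0, scheme="2-fold")
        assert res["p_value"] == pytest.approx(1.0 / 20.0)
        assert res["observed_accuracy"] == 1.0

    def test_p_bounds(self):
        res = permutation_test(_toy_dataset(n_per_group=6, sep=0.0),
                               n_shuffles=9, seed=0, scheme="2-fold")
        assert 0.1 <= res["p_value"] <= 1.0

    def test_shuffle_count_validated(self):
        with pytest.raises(ValueError):
            permutation_test(_toy_dataset(), n_shuffles=0)


class TestROC:
    def test_perfect_and_tied_scores(self):
        y = np.array([1, 1, 0, 0])
        assert roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), y) == 1.0
        assert roc_auc(np.full(4, 0.5), y) == 0.5

    def test_matches_concordance_oracle(self, rng):
        """Trapezoid AUC equals brute-force all-pairs concordance."""
        for _ in range(10):
            n = int(rng.integers(6, 50))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            pos, neg = s[y == 1], s[y == 0]
            pairs = [(1.0 if a > b else 0.5 if a == b else 0.0)
                     for a in pos for b in neg]
            assert roc_auc(s, y) == pytest.approx(np.mean(pairs))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestPredictiveValues:
    def test_perfect_test_all_prevalences(self):
        for prev in (1 / 68, 0.187, 0.5):
            rep = predictive_values(1.0, 1.0, prev)
            assert rep.ppv == 1.0 and rep.npv == 1.0

    def test_hand_evaluated_general_population(self):
        rep = predictive_values(0.93, 0.89, 1 / 68)
        assert rep.ppv == pytest.approx(0.1121, abs=5e-4)
        assert rep.npv == pytest.approx(0.9988, abs=5e-4)

    def test_ppv_increases_with_prevalence(self):
        ppvs = [predictive_values(0.9, 0.85, p).ppv
                for p in (0.01, 0.1, 0.187, 0.5)]
        assert all(a < b for a, b in zip(ppvs, ppvs[1:]))

    def test_round_trip_from_stored_fields(self):
        rep = predictive_values(0.8, 0.7, 0.2)
        re2 = predictive_values(rep.sensitivity, rep.specificity, rep.prevalence)
        assert re2.ppv == rep.ppv and re2.npv == rep.npv

    def test_zero_denominator_is_explicit_error(self):
        with pytest.raises(ZeroDivisionError):
            predictive_values(0.0, 1.0, 0.5)

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            predictive_values(1.2, 0.5, 0.1)
        with pytest.raises(ValueError):
            predictive_values(0.5, 0.5, 0.0)


class TestBehavioralCorrelation:
    def test_exact_linear_relation(self):
        scores = np.linspace(0.1, 0.9, 10)[:, None]
        behav = 2 * scores[:, 0] + 1
        out = behavioral_correlation(scores, behav)
        assert out[1][0] == pytest.approx(1.0)

    def test_null_relation_small_r(self):
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(50):
            scores = rng.uniform(size=(100, 1))
            behav = rng.normal(size=100)
            rs.append(abs(behavioral_correlation(scores, behav)[1][0]))
        assert np.mean(rs) < 0.15

    def test_positive_slope_recovered_from_phantom(self):
        hits = 0
        for run in range(10):
            spec = PhantomSpec(grid_shape=(10, 10, 6), n_timepoints=80,
                               n_areas=2, affected_areas={1}, effect_size=2.0,
                               noise_sigma=0.2, behavioral_noise_sd=0.5,
                               n_asd=20, n_td=4, seed=40 + run)
            ds, truth = phantom_dataset(spec, via_decomposition=False)
            asd = np.array([lab == "ASD" for lab in truth.labels])
            # affected area in-band power vs behavioral score
            power = ds.features[asd, 0, 1:8].mean(axis=1)[:, None]
            r, _ = behavioral_correlation(power, truth.behavioral_score[asd])[1]
            hits += r > 0
        assert hits >= 9

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = behavioral_correlation(np.full((5, 1), 0.5),
                                         np.arange(5, dtype=float))
        assert np.isnan(out[1][0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            behavioral_correlation(np.zeros((2, 1)), np.array([1.0, 2.0]))
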