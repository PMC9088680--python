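"""Chi-square selection and RUS/SMOTE balancing."""

import numpy as np
import pytest

from puppred.encoders import FeatureMatrix
from puppred.select_balance import (
    BalanceConfig,
    NonnegativeShifter,
    balance,
    chi2_scores,
    random_undersample,
    select_top_k,
    smote_oversample,
)


def _fm(values, names=None, ids=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return FeatureMatrix(names, values, ids)


def brute_chi2(X, y):
    """Independent oracle: observed vs expected class-conditional feature mass.

    For each feature, the observed statistic sums the feature over each
    class; the expected value follows from the class priors.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    out = []
    for j in range(X.shape[1]):
        col = X[:, j]
        total = col.sum()
        if total == 0:
            out.append(0.0)
            continue
        stat = 0.0
        for cls in (0, 1):
            observed = col[y == cls].sum()
            expected = total * np.mean(y == cls)
            stat += (observed - expected) ** 2 / expected
        out.append(stat)
    return np.array(out)


class TestChi2:
    def test_matches_contingency_oracle(self, rng):
        X = rng.random((40, 6))
        X[:, 2] = (rng.random(40) > 0.5).astype(float)  # binarized column
        y = rng.integers(0, 2, 40)
        while len(set(y)) < 2:
            y = rng.integers(0, 2, 40)
        res = chi2_scores(_fm(X), y)
        np.testing.assert_allclose(res.scores, brute_chi2(X, y), atol=1e-9)

    def test_label_identical_column_ranks_first(self, rng):
        y = np.array([0, 1] * 20)
        X = rng.random((40, 5))
        X[:, 3] = y.astype(float)
        res = chi2_scores(_fm(X), y)
        assert res.ranking[0] == 3

    def test_constant_column_scores_zero(self):
        X = np.column_stack([np.ones(10), np.arange(10, dtype=float)])
        y = np.array([0] * 5 + [1] * 5)
        res = chi2_scores(_fm(X), y)
        assert res.scores[0] == pytest.approx(0.0, abs=1e-9)

    def test_negative_features_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            chi2_scores(_fm([[-1.0, 0.0], [1.0, 2.0]]), [0, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            chi2_scores(_fm([[1.0], [2.0]]), [1, 1])

    def test_select_top_k(self, rng):
        X = rng.random((30, 8))
        y = rng.integers(0, 2, 30)
        y[:15], y[15:] = 0, 1
        res = chi2_scores(_fm(X), y)
        top = select_top_k(res, _fm(X), 3)
        assert top.n_features == 3
        assert top.feature_names == res.selected_names[:3]
        full = select_top_k(res, _fm(X), 8)
        assert sorted(full.feature_names) == sorted(f"f{i}" for i in range(8))
        with pytest.raises(ValueError):
            select_top_k(res, _fm(X), 9)


class TestShifter:
    def test_negative_columns_mapped_to_unit_interval(self, rng):
        X = rng.standard_normal((20, 4))
        X[:, 1] = np.abs(X[:, 1])  # already non-negative, must pass through
        sh = NonnegativeShifter().fit(X)
        Z = sh.transform(X)
        assert (Z >= 0).all()
        np.testing.assert_array_equal(Z[:, 1], X[:, 1])

    def test_round_trips_through_dict(self, rng):
        X = rng.standard_normal((10, 3))
        sh = NonnegativeShifter().fit(X)
        sh2 = NonnegativeShifter.from_dict(sh.to_dict())
        np.testing.assert_array_equal(sh.transform(X), sh2.transform(X))


class TestRus:
    def test_counts_contract(self, rng):
        X = rng.random((60, 3))
        y = np.array([1] * 10 + [0] * 50)
        Xb, yb = random_undersample(_fm(X), y, BalanceConfig(strategy="rus", seed=4))
        assert (yb == 1).sum() == 10 and (yb == 0).sum() == 10

    def test_already_balanced_unchanged(self, rng):
        X = rng.random((20, 2))
        y = np.array([0, 1] * 10)
        Xb, yb = random_undersample(_fm(X), y, BalanceConfig(strategy="rus", seed=4))
        assert Xb.n_samples == 20

    def test_rows_are_subset_and_seeded(self, rng):
        X = rng.random((30, 2))
        y = np.array([1] * 5 + [0] * 25)
        fm = _fm(X)
        X1, _ = random_undersample(fm, y, BalanceConfig(strategy="rus", seed=9))
        X2, _ = random_undersample(fm, y, BalanceConfig(strategy="rus", seed=9))
        assert X1.sample_ids == X2.sample_ids
        assert set(X1.sample_ids) <= set(fm.sample_ids)

    def test_unreachable_ratio_rejected(self, rng):
        X = rng.random((12, 2))
        y = np.array([1] * 2 + [0] * 10)
        with pytest.raises(ValueError):
            random_undersample(_fm(X), y, BalanceConfig(strategy="rus", target_ratio=100.0))


class TestSmote:
    def test_counts_contract(self, rng):
        X = rng.random((30, 3))
        y = np.array([1] * 10 + [0] * 20)
        Xb, yb = smote_oversample(_fm(X), y, BalanceConfig(strategy="smote", seed=2))
        assert (yb == 1).sum() == 20 and (yb == 0).sum() == 20

    def test_identical_minority_points_synthesize_the_same_point(self):
        X = np.vstack([np.full((3, 2), 7.0), np.zeros((9, 2))])
        y = np.array([1] * 3 + [0] * 9)
        Xb, yb = smote_oversample(_fm(X), y, BalanceConfig(strategy="smote", seed=0))
        synth = Xb.values[12:]
        np.testing.assert_allclose(synth, 7.0)

    def test_synthetic_points_on_parent_neighbor_segment(self, rng):
        """Geometric oracle: collinearity and convexity of each synthetic row."""
        X = np.column_stack([rng.random(40), rng.random(40)])
        y = np.array([1] * 12 + [0] * 28)
        Xb, yb = smote_oversample(_fm(X), y, BalanceConfig(strategy="smote", seed=6))
        minority = X[:12]
        for row in Xb.values[40:]:
            # find a pair (parent, neighbor) whose segment contains the row
            ok = False
            for i in range(12):
                for j in range(12):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    r = row - minority[i]
                    cross = abs(d[0] * r[1] - d[1] * r[0])
                    denom = d @ d
                    t = (r @ d) / denom if denom > 0 else 0.0
                    if cross < 1e-9 and -1e-12 <= t <= 1 + 1e-12:
                        ok = True
                        break
                if ok:
                    break
            assert ok, f"synthetic row {row} lies on no minority segment"

    def test_synthetic_ids_flagged(self, rng):
        X = rng.random((15, 2))
        y = np.array([1] * 5 + [0] * 10)
        Xb, _ = smote_oversample(_fm(X), y, BalanceConfig(strategy="smote", seed=1))
        assert all(s.startswith("synth:") for s in Xb.sample_ids[15:])

    def test_minority_of_one_rejected(self, rng):
        X = rng.random((5, 2))
        y = np.array([1, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            smote_oversample(_fm(X), y, BalanceConfig(strategy="smote"))

    def test_seeded_reproducibility(self, rng):
        X = rng.random((30, 4))
        y = np.array([1] * 8 + [0] * 22)
        fm = _fm(X)
        cfg = BalanceConfig(strategy="smote", seed=33)
        X1, _ = smote_oversample(fm, y, cfg)
        X2, _ = smote_oversample(fm, y, cfg)
        np.testing.assert_array_equal(X1.values, X2.values)


class TestCombinedStrategy:
    def test_rus_then_smote_reaches_one_to_one(self, rng):
        X = rng.random((66, 3))
        y = np.array([1] * 6 + [0] * 60)
        Xb, yb = balance(_fm(X), y, BalanceConfig(seed=5))
        assert (yb == 1).sum() == (yb == 0).sum() == 12  # RUS to 2:1 (12 neg), SMOTE up

    def test_balanced_input_passes_through(self, rng):
        X = rng.random((20, 2))
        y = np.array([0, 1] * 10)
        Xb, yb = balance(_fm(X), y, BalanceConfig(seed=5))
        assert Xb.n_samples == 20

    def test_feature_names_never_change(self, rng):
        X = rng.random((40, 3))
        y = np.array([1] * 10 + [0] * 30)
        fm = _fm(X)
        for strat in ("rus", "smote", "rus_then_smote"):
            Xb, _ = balance(fm, y, BalanceConfig(strategy=strat, seed=1))
            assert Xb.feature_names == fm.feature_names
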