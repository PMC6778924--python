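import itertools

import numpy as np
import pytest

from bioselect.ensemble import (
    ConstantFeatureError,
    EnsembleFeatureSelector,
    majority_vote,
    pearson_correlation,
    prune_correlated,
)
from bioselect.preprocess import information_gain_values
from bioselect.reference import (
    HEPATITIS_ENSEMBLE,
    HEPATITIS_VOTES,
    WDBC_ENSEMBLE,
    WDBC_VOTES,
)


# ---------------------------------------------------------------------------
# majority vote
# ---------------------------------------------------------------------------

def test_vote_rows_reproduce_published_hepatitis_selection():
    """The per-feature mode of the three selector rows equals the published
    ensemble row for the Hepatitis table."""
    majority = majority_vote([HEPATITIS_VOTES["de"], HEPATITIS_VOTES["gso"],
                              HEPATITIS_VOTES["lion"]])
    assert np.array_equal(majority, HEPATITIS_ENSEMBLE)
    assert majority.sum() == 15  # 3 of 18 attributes rejected


@pytest.mark.parametrize("column,expected", [(2, 1), (6, 0)])
def test_single_attribute_votes(column, expected):
    # Steroid: (DE=1, GSO=0, LION=1) -> 1; Anorexia: (1, 0, 0) -> 0
    bits = [HEPATITIS_VOTES[k][column] for k in ("de", "gso", "lion")]
    assert majority_vote([np.array([b]) for b in bits]).tolist() == [expected]


def test_unanimous_masks_pass_through():
    mask = np.array([1, 0, 1, 1, 0])
    assert np.array_equal(majority_vote([mask, mask, mask]), mask)


def test_vote_requires_three_equal_length_masks():
    with pytest.raises(ValueError):
        majority_vote([np.array([1, 0]), np.array([1, 0])])
    with pytest.raises(ValueError):
        majority_vote([np.array([1, 0]), np.array([1]), np.array([0, 1])])


def test_published_wdbc_final_is_subset_of_vote_majority():
    """Consistency of the published WDBC rows with vote-then-prune: the final
    column only ever removes features from the vote majority, and it rejects
    12 of the 31 attributes."""
    majority = majority_vote([WDBC_VOTES["de"], WDBC_VOTES["gso"],
                              WDBC_VOTES["lion"]])
    assert np.all(WDBC_ENSEMBLE <= majority)
    assert int((WDBC_ENSEMBLE == 0).sum()) == 12
    assert majority.sum() - WDBC_ENSEMBLE.sum() == 3  # pruning removed 3 more


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def test_correlation_of_vector_with_itself_and_negation():
    x = np.array([0.3, 1.2, 5.0, 2.2])
    assert pearson_correlation(x, x) == pytest.approx(1.0)
    assert pearson_correlation(x, -x) == pytest.approx(-1.0)


def test_correlation_closed_form_value():
    r = pearson_correlation(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0]))
    assert r == pytest.approx(9.0 / np.sqrt(84.0))


def test_correlation_matches_numpy_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        x, y = rng.normal(size=(2, 30))
        assert pearson_correlation(x, y) == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-12
        )


def test_constant_vector_raises():
    with pytest.raises(ConstantFeatureError):
        pearson_correlation(np.ones(5), np.arange(5.0))


# ---------------------------------------------------------------------------
# redundancy pruning
# ---------------------------------------------------------------------------

def test_duplicated_feature_pair_loses_one_member():
    rng = np.random.default_rng(1)
    x = rng.normal(size=50)
    X = np.column_stack([x, x, rng.normal(size=50)])
    y = rng.integers(0, 2, 50)
    final, pairs = prune_correlated(X, np.array([1, 1, 1]), 0.95, y=y)
    assert final.sum() == 2
    assert len(pairs) == 1
    assert final[2] == 1  # the independent feature is untouched


def test_uncorrelated_mask_unchanged():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(100, 4))
    y = rng.integers(0, 2, 100)
    mask = np.array([1, 1, 1, 1])
    final, pairs = prune_correlated(X, mask, 0.95, y=y)
    assert np.array_equal(final, mask)
    assert pairs == []


def test_prune_matches_exhaustive_subset_oracle():
    """3 duplicates of one feature + 2 independent: the final mask equals the
    maximum-total-gain subset of size 3 with no > 0.95 pair."""
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 120)
    base = rng.normal(size=120) + y * 1.0
    X = np.column_stack([
        base,
        base + rng.normal(0, 1e-3, 120),
        base + rng.normal(0, 1e-3, 120),
        rng.normal(size=120),
        rng.normal(size=120) + y * 0.5,
    ])
    gains = information_gain_values(X, y)
    final, _ = prune_correlated(X, np.ones(5, dtype=int), 0.95, gains=gains)
    assert final.sum() == 3

    # oracle: enumerate all subsets free of >0.95 pairs, take max total gain
    # among the largest ones
    corr = np.corrcoef(X, rowvar=False)
    valid = []
    for bits in itertools.product([0, 1], repeat=5):
        sel = [i for i, b in enumerate(bits) if b]
        if all(abs(corr[a, b]) <= 0.95 for a in sel for b in sel if a < b):
            valid.append(sel)
    best_size = max(len(s) for s in valid)
    assert best_size == 3
    best_gain = max(sum(gains[i] for i in s) for s in valid if len(s) == best_size)
    # the three duplicates have identical estimated gains, so several optimal
    # subsets tie; the implementation must match the optimum in total gain
    final_gain = sum(gains[i] for i in np.where(final)[0])
    assert final_gain == pytest.approx(best_gain)
    assert sorted(np.where(final)[0]) in [sorted(s) for s in valid]


def test_pruning_is_idempotent():
    rng = np.random.default_rng(4)
    x = rng.normal(size=60)
    X = np.column_stack([x, x + rng.normal(0, 0.01, 60), rng.normal(size=60)])
    y = rng.integers(0, 2, 60)
    once, _ = prune_correlated(X, np.ones(3, dtype=int), 0.95, y=y)
    twice, pairs = prune_correlated(X, once, 0.95, y=y)
    assert np.array_equal(once, twice)
    assert pairs == []


def test_final_mask_has_no_correlated_pair():
    rng = np.random.default_rng(5)
    x = rng.normal(size=80)
    X = np.column_stack([x + rng.normal(0, 0.05, 80) for _ in range(4)]
                        + [rng.normal(size=80)])
    y = rng.integers(0, 2, 80)
    final, _ = prune_correlated(X, np.ones(5, dtype=int), 0.95, y=y)
    sel = np.where(final)[0]
    for a, b in itertools.combinations(sel, 2):
        assert abs(pearson_correlation(X[:, a], X[:, b])) <= 0.95


def test_strong_negative_correlation_is_pruned_by_default():
    rng = np.random.default_rng(6)
    x = rng.normal(size=60)
    X = np.column_stack([x, -x + rng.normal(0, 1e-3, 60)])
    y = rng.integers(0, 2, 60)
    final, _ = prune_correlated(X, np.ones(2, dtype=int), 0.95, y=y)
    assert final.sum() == 1
    final_signed, _ = prune_correlated(X, np.ones(2, dtype=int), 0.95, y=y,
                                       use_absolute=False)
    assert final_signed.sum() == 2


# ---------------------------------------------------------------------------
# full ensemble estimator
# ---------------------------------------------------------------------------

def test_ensemble_final_subset_of_majority(surrogate):
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 6))
    selector = EnsembleFeatureSelector(
        fitness=surrogate, random_state=0,
        de_params=dict(population_size=8, max_iterations=3),
        loa_params=dict(n_prides=4, n_nomads=4, n_center_wing=2, max_iterations=3),
        gso_params=dict(n_glowworms=8, max_iterations=3),
    )
    selector.fit(X)
    final = selector.support_mask_.astype(int)
    assert np.all(final <= selector.majority_)
    votes = np.sum([selector.votes_[k] for k in ("de", "loa", "gso")], axis=0)
    assert np.all(votes[final.astype(bool)] >= 2)


def test_ensemble_transform_reduces_columns(small_dataset):
    ds, _ = small_dataset
    selector = EnsembleFeatureSelector(
        random_state=1,
        de_params=dict(population_size=6, max_iterations=2),
        loa_params=dict(n_prides=4, n_nomads=4, n_center_wing=2, max_iterations=2),
        gso_params=dict(n_glowworms=6, max_iterations=2),
    )
    Xt = selector.fit(ds.X, ds.y).transform(ds.X)
    assert Xt.shape == (ds.n_instances, selector.support_mask_.sum())
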