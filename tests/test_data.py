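"""Imputation, outlier removal, the 80/20 split and CSV round-trips."""

import numpy as np
import pandas as pd
import pytest

from ssrnn.data import (
    drop_outliers,
    impute_missing,
    load_sequence_csv,
    load_tabular_csv,
    round_half_up,
    save_sequence_csv,
    save_tabular_csv,
    standard_split,
)

# published train/test sizes for the five benchmark datasets
KNOWN_SPLITS = [
    (109_338, 87_470, 21_868),
    (11_500, 9_200, 2_300),
    (361_377, 289_102, 72_275),
    (520, 416, 104),
    (116, 93, 23),
]


# -----------------------------------------------------------------------------
# imputation
# -----------------------------------------------------------------------------
def test_mean_imputation_simple_column():
    df = pd.DataFrame({"a": [1.0, np.nan, 3.0], "label": [0, 1, 0]})
    out = impute_missing(df, label_col="label")
    assert out["a"].tolist() == [1.0, 2.0, 3.0]


def test_imputation_identity_when_complete():
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0], "label": [0, 1]})
    assert impute_missing(df, label_col="label").equals(df)


def test_imputed_values_equal_observed_column_means(rng):
    X = rng.normal(size=(10, 5))
    df = pd.DataFrame(X, columns=list("abcde"))
    mask = rng.random((10, 5)) < 0.2
    mask[0] = False  # keep at least one observed value per column
    dfm = df.mask(mask)
    out = impute_missing(dfm)
    for j, c in enumerate("abcde"):
        observed = dfm[c].dropna()
        filled = out[c][mask[:, j]]
        assert np.allclose(filled, observed.mean())


def test_binary_columns_use_mode():
    df = pd.DataFrame({"flag": [1.0, 1.0, 0.0, np.nan]})
    assert impute_missing(df)["flag"].iloc[-1] == 1.0


def test_entirely_missing_column_is_an_error():
    df = pd.DataFrame({"a": [np.nan, np.nan]})
    with pytest.raises(ValueError, match="a"):
        impute_missing(df)


def test_imputation_is_idempotent(rng):
    df = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc")).mask(
        rng.random((8, 3)) < 0.3
    )
    once = impute_missing(df)
    assert impute_missing(once).equals(once)


# -----------------------------------------------------------------------------
# outliers
# -----------------------------------------------------------------------------
def test_identical_records_never_flagged():
    df = pd.DataFrame({"a": [2.0] * 10})
    out, removed = drop_outliers(df)
    assert removed == 0 and len(out) == 10


def test_single_extreme_record_removed(rng):
    # bulk kept within 2 sigma so exactly the planted 10-sigma record flags
    vals = rng.standard_normal(100)
    vals = np.clip(vals, -2, 2)
    vals[42] = 10.0
    df = pd.DataFrame({"a": vals})
    out, removed = drop_outliers(df, z_max=3.0)
    assert removed == 1
    assert 42 not in out.index


def test_infinite_threshold_is_identity(rng):
    df = pd.DataFrame({"a": rng.normal(size=20)})
    out, removed = drop_outliers(df, z_max=np.inf)
    assert removed == 0 and out.equals(df)


def test_outlier_removal_idempotent_at_fixed_threshold(rng):
    df = pd.DataFrame(rng.standard_t(2, size=(200, 3)), columns=list("abc"))
    once, n1 = drop_outliers(df, z_max=3.0)
    twice, n2 = drop_outliers(once, z_max=3.0)
    assert n2 == 0
    assert twice.equals(once)


# -----------------------------------------------------------------------------
# standard split
# -----------------------------------------------------------------------------
@pytest.mark.parametrize("n,n_train,n_test", KNOWN_SPLITS)
def test_round_half_up_reproduces_published_split_sizes(n, n_train, n_test):
    s = standard_split(n, fraction=0.8, seed=0)
    assert len(s.train) == n_train
    assert len(s.test) == n_test


def test_round_half_up_rounds_up_at_half():
    assert round_half_up(92.8) == 93
    assert round_half_up(92.5) == 93
    assert round_half_up(92.4) == 92


def test_split_is_a_permutation_partition():
    s = standard_split(137, seed=5)
    assert np.array_equal(np.sort(np.concatenate([s.train, s.test])), np.arange(137))


def test_split_deterministic_per_seed():
    a = standard_split(50, seed=9)
    b = standard_split(50, seed=9)
    c = standard_split(50, seed=10)
    assert np.array_equal(a.train, b.train)
    assert not np.array_equal(a.train, c.train)


def test_stratified_split_preserves_class_balance():
    labels = np.array([0] * 80 + [1] * 20)
    s = standard_split(100, seed=0, labels=labels)
    assert len(s.train) == 80
    assert labels[s.train].sum() == 16  # 20% positives preserved


def test_split_validates_arguments():
    with pytest.raises(ValueError):
        standard_split(1)
    with pytest.raises(ValueError):
        standard_split(10, fraction=1.2)


# -----------------------------------------------------------------------------
# CSV I/O
# -----------------------------------------------------------------------------
def test_sequence_csv_round_trip(tmp_path, rng):
    X = rng.normal(size=(3, 5, 2))
    y = np.array([0, 2, 1])
    path = tmp_path / "seq.csv"
    save_sequence_csv(path, X, y)
    X2, y2 = load_sequence_csv(path)
    assert np.array_equal(X, X2)  # bit-exact round-trip
    assert np.array_equal(y, y2)


def test_sequence_csv_ragged_row_names_the_row(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("1,2,3,0\n1,2,0\n")
    with pytest.raises(ValueError, match="row 1"):
        load_sequence_csv(path)


def test_sequence_csv_non_numeric_entry(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("1,x,0\n")
    with pytest.raises(ValueError, match="row 0"):
        load_sequence_csv(path)


def test_tabular_csv_round_trip_with_missing(tmp_path):
    df = pd.DataFrame({"a": [1.5, np.nan, 2.5], "b": [0.0, 1.0, 1.0], "label": [0, 1, 0]})
    path = tmp_path / "tab.csv"
    save_tabular_csv(path, df)
    out = load_tabular_csv(path)
    assert out["a"].isna().tolist() == [False, True, False]
    assert np.allclose(out["a"].dropna(), [1.5, 2.5])


def test_tabular_schema_encoding_and_unknown_category(tmp_path):
    path = tmp_path / "tab.csv"
    path.write_text("sex,label\nM,0\nF,1\n")
    out = load_tabular_csv(path, schema={"sex": {"M": 0, "F": 1}})
    assert out["sex"].tolist() == [0, 1]
    path.write_text("sex,label\nM,0\nX,1\n")
    with pytest.raises(ValueError, match="row 1"):
        load_tabular_csv(path, schema={"sex": {"M": 0, "F": 1}})


def test_tabular_ragged_row_rejected(tmp_path):
    path = tmp_path / "tab.csv"
    path.write_text("a,b,label\n1,2,0\n1,0\n")
    with pytest.raises(ValueError, match="row 2"):
        load_tabular_csv(path)
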