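"""ANN regression: stratified splitting with range containment, forward
variable selection against a brute-force oracle, Levenberg-Marquardt
training fixtures, and prediction arithmetic."""

import numpy as np
import pytest

from cartinirs import ann_regression as ann


# ----------------------------------------------------------------- splitting


def test_split_sizes_530_points(rng):
    grades = np.repeat([0, 1, 2], [318, 159, 53])
    y = rng.normal(size=530)
    split = ann.stratified_split(y, grades, seed=3)
    assert abs(split.train.size - 318) <= 2
    assert abs(split.val.size - 159) <= 2
    assert abs(split.test.size - 53) <= 2
    assert split.train.size + split.val.size + split.test.size == 530


def test_split_deterministic(rng):
    grades = np.repeat([0, 1], [40, 20])
    y = rng.normal(size=60)
    s1 = ann.stratified_split(y, grades, seed=9)
    s2 = ann.stratified_split(y, grades, seed=9)
    assert np.array_equal(s1.train, s2.train)
    assert np.array_equal(s1.test, s2.test)


def test_split_range_containment_enforced():
    """The global extremes end up in the training set even when the raw
    allocation puts them elsewhere."""
    rng = np.random.default_rng(0)
    for seed in range(8):
        y = rng.normal(size=60)
        grades = np.repeat([0, 1], [40, 20])
        s = ann.stratified_split(y, grades, seed=seed)
        held = np.concatenate([s.val, s.test])
        assert y[held].min() >= y[s.train].min()
        assert y[held].max() <= y[s.train].max()


def test_split_small_stratum_rejected(rng):
    grades = np.array([0] * 20 + [1] * 2)
    with pytest.raises(ValueError):
        ann.stratified_split(rng.normal(size=22), grades)


# ----------------------------------------------------------------- forward IVS


def _ivs_oracle(X, y, max_vars):
    """Plain-loop forward search under the residual-correlation criterion."""
    n, m = X.shape
    selected, avail = [], list(range(m))
    resid = y - y.mean()
    while len(selected) < min(max_vars, m):
        best, best_c = None, 0.0
        for j in avail:
            c = abs(np.corrcoef(X[:, j], resid)[0, 1])
            if c > best_c + 1e-15:
                best, best_c = j, c
        if best is None:
            break
        selected.append(best)
        avail.remove(best)
        A = np.column_stack([np.ones(n), X[:, selected]])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
    return selected


def test_ivs_exact_column_found_first(rng):
    X = rng.normal(size=(80, 100))
    y = X[:, 57].copy()
    assert ann.forward_ivs(X, y, max_vars=3)[0] == 57


def test_ivs_orthonormal_two_step(rng):
    raw = rng.normal(size=(40, 20))
    Q, _ = np.linalg.qr(raw)
    y = Q[:, 3] + Q[:, 9]
    sel = ann.forward_ivs(Q, y, max_vars=2)
    assert set(sel) == {3, 9}


def test_ivs_matches_bruteforce_oracle(rng):
    for _ in range(10):
        n = int(rng.integers(25, 60))
        m = int(rng.integers(5, 21))
        X = rng.normal(size=(n, m))
        beta = rng.normal(size=m) * (rng.random(m) < 0.4)
        y = X @ beta + 0.1 * rng.normal(size=n)
        k = int(rng.integers(1, m + 1))
        assert ann.forward_ivs(X, y, max_vars=k) == _ivs_oracle(X, y, k)


def test_ivs_returns_all_columns_once(rng):
    X = rng.normal(size=(50, 12))
    y = rng.normal(size=50)
    sel = ann.forward_ivs(X, y, max_vars=100)
    assert sorted(sel) == list(range(12))


def test_ivs_skips_zero_variance_column(rng):
    X = rng.normal(size=(40, 6))
    X[:, 2] = 1.0
    y = X[:, 0] + rng.normal(size=40) * 0.1
    with pytest.warns(RuntimeWarning):
        sel = ann.forward_ivs(X, y, max_vars=10)
    assert 2 not in sel


# ----------------------------------------------------------------- training


def _simple_split(n, seed=0):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    return ann.DataSplit(
        np.sort(idx[: int(0.6 * n)]),
        np.sort(idx[int(0.6 * n) : int(0.9 * n)]),
        np.sort(idx[int(0.9 * n) :]),
        np.zeros(n, dtype=int),
        (0.6, 0.3, 0.1),
        seed,
    )


def test_lm_learns_affine_map(rng):
    X = rng.normal(size=(120, 3))
    y = 2.0 + X @ np.array([1.5, -0.7, 0.3])
    split = _simple_split(120)
    model = ann.train_lm(X, y, split.train, split.val, hidden_size=1, seed=4)
    pred = ann.predict(model, X)
    assert np.sqrt(np.mean((y - pred) ** 2)) < 1e-6


def test_lm_learns_sine_fixture(rng):
    X = np.linspace(-np.pi, np.pi, 300).reshape(-1, 1)
    y = np.sin(X).ravel()
    split = _simple_split(300, seed=1)
    model = ann.train_lm(X, y, split.train, split.val, hidden_size=5, seed=7)
    pred = ann.predict(model, X[split.test])
    assert np.sqrt(np.mean((y[split.test] - pred) ** 2)) < 0.05


def test_lm_bitwise_deterministic(rng):
    X = rng.normal(size=(100, 4))
    y = np.tanh(X[:, 0]) + 0.2 * X[:, 1]
    split = _simple_split(100, seed=2)
    m1 = ann.train_lm(X, y, split.train, split.val, hidden_size=3, seed=11)
    m2 = ann.train_lm(X, y, split.train, split.val, hidden_size=3, seed=11)
    assert np.array_equal(m1.W1, m2.W1)
    assert np.array_equal(m1.w2, m2.w2)
    assert m1.record == m2.record


def test_lm_hidden_size_bounds(rng):
    X = rng.normal(size=(30, 2))
    y = X[:, 0]
    split = _simple_split(30)
    with pytest.raises(ValueError):
        ann.train_lm(X, y, split.train, split.val, hidden_size=11)


def test_predict_hand_computed_forward_pass():
    model = ann.ANNModel(
        selected_vars=[0, 1],
        hidden_size=1,
        W1=np.array([[0.5, -0.25]]),
        b1=np.array([0.1]),
        w2=np.array([2.0]),
        b2=0.3,
        x_mean=np.zeros(2),
        x_sd=np.ones(2),
        y_mean=1.0,
        y_sd=2.0,
        seed=0,
    )
    x = np.array([[0.4, 0.8]])
    hidden = np.tanh(0.5 * 0.4 - 0.25 * 0.8 + 0.1)
    expected = (2.0 * hidden + 0.3) * 2.0 + 1.0
    assert ann.predict(model, x)[0] == pytest.approx(expected, abs=1e-12)


def test_predict_zero_weights_constant():
    model = ann.ANNModel(
        selected_vars=[0],
        hidden_size=2,
        W1=np.zeros((2, 1)),
        b1=np.zeros(2),
        w2=np.zeros(2),
        b2=0.7,
        x_mean=np.zeros(1),
        x_sd=np.ones(1),
        y_mean=0.0,
        y_sd=1.0,
        seed=0,
    )
    out = ann.predict(model, np.linspace(-3, 3, 9).reshape(-1, 1))
    assert np.allclose(out, 0.7)


def test_predict_column_mismatch_rejected(rng):
    X = rng.normal(size=(50, 3))
    y = X.sum(axis=1)
    split = _simple_split(50)
    model = ann.train_lm(X, y, split.train, split.val, hidden_size=2, seed=1)
    with pytest.raises(ValueError):
        ann.predict(model, rng.normal(size=(5, 4)))


def test_select_model_argmin_consistency(rng):
    X = rng.normal(size=(90, 3))
    y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=90)
    split = _simple_split(90, seed=3)
    model, audit = ann.select_model(
        X, y, split, hidden_sizes=(1, 2, 3), restarts=2, seed=5, max_epochs=60
    )
    assert model.record["test_rmse"] == pytest.approx(audit["test_rmse"].min())
    model2, audit2 = ann.select_model(
        X, y, split, hidden_sizes=(1, 2, 3), restarts=2, seed=5, max_epochs=60
    )
    assert np.array_equal(model.W1, model2.W1)
    assert audit.equals(audit2)


def test_model_json_round_trip(rng, tmp_path):
    X = rng.normal(size=(60, 2))
    y = X[:, 0] - X[:, 1]
    split = _simple_split(60, seed=4)
    model = ann.train_lm(X, y, split.train, split.val, hidden_size=2, seed=9)
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = ann.ANNModel.from_json(path)
    assert np.allclose(ann.predict(loaded, X), ann.predict(model, X))
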