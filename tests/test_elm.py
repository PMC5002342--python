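"""Pattern extraction and extreme-learning-machine training/classification."""

import numpy as np
import pytest
import scipy.linalg

import oracles
from tumorseg import Volume
from tumorseg.elm import (
    ELMModel,
    build_training_set,
    classify,
    extract_pattern,
    extract_patterns,
    hidden_matrix,
    init_hidden,
    load_model,
    save_model,
    train,
    train_output_weights,
)


def _roi(data, spacing=(1, 1, 1)):
    return Volume(np.asarray(data, dtype=float), spacing)


# ---------------------------------------------------------------------------
# pattern extraction


def test_pattern_normalization_endpoints():
    data = np.full((3, 3, 3), 5.0)
    data[1, 1, 1] = 0.0
    data[0, 0, 0] = 10.0
    roi = _roi(data)
    p = extract_pattern(roi, (1, 1, 1), (1, 1, 1), i_min=0.0, i_max=10.0)
    assert p.values[0] == -1.0
    p = extract_pattern(roi, (0, 0, 0), (1, 1, 1), i_min=0.0, i_max=10.0)
    assert p.values[0] == 1.0


def test_pattern_midpoint_maps_to_zero():
    roi = _roi(np.full((5, 5, 5), 7.0))
    p = extract_pattern(roi, (2, 2, 2), (3, 3, 3), i_min=0.0, i_max=14.0)
    np.testing.assert_array_equal(p.values, np.zeros(27))


def test_pattern_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    data = rng.permutation(125).reshape(5, 5, 5).astype(float)
    roi = _roi(data)
    for center in [(2, 2, 2), (0, 0, 0), (4, 1, 3)]:  # interior and border
        got = extract_pattern(roi, center, (3, 3, 3), 0.0, 124.0).values
        want = oracles.brute_pattern(data, center, (3, 3, 3), 0.0, 124.0)
        np.testing.assert_allclose(got, want, atol=1e-12)
        assert got.shape == (27,)
        assert np.all((got >= -1) & (got <= 1))


def test_degenerate_contrast_rejected():
    roi = _roi(np.zeros((3, 3, 3)))
    with pytest.raises(ValueError, match="degenerate"):
        extract_pattern(roi, (1, 1, 1), (3, 3, 3), 1.0, 1.0)


def test_even_window_rejected():
    roi = _roi(np.zeros((4, 4, 4)))
    with pytest.raises(ValueError, match="odd"):
        extract_patterns(roi, [(1, 1, 1)], (2, 3, 3), 0.0, 1.0)


# ---------------------------------------------------------------------------
# training set


def test_training_set_counts_and_coding():
    rng = np.random.default_rng(1)
    roi = _roi(rng.normal(size=(6, 6, 6)))
    labels = np.zeros((6, 6, 6), dtype=np.uint8)
    labels.flat[:10] = 1
    labels.flat[10:25] = 2
    ts = build_training_set(roi, labels, (3, 3, 3))
    assert ts.patterns.shape == (25, 27)
    assert ts.targets.shape == (25, 2)
    # tumor voxels -> (0, 1), nontumor -> (1, 0)
    lab = labels[labels > 0]
    np.testing.assert_array_equal(ts.targets[lab == 1], np.tile([0.0, 1.0], (10, 1)))
    np.testing.assert_array_equal(ts.targets[lab == 2], np.tile([1.0, 0.0], (15, 1)))


def test_single_class_training_rejected():
    roi = _roi(np.random.default_rng(0).normal(size=(4, 4, 4)))
    labels = np.zeros((4, 4, 4), dtype=np.uint8)
    with pytest.raises(ValueError, match="classes"):
        build_training_set(roi, labels)
    labels[0, 0, 0] = 1
    with pytest.raises(ValueError, match="classes"):
        build_training_set(roi, labels)


# ---------------------------------------------------------------------------
# hidden layer


def test_init_hidden_deterministic_and_shaped():
    w1, b1 = init_hidden(27, 200, rng_seed=7)
    w2, b2 = init_hidden(27, 200, rng_seed=7)
    assert w1.shape == (200, 27) and b1.shape == (200,)
    np.testing.assert_array_equal(w1, w2)
    np.testing.assert_array_equal(b1, b2)
    w3, _ = init_hidden(27, 200, rng_seed=8)
    assert np.any(w3 != w1)
    assert np.all((w1 >= -1) & (w1 <= 1))


def test_hidden_matrix_sigmoid_at_zero():
    model = ELMModel(np.zeros((3, 5)), np.zeros(3), 3)
    H = hidden_matrix(np.zeros((2, 5)), model)
    np.testing.assert_array_equal(H, np.full((2, 3), 0.5))


def test_hidden_matrix_matches_loop_oracle():
    rng = np.random.default_rng(2)
    P = rng.normal(size=(4, 6))
    w, b = init_hidden(6, 3, rng_seed=0)
    model = ELMModel(w, b, 3)
    H = hidden_matrix(P, model)
    np.testing.assert_allclose(H, oracles.loop_hidden(P, w, b), atol=1e-12)
    assert np.all((H > 0) & (H < 1))


def test_hidden_matrix_dimension_mismatch():
    model = ELMModel(np.zeros((3, 5)), np.zeros(3), 3)
    with pytest.raises(ValueError, match="dimension"):
        hidden_matrix(np.zeros((2, 4)), model)


# ---------------------------------------------------------------------------
# output weights


def test_identity_system_solution():
    H = np.eye(2)
    T = np.array([[0.0, 1.0], [1.0, 0.0]])
    np.testing.assert_allclose(train_output_weights(H, T, ridge=0.0), T, atol=1e-12)


def test_tiny_ridge_approaches_pseudoinverse():
    rng = np.random.default_rng(3)
    H = rng.normal(size=(10, 3))  # full column rank
    T = rng.integers(0, 2, size=(10, 1)).astype(float)
    T = np.hstack([T, 1 - T])
    A_pinv = train_output_weights(H, T, ridge=0.0)
    A_ridge = train_output_weights(H, T, ridge=1e-12)
    np.testing.assert_allclose(A_ridge, A_pinv, atol=1e-6)


def test_ridge_solution_matches_independent_solver():
    rng = np.random.default_rng(4)
    H = rng.normal(size=(12, 5))
    T = np.tile([[1.0, 0.0]], (12, 1))
    T[::2] = [0.0, 1.0]
    lam = 0.01
    A = train_output_weights(H, T, ridge=lam)
    # independent route: augmented least squares [H; sqrt(lam) I] A = [T; 0]
    Haug = np.vstack([H, np.sqrt(lam) * np.eye(5)])
    Taug = np.vstack([T, np.zeros((5, 2))])
    A_ref, *_ = scipy.linalg.lstsq(Haug, Taug)
    np.testing.assert_allclose(A, A_ref, atol=1e-8)


def test_least_squares_residual_matches_lstsq():
    rng = np.random.default_rng(5)
    H = rng.normal(size=(20, 6))
    T = rng.normal(size=(20, 2))
    A = train_output_weights(H, T, ridge=0.0)
    A_ref, *_ = scipy.linalg.lstsq(H, T)
    res = np.linalg.norm(H @ A - T)
    res_ref = np.linalg.norm(H @ A_ref - T)
    assert abs(res - res_ref) < 1e-8


def test_training_pair_permutation_invariance():
    rng = np.random.default_rng(6)
    H = rng.normal(size=(15, 4))
    T = rng.normal(size=(15, 2))
    perm = rng.permutation(15)
    for lam in (0.0, 0.01):
        A = train_output_weights(H, T, ridge=lam)
        A_p = train_output_weights(H[perm], T[perm], ridge=lam)
        np.testing.assert_allclose(A, A_p, atol=1e-10)


def test_ridge_monotonically_shrinks_weights():
    rng = np.random.default_rng(7)
    H = rng.normal(size=(30, 8))
    T = rng.normal(size=(30, 2))
    norms = [
        np.linalg.norm(train_output_weights(H, T, ridge=lam))
        for lam in (1e-6, 1e-3, 1e-1, 10.0)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


def test_nonfinite_hidden_matrix_rejected():
    H = np.array([[1.0, np.inf]])
    with pytest.raises(ValueError):
        train_output_weights(H, np.array([[0.0, 1.0]]), ridge=0.0)


# ---------------------------------------------------------------------------
# classification


def _small_case(rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    data = rng.normal(100, 20, size=(5, 5, 5))
    data[1:4, 1:4, 1:4] += 60  # bright core
    labels = np.zeros((5, 5, 5), dtype=np.uint8)
    labels[2, 2, 2] = 1
    labels[2, 2, 1] = 1
    labels[0, :, :] = 2
    return _roi(data), labels


def test_classify_passthrough_when_fully_labeled():
    roi, _ = _small_case()
    labels = np.full((5, 5, 5), 2, dtype=np.uint8)
    labels[2, 2, 2] = 1
    model = train(roi, labels, K=10, ridge=0.01, rng_seed=0)
    out = classify(roi, labels, model)
    np.testing.assert_array_equal(out, labels)


def test_interpolating_model_reproduces_teacher_labels():
    # n <= K with full row rank: the min-norm solution interpolates exactly
    roi, labels = _small_case()
    n = int(np.count_nonzero(labels))
    model = train(roi, labels, K=n + 40, ridge=0.0, rng_seed=1)
    out = classify(roi, np.where(labels > 0, 0, labels).astype(np.uint8), model)
    # re-presenting the training voxels reproduces their teacher labels
    np.testing.assert_array_equal(out[labels > 0], labels[labels > 0])


def test_classify_fills_every_voxel():
    roi, labels = _small_case()
    model = train(roi, labels, K=50, rng_seed=0)
    out = classify(roi, labels, model)
    assert np.all(out > 0)
    np.testing.assert_array_equal(out[labels > 0], labels[labels > 0])


def test_untrained_model_rejected():
    roi, labels = _small_case()
    model = ELMModel(*init_hidden(27, 5), 5)
    with pytest.raises(RuntimeError, match="train"):
        classify(roi, labels, model)


def test_pipeline_determinism_for_equal_seeds():
    roi, labels = _small_case()
    out1 = classify(roi, labels, train(roi, labels, K=30, rng_seed=5))
    out2 = classify(roi, labels, train(roi, labels, K=30, rng_seed=5))
    np.testing.assert_array_equal(out1, out2)


def test_model_save_load_round_trip(tmp_path):
    roi, labels = _small_case()
    model = train(roi, labels, K=30, rng_seed=3)
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path)
    out1 = classify(roi, labels, model)
    out2 = classify(roi, labels, back)
    np.testing.assert_array_equal(out1, out2)
    np.testing.assert_array_equal(back.input_weights, model.input_weights)
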