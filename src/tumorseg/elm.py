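"""Voxel-window patterns and the extreme-learning-machine classifier.

A single hidden layer feedforward network (SLFN) classifies each voxel from
the raw normalized gray levels in a small window (default 3x3x3) centred on
it.  Training is noniterative: the hidden layer (input weights ``w_k`` and
biases ``b_k``) is drawn at random and frozen, the hidden activations
``H_ik = sigmoid(w_k . p_i + b_k)`` are computed for the teacher voxels, and
the linear output weights ``A`` solve ``H A = T`` in closed form — either the
minimum-norm least-squares solution ``A = pinv(H) T`` or, with a ridge
coefficient ``lambda > 0``, ``A = (H' H + lambda I)^-1 H' T``.  This is the
extreme learning machine (ELM) scheme: no backpropagation, no epochs, no
learning rate.

Targets use a two-component one-hot coding: tumor voxels (teacher label 1)
map to ``(0, 1)``, nontumor voxels (label 2) to ``(1, 0)``; classification is
by argmax with ties going to nontumor.

Window intensities are normalized to [-1, 1] via the ROI-wide minimum and
maximum: ``q = -1 + 2 (v - I_min) / (I_max - I_min)``.  Window entries are
raster-ordered with the z offset slowest, then y, then x, offsets ascending;
windows reaching outside the ROI use replicate padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .volume import Volume

__all__ = [
    "Pattern",
    "TrainingSet",
    "ELMModel",
    "extract_pattern",
    "extract_patterns",
    "build_training_set",
    "init_hidden",
    "hidden_matrix",
    "train_output_weights",
    "classify",
    "save_model",
    "load_model",
]

TUMOR_TARGET = (0.0, 1.0)
NONTUMOR_TARGET = (1.0, 0.0)


@dataclass
class Pattern:
    values: np.ndarray  # window intensities normalized to [-1, 1]
    center_index: tuple[int, int, int]


@dataclass
class TrainingSet:
    patterns: np.ndarray  # (n, d)
    targets: np.ndarray  # (n, 2), rows one-hot


@dataclass
class ELMModel:
    """Random hidden layer plus learned linear output weights."""

    input_weights: np.ndarray  # (K, d)
    biases: np.ndarray  # (K,)
    hidden_size: int
    ridge: float = 0.01
    rng_seed: int = 0
    output_weights: np.ndarray | None = None  # (K, 2) after training

    @property
    def trained(self) -> bool:
        return self.output_weights is not None


def _check_window(window: Sequence[int]) -> tuple[int, int, int]:
    w = tuple(int(x) for x in window)
    if len(w) != 3 or any(x < 1 or x % 2 == 0 for x in w):
        raise ValueError(f"window must be three odd positive integers, got {window}")
    return w


def _normalize(data: np.ndarray, i_min: float, i_max: float) -> np.ndarray:
    if i_max <= i_min:
        raise ValueError(f"degenerate intensity range [{i_min}, {i_max}]")
    return -1.0 + 2.0 * (data - i_min) / (i_max - i_min)


def extract_patterns(roi: Volume, centers: np.ndarray, window: Sequence[int],
                     i_min: float, i_max: float) -> np.ndarray:
    """Window patterns for many center voxels at once; shape (n, prod(window))."""
    wx, wy, wz = _check_window(window)
    rx, ry, rz = wx // 2, wy // 2, wz // 2
    norm = _normalize(np.asarray(roi.data, dtype=np.float64), float(i_min), float(i_max))
    padded = np.pad(norm, ((rx, rx), (ry, ry), (rz, rz)), mode="edge")
    centers = np.atleast_2d(np.asarray(centers, dtype=np.intp))
    cx = centers[:, 0] + rx
    cy = centers[:, 1] + ry
    cz = centers[:, 2] + rz
    cols = []
    for k in range(-rz, rz + 1):  # z slowest
        for j in range(-ry, ry + 1):
            for i in range(-rx, rx + 1):
                cols.append(padded[cx - i, cy - j, cz - k])
    return np.stack(cols, axis=1)


def extract_pattern(roi: Volume, center: Sequence[int], window: Sequence[int],
                    i_min: float, i_max: float) -> Pattern:
    """Single-voxel version of :func:`extract_patterns`."""
    center = tuple(int(c) for c in center)
    vals = extract_patterns(roi, np.asarray([center]), window, i_min, i_max)[0]
    return Pattern(vals, center)


def build_training_set(roi: Volume, labels: np.ndarray, window: Sequence[int] = (3, 3, 3)) -> TrainingSet:
    """One (pattern, target) pair per teacher-labeled voxel.

    The normalization bounds are the global min/max of the ROI, computed once.
    Raises if either teacher class is absent (training would be degenerate).
    """
    labels = np.asarray(labels)
    if labels.shape != roi.data.shape:
        raise ValueError(f"labels shape {labels.shape} does not match ROI {roi.data.shape}")
    n_tumor = int(np.count_nonzero(labels == 1))
    n_back = int(np.count_nonzero(labels == 2))
    if n_tumor == 0 or n_back == 0:
        raise ValueError(
            f"both teacher classes are required (tumor={n_tumor}, nontumor={n_back})"
        )
    i_min = float(roi.data.min())
    i_max = float(roi.data.max())
    centers = np.argwhere(labels > 0)
    patterns = extract_patterns(roi, centers, window, i_min, i_max)
    lab = labels[centers[:, 0], centers[:, 1], centers[:, 2]]
    targets = np.where((lab == 1)[:, None], np.asarray(TUMOR_TARGET), np.asarray(NONTUMOR_TARGET))
    return TrainingSet(patterns, targets)


def init_hidden(dim: int, K: int, rng_seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Random hidden layer: weights and biases i.i.d. uniform on [-1, 1]."""
    if dim < 1 or K < 1:
        raise ValueError("dim and K must be positive")
    rng = np.random.default_rng(rng_seed)
    w = rng.uniform(-1.0, 1.0, size=(K, dim))
    b = rng.uniform(-1.0, 1.0, size=K)
    return w, b


def hidden_matrix(patterns: np.ndarray, model: ELMModel) -> np.ndarray:
    """H_ik = sigmoid(w_k . p_i + b_k), shape (n, K)."""
    P = np.atleast_2d(np.asarray(patterns, dtype=np.float64))
    if P.shape[1] != model.input_weights.shape[1]:
        raise ValueError(
            f"pattern dimension {P.shape[1]} does not match model dimension "
            f"{model.input_weights.shape[1]}"
        )
    return expit(P @ model.input_weights.T + model.biases)


def train_output_weights(H: np.ndarray, T: np.ndarray, ridge: float = 0.01) -> np.ndarray:
    """Closed-form output weights.

    ``ridge == 0``: minimum-norm least squares via the Moore-Penrose
    pseudoinverse, ``A = pinv(H) T``.  ``ridge > 0``: ridge regression,
    ``A = (H' H + ridge I)^-1 H' T``.
    """
    H = np.asarray(H, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    if not np.all(np.isfinite(H)):
        raise ValueError("hidden matrix contains non-finite values")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if ridge == 0:
        return np.linalg.pinv(H) @ T
    K = H.shape[1]
    return np.linalg.solve(H.T @ H + ridge * np.eye(K), H.T @ T)


def train(roi: Volume, labels: np.ndarray, window: Sequence[int] = (3, 3, 3),
          K: int = 200, ridge: float = 0.01, rng_seed: int = 0) -> ELMModel:
    """Convenience: build training set, init hidden layer, solve output weights."""
    ts = build_training_set(roi, labels, window)
    w, b = init_hidden(ts.patterns.shape[1], K, rng_seed)
    model = ELMModel(w, b, K, ridge, rng_seed)
    H = hidden_matrix(ts.patterns, model)
    model.output_weights = train_output_weights(H, ts.targets, ridge)
    return model


def classify(roi: Volume, labels: np.ndarray, model: ELMModel,
             window: Sequence[int] = (3, 3, 3), chunk: int = 200_000) -> np.ndarray:
    """Assign every unlabeled voxel to tumor (1) or nontumor (2).

    Labeled voxels pass through unchanged; unlabeled voxels get the argmax of
    the network's two outputs (identity output activation), ties going to
    nontumor.  The result contains no zeros.
    """
    if not model.trained:
        raise RuntimeError("model has no output weights; train it first")
    labels = np.asarray(labels)
    out = labels.astype(np.uint8).copy()
    centers = np.argwhere(labels == 0)
    if centers.size == 0:
        return out
    i_min = float(roi.data.min())
    i_max = float(roi.data.max())
    for start in range(0, len(centers), chunk):
        part = centers[start : start + chunk]
        P = extract_patterns(roi, part, window, i_min, i_max)
        o = hidden_matrix(P, model) @ model.output_weights
        lab = np.where(o[:, 1] > o[:, 0], 1, 2).astype(np.uint8)
        out[part[:, 0], part[:, 1], part[:, 2]] = lab
    return out


def save_model(model: ELMModel, path) -> None:
    """Serialize a model to a portable .npz file."""
    np.savez(
        path,
        input_weights=model.input_weights,
        biases=model.biases,
        hidden_size=model.hidden_size,
        ridge=model.ridge,
        rng_seed=model.rng_seed,
        output_weights=model.output_weights if model.trained else np.zeros(0),
    )


def load_model(path) -> ELMModel:
    with np.load(path) as z:
        ow = z["output_weights"]
        return ELMModel(
            input_weights=z["input_weights"],
            biases=z["biases"],
            hidden_size=int(z["hidden_size"]),
            ridge=float(z["ridge"]),
            rng_seed=int(z["rng_seed"]),
            output_weights=None if ow.size == 0 else ow,
        )
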