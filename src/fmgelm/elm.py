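"""Non-kernel extreme learning machine with a sigmoid hidden basis.

An ELM is a single-hidden-layer network whose hidden parameters are
drawn at random and frozen; only the output weights are learned, in
closed form.  The decision function is

    f(x) = h(x) beta,      h_i(x) = sigmoid(a_i . x + b_i)

with L hidden nodes.  Given the N x L hidden matrix H and the 1-of-K
target matrix T, the ridge-regularised output weights are

    beta = H^T (I/C + H H^T)^{-1} T          (dual, N x N system)
         = (I/C + H^T H)^{-1} H^T T          (primal, L x L system)

which are algebraically identical; the implementation solves whichever
system is smaller.  C is the inverse ridge penalty: larger C means
weaker regularisation.  The predicted class is the argmax over output
nodes, ties broken toward the earliest label in ``class_labels``.

Because (a_i, b_i) need only come from some continuous distribution,
they are drawn i.i.d. uniform on [-1, 1] — bounded and well matched to
[0, 1]-normalised inputs — and a basis can be reused across trainings
as long as L and the input dimension are unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import solve
from scipy.special import expit

from .exceptions import ConfigurationError, ParseError
from .preprocess import NormalizationParams


@dataclass(frozen=True)
class HiddenBasis:
    """Random frozen hidden layer: weights ``A`` (L x d) and biases ``b`` (L,)."""

    A: np.ndarray
    b: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if A.ndim != 2 or b.shape != (A.shape[0],):
            raise ConfigurationError("basis needs A of shape (L, d) and b of shape (L,)")
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
            raise ConfigurationError("basis parameters must be finite")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "b", b)

    @property
    def L(self) -> int:
        return self.A.shape[0]

    @property
    def d(self) -> int:
        return self.A.shape[1]


def random_basis(L: int, d: int, seed: int) -> HiddenBasis:
    """Draw hidden weights and biases i.i.d. uniform on [-1, 1]."""
    if L < 1 or d < 1:
        raise ConfigurationError("need L >= 1 and d >= 1")
    rng = np.random.default_rng(seed)
    return HiddenBasis(
        A=rng.uniform(-1.0, 1.0, size=(L, d)),
        b=rng.uniform(-1.0, 1.0, size=L),
        seed=seed,
    )


def hidden_map(x: np.ndarray, basis: HiddenBasis) -> np.ndarray:
    """Hidden-layer activations: sigmoid(a_i . x + b_i), in (0, 1).

    Accepts a single d-vector or an (N, d) batch.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != basis.d:
        raise ConfigurationError(
            f"input dimension {x.shape[1]} != basis dimension {basis.d}"
        )
    h = expit(x @ basis.A.T + basis.b)
    return h[0] if single else h


def one_hot_targets(labels: Sequence[int], class_labels: Sequence[int]) -> np.ndarray:
    """1-of-K target matrix in the column order of ``class_labels``."""
    index = {lbl: j for j, lbl in enumerate(class_labels)}
    unknown = sorted({l for l in labels if l not in index})
    if unknown:
        raise ConfigurationError(f"labels {unknown} outside the class label set")
    T = np.zeros((len(labels), len(class_labels)))
    for i, lbl in enumerate(labels):
        T[i, index[lbl]] = 1.0
    return T


@dataclass
class ELMModel:
    """Trained classifier: frozen basis, output weights, and the
    normalization parameters the features were scaled with."""

    basis: HiddenBasis
    beta: np.ndarray
    C: float
    class_labels: tuple[int, ...]
    norm: NormalizationParams | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.class_labels = tuple(int(l) for l in self.class_labels)
        if len(self.class_labels) < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.beta.shape != (self.basis.L, len(self.class_labels)):
            raise ConfigurationError("beta must be (L, K)")
        if not np.all(np.isfinite(self.beta)):
            raise ConfigurationError("beta must be finite")


def solve_output_weights(H: np.ndarray, T: np.ndarray, C: float) -> np.ndarray:
    """Closed-form ridge solution for the output weights.

    Uses the dual (N x N) system when N <= L and the primal (L x L)
    system otherwise; the two agree to machine precision.
    """
    if C <= 0:
        raise ConfigurationError("regularization parameter C must be > 0")
    N, L = H.shape
    if N <= L:
        G = H @ H.T
        G[np.diag_indices(N)] += 1.0 / C
        return H.T @ solve(G, T, assume_a="pos")
    G = H.T @ H
    G[np.diag_indices(L)] += 1.0 / C
    return solve(G, H.T @ T, assume_a="pos")


def train(
    features: np.ndarray,
    labels: Sequence[int],
    basis: HiddenBasis,
    C: float,
    class_labels: Sequence[int] | None = None,
    norm: NormalizationParams | None = None,
) -> ELMModel:
    """Fit output weights on (already normalized) feature samples."""
    X = np.asarray(features, dtype=float)
    labels = [int(l) for l in labels]
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise ConfigurationError("features must be (N, d) matching labels")
    if class_labels is None:
        class_labels = sorted(set(labels))
    K = len(class_labels)
    if K < 2:
        raise ConfigurationError("need at least 2 classes")
    if X.shape[0] < K:
        raise ConfigurationError("need at least K training samples")
    T = one_hot_targets(labels, class_labels)
    H = hidden_map(X, basis)
    beta = solve_output_weights(H, T, C)
    return ELMModel(
        basis=basis, beta=beta, C=float(C), class_labels=tuple(class_labels), norm=norm
    )


def predict(model: ELMModel, x: np.ndarray) -> tuple[np.ndarray | int, np.ndarray]:
    """Class label(s) and raw output-node scores for normalized input(s).

    The label is the class whose output node scores highest; exact ties
    resolve to the earliest entry of ``model.class_labels``.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    scores = hidden_map(x, model.basis) @ model.beta
    idx = np.argmax(scores, axis=-1)
    labels_arr = np.asarray(model.class_labels)
    if single:
        return int(labels_arr[idx]), scores
    return labels_arr[idx], scores


def save_model(model: ELMModel, path) -> None:
    """Serialize a model (basis, beta, C, labels, normalization) as JSON."""
    payload = {
        "format": "fmgelm-model",
        "version": 1,
        "L": model.basis.L,
        "d": model.basis.d,
        "C": model.C,
        "basis_seed": model.basis.seed,
        "class_labels": list(model.class_labels),
        "A": model.basis.A.tolist(),
        "b": model.basis.b.tolist(),
        "beta": model.beta.tolist(),
        "norm": None
        if model.norm is None
        else {
            "mins": model.norm.mins.tolist(),
            "maxs": model.norm.maxs.tolist(),
            "degenerate": model.norm.degenerate.tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> ELMModel:
    """Load a model written by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "fmgelm-model":
        raise ParseError(f"{path} is not an fmgelm model file")
    norm = payload.get("norm")
    return ELMModel(
        basis=HiddenBasis(
            A=np.asarray(payload["A"], dtype=float),
            b=np.asarray(payload["b"], dtype=float),
            seed=payload.get("basis_seed"),
        ),
        beta=np.asarray(payload["beta"], dtype=float),
        C=float(payload["C"]),
        class_labels=tuple(payload["class_labels"]),
        norm=None
        if norm is None
        else NormalizationParams(
            mins=np.asarray(norm["mins"], dtype=float),
            maxs=np.asarray(norm["maxs"], dtype=float),
            degenerate=np.asarray(norm["degenerate"], dtype=bool),
        ),
    )
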