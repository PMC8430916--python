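"""Second-level support-vector regression for mid-polar phases and GC x GC.

The stacker consumes a fixed 441-feature vector per compound: the 114
predicted-RI features (four base nets x registry phases, RI/1000) followed by
the 327 scaled molecular descriptors.  Targets are divided by 1000 for
training and predictions multiplied back, whether they are retention indices
or second-dimension retention times (the unit tag travels with the model).

The default hyperparameters (sigma 31.0, epsilon 0.82, C 31e3, tolerance 2.7)
are kept verbatim from the reference configuration even though epsilon and
tolerance are surprisingly large for /1000-scaled labels; both are plain
fields and every experiment in this package that needs a tight tube passes
explicit overrides (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.svm import SVR as _SkSVR

from .features import N_TOTAL as DESC_DIM

RI_BLOCK_DIM = 114
STACKED_DIM = RI_BLOCK_DIM + DESC_DIM  # 441
TARGET_SCALE = 1000.0


class FeatureManifestError(ValueError):
    """Raised for feature blocks of the wrong shape or version."""


@dataclass(frozen=True)
class SVRHyperparams:
    """Kernel width, tube threshold, box constraint and solver tolerance.

    ``kernel`` selects the exponential kernel form: "laplacian" is
    exp(-||x-y||/sigma), "gaussian" is exp(-||x-y||^2/(2 sigma^2)).
    """

    sigma: float = 31.0
    epsilon: float = 0.82
    C: float = 31_000.0
    tolerance: float = 2.7
    kernel: str = "laplacian"

    def __post_init__(self):
        if min(self.sigma, self.epsilon, self.C, self.tolerance) < 0 or \
                self.sigma == 0 or self.C == 0 or self.tolerance == 0:
            raise ValueError("sigma, C and tolerance must be positive; epsilon >= 0")
        if self.kernel not in ("laplacian", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")

    def with_overrides(self, **kw) -> "SVRHyperparams":
        return replace(self, **kw)


def kernel_matrix(x: np.ndarray, y: np.ndarray, hp: SVRHyperparams) -> np.ndarray:
    """Exponential kernel values k(x_i, y_j); k(x, x) = 1, symmetric."""
    d = euclidean_distances(np.atleast_2d(x), np.atleast_2d(y))
    if hp.kernel == "laplacian":
        return np.exp(-d / hp.sigma)
    return np.exp(-(d ** 2) / (2.0 * hp.sigma ** 2))


def assemble_features(ri_block: np.ndarray, descriptors: np.ndarray) -> np.ndarray:
    """Concatenate the 114 predicted-RI features with the 327 descriptors."""
    ri_block = np.asarray(ri_block, dtype=np.float64)
    descriptors = np.asarray(descriptors, dtype=np.float64)
    if ri_block.shape[-1] != RI_BLOCK_DIM:
        raise FeatureManifestError(f"RI block must have length {RI_BLOCK_DIM}")
    if descriptors.shape[-1] != DESC_DIM:
        raise FeatureManifestError(f"descriptor block must have length {DESC_DIM}")
    return np.concatenate([ri_block, descriptors], axis=-1)


@dataclass
class StackedModel:
    """A fitted epsilon-SVR: support vectors, dual coefficients and bias.

    Predictions are the kernel expansion sum_i alpha_i k(x, sv_i) + b times
    1000 (back to the target's original units).
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    bias: float
    hyperparams: SVRHyperparams
    target_units: str = "RI"
    feature_dim: int = STACKED_DIM

    def __post_init__(self):
        if len(self.dual_coef) != len(self.support_vectors):
            raise ValueError("one dual coefficient per support vector")
        if len(self.dual_coef) and np.max(np.abs(self.dual_coef)) > self.hyperparams.C * (1 + 1e-9):
            raise ValueError("dual coefficients must satisfy |alpha| <= C")


def train_stack(features: np.ndarray, targets: np.ndarray,
                hp: SVRHyperparams = SVRHyperparams(),
                target_units: str = "RI") -> StackedModel:
    """Fit the second-level epsilon-SVR on /1000-scaled targets.

    Identical feature rows with conflicting targets are legal (replicate
    measurements); the fit proceeds with a logged warning.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64) / TARGET_SCALE
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("features must be (n, d) aligned with targets")
    if len(x) < 1:
        raise ValueError("at least one training row is required")
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    if len(x) <= 4096:
        _, inverse = np.unique(x, axis=0, return_inverse=True)
        for group in range(inverse.max() + 1):
            ys = y[inverse == group]
            if len(ys) > 1 and np.ptp(ys) > 0:
                warnings.warn("identical feature rows with conflicting targets",
                              stacklevel=2)
                break
    svr = _SkSVR(kernel="precomputed", C=hp.C, epsilon=hp.epsilon, tol=hp.tolerance)
    svr.fit(kernel_matrix(x, x, hp), y)
    return StackedModel(
        support_vectors=x[svr.support_],
        dual_coef=svr.dual_coef_.ravel().copy(),
        bias=float(svr.intercept_[0]),
        hyperparams=hp,
        target_units=target_units,
        feature_dim=x.shape[1],
    )


def predict_stack(model: StackedModel, features: np.ndarray) -> np.ndarray | float:
    """Kernel-expansion prediction, scaled back to the original units."""
    x = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if x.shape[1] != model.feature_dim:
        raise FeatureManifestError(
            f"feature dimension {x.shape[1]} does not match model ({model.feature_dim})")
    if len(model.support_vectors):
        k = kernel_matrix(x, model.support_vectors, model.hyperparams)
        raw = k @ model.dual_coef + model.bias
    else:
        raw = np.full(len(x), model.bias)
    out = raw * TARGET_SCALE
    return out if np.asarray(features).ndim > 1 else float(out[0])


def kkt_report(model: StackedModel, features: np.ndarray, targets: np.ndarray,
               slack: float = 1e-6) -> dict:
    """Check Karush-Kuhn-Tucker conditions of a fit on its training data.

    Conditions checked (on /1000-scaled residuals r = f(x) - y):
      * every dual coefficient satisfies |alpha| <= C;
      * rows strictly inside the epsilon tube carry zero dual coefficient;
      * bound support vectors (|alpha| = C) lie on or outside the tube.
    ``slack`` absorbs solver tolerance; the solver's own ``tolerance`` is
    added where the condition depends on convergence accuracy.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64) / TARGET_SCALE
    hp = model.hyperparams
    pred = np.atleast_1d(np.asarray(predict_stack(model, x))) / TARGET_SCALE
    residual = pred - y

    alpha = np.zeros(len(x))
    if len(model.support_vectors):
        d = euclidean_distances(x, model.support_vectors)
        for j in np.flatnonzero(np.isclose(d, 0.0).any(axis=1)):
            alpha[j] = model.dual_coef[int(np.argmin(d[j]))]

    tol = hp.tolerance + slack
    box_ok = bool(np.all(np.abs(model.dual_coef) <= hp.C * (1 + 1e-9) + slack))
    inside = np.abs(residual) < hp.epsilon - tol
    inside_zero_ok = bool(np.all(np.abs(alpha[inside]) <= slack))
    bound = np.abs(np.abs(alpha) - hp.C) <= hp.C * 1e-9 + slack
    bound_outside_ok = bool(np.all(np.abs(residual[bound & (alpha != 0)])
                                   >= hp.epsilon - tol))
    return {
        "box_constraint": box_ok,
        "inside_tube_zero_coef": inside_zero_ok,
        "bound_sv_outside_tube": bound_outside_ok,
        "n_support": int(len(model.support_vectors)),
        "ok": box_ok and inside_zero_ok and bound_outside_ok,
    }
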