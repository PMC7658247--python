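"""Stacked meta-models over constituent predictor scores.

The stack treats each constituent ddG predictor's output as one feature
and learns a regression from the feature vector to the experimental
ddG_binding.  Two model families are supported:

* Gaussian-process regression (GPR) with a ``constant * RBF + white noise``
  kernel.  Kernel hyperparameters (amplitude, shared length-scale, noise
  level) are chosen by maximizing the log marginal likelihood on the
  training data alone, so no validation split is needed.
* Random-forest regression (RFR) with squared-error splits, bootstrap
  resampling, unlimited depth and all features considered at every split.
  The number of trees is the one tuned hyperparameter (selected by the
  nested cross-validation harness, not here).

Features are standardized per column with statistics learned on the
training data; the target is centered for GPR so the GP prior mean of
zero is appropriate.  Both transforms are stored on the fitted model and
re-applied at predict time — no test-set statistics ever enter the
transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .errors import FitError, ModelKindError, SchemaError, TableValidationError

__all__ = [
    "StackSpec",
    "FittedStack",
    "fit_gpr",
    "fit_rfr",
    "predict",
    "gini_importance",
    "save_stack",
    "load_stack",
]

_ARCHIVE_VERSION = 1


@dataclass(frozen=True)
class StackSpec:
    """Configuration of a stacked meta-model.

    Parameters
    ----------
    model_kind
        ``"gpr"`` or ``"rfr"``.
    gpr_amplitude_bounds, gpr_length_scale_bounds, gpr_noise_bounds
        Log-uniform search bounds for the kernel hyperparameters.  The
        noise floor of 1e-6 (on the centered-target scale) prevents
        degenerate noise-free fits on noisy ddG data.
    gpr_n_restarts
        Seeded random restarts for the marginal-likelihood optimizer, on
        top of the default initialization.
    rfr_tree_grid
        Strictly increasing candidate tree counts for nested-CV selection.
    standardize_features
        Per-column feature standardization (mean 0, sd 1 on training
        data).  Matters for GPR, where one RBF length-scale is shared
        across features; harmless for RFR.
    seed
        Seeds the GPR restart initializations and the RFR bootstrap.
    """

    model_kind: str = "gpr"
    gpr_amplitude_bounds: tuple[float, float] = (1e-3, 1e3)
    gpr_length_scale_bounds: tuple[float, float] = (1e-2, 1e3)
    gpr_noise_bounds: tuple[float, float] = (1e-6, 1e1)
    gpr_n_restarts: int = 2
    rfr_tree_grid: tuple[int, ...] = (16, 64, 128, 256, 512)
    standardize_features: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in ("gpr", "rfr"):
            raise ModelKindError(f"unknown model_kind {self.model_kind!r}")
        if not self.rfr_tree_grid:
            raise TableValidationError("rfr_tree_grid must be non-empty")
        if any(b <= a for a, b in zip(self.rfr_tree_grid, self.rfr_tree_grid[1:])):
            raise TableValidationError("rfr_tree_grid must be strictly increasing")
        if min(self.rfr_tree_grid) < 1:
            raise TableValidationError("tree counts must be >= 1")
        for lo, hi in (
            self.gpr_amplitude_bounds,
            self.gpr_length_scale_bounds,
            self.gpr_noise_bounds,
        ):
            if not (0 < lo < hi < np.inf):
                raise TableValidationError(
                    "hyperparameter bounds must be positive, finite and ordered"
                )


@dataclass
class FittedStack:
    """A trained meta-model plus everything needed to reapply it.

    ``predictor_names`` freezes the feature order at fit time; `predict`
    requires the same order (align by name before calling).
    """

    spec: StackSpec
    predictor_names: list[str]
    model: object
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    target_center: float
    n_trees: int | None = None  # populated for RFR


def _check_training_inputs(features: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2:
        raise TableValidationError("features must be a 2-D matrix")
    if y.shape != (X.shape[0],):
        raise SchemaError(f"targets shape {y.shape} does not match {X.shape[0]} rows")
    if X.shape[0] < 8:
        raise TableValidationError(f"need at least 8 training rows, got {X.shape[0]}")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise TableValidationError("non-finite values in training inputs")
    return X, y


def _standardize_fit(X: np.ndarray, spec: StackSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not spec.standardize_features:
        return X, np.zeros(X.shape[1]), np.ones(X.shape[1])
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns pass through centered
    return (X - mean) / sd, mean, sd


def _names_for(features: np.ndarray, names: Sequence[str] | None) -> list[str]:
    if names is None:
        return [f"f{j}" for j in range(features.shape[1])]
    names = list(names)
    if len(names) != features.shape[1]:
        raise SchemaError(
            f"{len(names)} feature names for {features.shape[1]} feature columns"
        )
    return names


def fit_gpr(
    features: np.ndarray,
    targets: np.ndarray,
    spec: StackSpec | None = None,
    feature_names: Sequence[str] | None = None,
) -> FittedStack:
    """Fit the Gaussian-process stack.

    Hyperparameters of the ``constant * RBF + white`` kernel are set by
    maximizing the log marginal likelihood on (features, targets) only,
    with ``spec.gpr_n_restarts`` seeded restarts.  Deterministic for a
    fixed ``spec.seed``.
    """
    spec = spec or StackSpec(model_kind="gpr")
    if spec.model_kind != "gpr":
        raise ModelKindError("fit_gpr requires spec.model_kind = 'gpr'")
    X, y = _check_training_inputs(features, targets)
    names = _names_for(X, feature_names)
    Xs, mean, sd = _standardize_fit(X, spec)
    center = float(y.mean())
    # Initialization matters: the LML surface has a spurious basin where the
    # length-scale collapses and the GP degenerates to a constant predictor.
    # Starting the noise at the centered-target variance scale and the
    # length-scale at the typical inter-point distance of standardized
    # features (~sqrt(d)) avoids it.
    kernel = (
        ConstantKernel(1.0, spec.gpr_amplitude_bounds)
        * RBF(float(np.sqrt(X.shape[1])), spec.gpr_length_scale_bounds)
        + WhiteKernel(1.0, spec.gpr_noise_bounds)
    )
    gp = GaussianProcessRegressor(
        kernel=kernel,
        n_restarts_optimizer=spec.gpr_n_restarts,
        normalize_y=False,
        random_state=spec.seed,
    )
    try:
        gp.fit(Xs, y - center)
    except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
        raise FitError(f"GPR marginal-likelihood optimization failed: {exc}") from exc
    return FittedStack(
        spec=spec,
        predictor_names=names,
        model=gp,
        feature_mean=mean,
        feature_sd=sd,
        target_center=center,
    )


def fit_rfr(
    features: np.ndarray,
    targets: np.ndarray,
    n_trees: int,
    spec: StackSpec | None = None,
    feature_names: Sequence[str] | None = None,
) -> FittedStack:
    """Fit the random-forest stack with a fixed number of trees.

    Squared-error splits, bootstrap resampling, unlimited depth, all
    features considered at every split.  Deterministic for a fixed
    ``spec.seed``.
    """
    spec = spec or StackSpec(model_kind="rfr")
    if spec.model_kind != "rfr":
        raise ModelKindError("fit_rfr requires spec.model_kind = 'rfr'")
    if n_trees < 1:
        raise TableValidationError(f"n_trees must be >= 1, got {n_trees}")
    X, y = _check_training_inputs(features, targets)
    names = _names_for(X, feature_names)
    Xs, mean, sd = _standardize_fit(X, spec)
    rf = RandomForestRegressor(
        n_estimators=int(n_trees),
        criterion="squared_error",
        max_depth=None,
        max_features=1.0,
        bootstrap=True,
        random_state=spec.seed,
        n_jobs=1,
    )
    rf.fit(Xs, y)
    return FittedStack(
        spec=spec,
        predictor_names=names,
        model=rf,
        feature_mean=mean,
        feature_sd=sd,
        target_center=0.0,
        n_trees=int(n_trees),
    )


def predict(model: FittedStack, features: np.ndarray) -> np.ndarray:
    """Predict ddG_binding for rows of ``features``.

    ``features`` columns must be in ``model.predictor_names`` order; the
    stored standardization and target centering are reapplied.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise SchemaError("features must be a 2-D matrix")
    if X.shape[1] != len(model.predictor_names):
        raise SchemaError(
            f"model expects {len(model.predictor_names)} feature columns "
            f"({model.predictor_names}), got {X.shape[1]}"
        )
    if X.shape[0] == 0:
        return np.empty(0, dtype=float)
    if not np.all(np.isfinite(X)):
        raise TableValidationError("non-finite values in prediction features")
    Xs = (X - model.feature_mean) / model.feature_sd
    yhat = np.asarray(model.model.predict(Xs), dtype=float)
    return yhat + model.target_center


def gini_importance(model: FittedStack) -> np.ndarray:
    """Mean-decrease-in-impurity importance of each feature.

    Averaged over the forest's trees and normalized to sum to one; only
    defined for the RFR stack.
    """
    if model.spec.model_kind != "rfr" or not isinstance(model.model, RandomForestRegressor):
        raise ModelKindError("Gini importance is only defined for the RFR stack")
    imp = np.asarray(model.model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return imp


def save_stack(model: FittedStack, path: str | Path) -> None:
    """Serialize a fitted stack as a versioned archive."""
    payload = {
        "format": "ddgstack.FittedStack",
        "version": _ARCHIVE_VERSION,
        "spec": model.spec,
        "predictor_names": model.predictor_names,
        "model": model.model,
        "feature_mean": model.feature_mean,
        "feature_sd": model.feature_sd,
        "target_center": model.target_center,
        "n_trees": model.n_trees,
    }
    joblib.dump(payload, path)


def load_stack(path: str | Path) -> FittedStack:
    """Load a fitted stack, refusing incompatible archive versions."""
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != "ddgstack.FittedStack":
        raise SchemaError(f"{path}: not a ddgstack model archive")
    if payload.get("version") != _ARCHIVE_VERSION:
        raise SchemaError(
            f"{path}: archive version {payload.get('version')} is incompatible "
            f"with supported version {_ARCHIVE_VERSION}"
        )
    return FittedStack(
        spec=payload["spec"],
        predictor_names=list(payload["predictor_names"]),
        model=payload["model"],
        feature_mean=payload["feature_mean"],
        feature_sd=payload["feature_sd"],
        target_center=payload["target_center"],
        n_trees=payload["n_trees"],
    )
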