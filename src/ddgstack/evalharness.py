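"""Repeated (nested) cross-validation evaluation of ddG predictors.

Implements the full comparison protocol:

* repeated k-fold cross-validation (default: 100 repeats of 4 folds) with
  the repeat-level score defined as the unweighted mean, over outer test
  folds, of the Pearson correlation between predicted and experimental
  ddG_binding;
* nested CV for the random-forest stack, where an inner k-fold loop
  selects the number of trees strictly inside each outer training set;
* plain CV for the Gaussian-process stack, whose kernel hyperparameters
  are set by marginal likelihood on training data and need no validation
  split;
* paired method comparison via the Wilcoxon signed-rank test over
  per-repeat scores, with common fold assignments across methods (common
  random numbers);
* a leakage firewall that substitutes leakage-safe values for cells of a
  machine-learning constituent predictor that overlap its own training
  data;
* inter-predictor correlation and importance-based feature reduction.

Every repeat's fold assignment (and, for nested CV, every inner split and
selected tree count) is recorded in an audit trail so that CV hygiene can
be proven rather than assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateDataError,
    FirewallError,
    PairingError,
    SchemaError,
    TableValidationError,
    UndefinedCorrelationError,
)
from .stack import StackSpec, fit_gpr, fit_rfr, gini_importance, predict
from .tables import FeatureTable

__all__ = [
    "FoldAssignment",
    "CVScheme",
    "EvaluationResult",
    "make_folds",
    "pearson_r",
    "sem",
    "wilcoxon_signed_rank",
    "cv_evaluate_gpr",
    "nested_cv_evaluate_rfr",
    "cv_evaluate_precomputed",
    "apply_leakage_firewall",
    "detect_firewall_violations",
    "predictor_correlation_matrix",
    "select_features_by_importance",
    "train_test_evaluate",
    "compare_methods",
    "verify_cv_hygiene",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldAssignment:
    """A balanced random partition of ``n`` items into ``k`` folds."""

    n: int
    k: int
    seed: int
    labels: np.ndarray  # shape (n,), values in [0, k)

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels == fold)

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_indices, test_indices) for one fold."""
        test = self.indices(fold)
        train = np.flatnonzero(self.labels != fold)
        return train, test


def make_folds(n: int, k: int, seed: int) -> FoldAssignment:
    """Uniformly random balanced partition, deterministic given ``seed``.

    Fold sizes differ by at most one; the ``n mod k`` larger folds get the
    lower fold labels.
    """
    if k < 2:
        raise TableValidationError(f"need k >= 2 folds, got {k}")
    if k > n:
        raise TableValidationError(f"cannot split n={n} items into k={k} folds")
    rng = np.random.default_rng(seed)
    sizes = np.full(k, n // k, dtype=int)
    sizes[: n % k] += 1
    fold_seq = np.repeat(np.arange(k), sizes)
    labels = np.empty(n, dtype=int)
    labels[rng.permutation(n)] = fold_seq
    labels.setflags(write=False)
    return FoldAssignment(n=n, k=k, seed=seed, labels=labels)


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SchemaError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise UndefinedCorrelationError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return float(np.clip(r, -1.0, 1.0))


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean: sample sd (ddof=1) / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise TableValidationError(f"SEM needs at least 2 values, got {v.size}")
    return float(v.std(ddof=1) / np.sqrt(v.size))


_EXACT_MAX_N = 25


def wilcoxon_signed_rank(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "auto",
) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test on ``a - b``.

    Zero differences are dropped (Wilcoxon's original treatment); tied
    absolute differences receive midranks.  Returns ``(W_plus, p)`` where
    ``W_plus`` is the rank sum of positive differences.

    ``method``: ``"exact"`` enumerates the null distribution of W+ over
    all sign assignments (via a rank-sum convolution, so ties are handled
    exactly); ``"approx"`` uses the normal approximation with continuity
    and tie corrections; ``"auto"`` picks exact for effective n <= 25.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise SchemaError(f"shape mismatch: {a.shape} vs {b.shape}")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())

    if method == "auto":
        method = "exact" if n <= _EXACT_MAX_N else "approx"
    if method == "exact":
        p = _exact_signed_rank_p(ranks, w_plus)
    elif method == "approx":
        p = _approx_signed_rank_p(ranks, w_plus, n)
    else:
        raise ValueError(f"unknown method {method!r}")
    return w_plus, p


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    # Work on doubled ranks so midranks (k + 1/2) become integers.
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    # counts[s] = number of sign assignments with doubled W+ equal to s
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= 2.0 ** len(r2)
    w2 = int(np.rint(2 * w_plus))
    p_ge = counts[w2:].sum()
    p_le = counts[: w2 + 1].sum()
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def _approx_signed_rank_p(ranks: np.ndarray, w_plus: float, n: int) -> float:
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise DegenerateDataError("zero variance in signed-rank null distribution")
    dev = w_plus - mu
    # continuity correction toward the mean
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Evaluation schemes and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVScheme:
    """Repeated cross-validation layout.

    Repeat ``r`` derives its fold seed as ``master_seed + r``, so two
    methods evaluated under an equal scheme see identical fold
    assignments in every repeat (paired comparison by common random
    numbers).  ``k_inner`` is used only by the nested RFR loop.
    """

    k_outer: int = 4
    k_inner: int = 4
    n_repeats: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_outer < 2:
            raise TableValidationError("k_outer must be >= 2")
        if self.k_inner < 2:
            raise TableValidationError("k_inner must be >= 2")
        if self.n_repeats < 1:
            raise TableValidationError("n_repeats must be >= 1")

    def repeat_seed(self, r: int) -> int:
        return self.master_seed + r


@dataclass
class EvaluationResult:
    """Per-repeat Pearson correlations of one method, with audit trail.

    ``per_repeat_r[r]`` is the mean over outer test folds of repeat ``r``;
    ``mean_r`` / ``sem_r`` aggregate over repeats.  ``audit`` holds the
    fold labels of every repeat plus, for nested RFR, the inner splits and
    selected tree counts.
    """

    method_label: str
    per_repeat_r: np.ndarray
    mean_r: float
    sem_r: float
    scheme: CVScheme
    audit: dict = field(default_factory=dict)

    @classmethod
    def from_repeats(
        cls, label: str, per_repeat_r: Sequence[float], scheme: CVScheme, audit: dict
    ) -> "EvaluationResult":
        arr = np.asarray(per_repeat_r, dtype=float)
        return cls(
            method_label=label,
            per_repeat_r=arr,
            mean_r=float(arr.mean()),
            sem_r=sem(arr) if arr.size >= 2 else float("nan"),
            scheme=scheme,
            audit=audit,
        )


def _fold_r(
    predictions: np.ndarray, targets: np.ndarray, repeat: int, fold: int
) -> float:
    # A model that predicts a constant (e.g. a GP that has honestly collapsed
    # to its noise-only optimum on uninformative features) carries no linear
    # association with the target: score the fold 0 rather than erroring, so
    # null evaluations stay well-defined.  A constant *target* is still an
    # error — the fold cannot be scored at all.
    if np.ptp(targets) == 0:
        raise UndefinedCorrelationError(
            f"repeat {repeat}, fold {fold}: constant target in test fold"
        )
    if np.ptp(predictions) == 0:
        logger.debug("repeat %d, fold %d: constant predictions, R := 0", repeat, fold)
        return 0.0
    try:
        return pearson_r(predictions, targets)
    except UndefinedCorrelationError as exc:
        raise UndefinedCorrelationError(
            f"repeat {repeat}, fold {fold}: {exc}"
        ) from exc


def cv_evaluate_gpr(
    table: FeatureTable,
    feature_subset: Sequence[str] | None = None,
    spec: StackSpec | None = None,
    scheme: CVScheme | None = None,
    label: str | None = None,
) -> EvaluationResult:
    """Repeated k-fold CV of the GPR stack.

    For each repeat and outer fold the GP is refit from scratch on the
    training folds (kernel hyperparameters by marginal likelihood, no
    validation data) and scored on the held-out fold.
    """
    spec = spec or StackSpec(model_kind="gpr")
    scheme = scheme or CVScheme()
    names = list(feature_subset) if feature_subset is not None else table.predictor_names
    if not names:
        raise SchemaError("feature_subset must be non-empty")
    X = table.feature_matrix(names)
    y = table.ddg_exp
    per_repeat: list[float] = []
    fold_labels: list[np.ndarray] = []
    for r in range(scheme.n_repeats):
        folds = make_folds(table.n_records, scheme.k_outer, scheme.repeat_seed(r))
        fold_labels.append(folds.labels)
        fold_rs = []
        for f in range(scheme.k_outer):
            train, test = folds.split(f)
            model = fit_gpr(X[train], y[train], spec, feature_names=names)
            yhat = predict(model, X[test])
            fold_rs.append(_fold_r(yhat, y[test], r, f))
        per_repeat.append(float(np.mean(fold_rs)))
        logger.debug("gpr repeat %d/%d: R=%.4f", r + 1, scheme.n_repeats, per_repeat[-1])
    audit = {"fold_labels": fold_labels, "features": names}
    return EvaluationResult.from_repeats(label or "gpr-stack", per_repeat, scheme, audit)


def _select_n_trees(
    X: np.ndarray,
    y: np.ndarray,
    spec: StackSpec,
    k_inner: int,
    inner_seed: int,
    names: Sequence[str],
) -> tuple[int, FoldAssignment]:
    """Inner-CV selection of the tree count (ties -> smallest count)."""
    inner = make_folds(X.shape[0], k_inner, inner_seed)
    best_trees, best_r = None, -np.inf
    for n_trees in spec.rfr_tree_grid:
        rs = []
        for f in range(k_inner):
            tr, va = inner.split(f)
            model = fit_rfr(X[tr], y[tr], n_trees, spec, feature_names=names)
            rs.append(pearson_r(predict(model, X[va]), y[va]))
        mean_r = float(np.mean(rs))
        if mean_r > best_r:  # strict: ties keep the smaller, earlier count
            best_trees, best_r = n_trees, mean_r
    assert best_trees is not None
    return best_trees, inner


def nested_cv_evaluate_rfr(
    table: FeatureTable,
    feature_subset: Sequence[str] | None = None,
    spec: StackSpec | None = None,
    scheme: CVScheme | None = None,
    label: str | None = None,
) -> EvaluationResult:
    """Repeated nested k-fold CV of the RFR stack.

    The outer loop matches :func:`cv_evaluate_gpr`; inside each outer
    training set, a ``k_inner``-fold CV picks the tree count from
    ``spec.rfr_tree_grid`` by maximal mean validation Pearson R (ties go
    to the smallest count), the forest is refit on the full outer
    training set, and scored on the outer test fold.  The audit records
    every inner split and selected tree count; outer test indices never
    enter an inner loop (checkable via :func:`verify_cv_hygiene`).
    """
    spec = spec or StackSpec(model_kind="rfr")
    scheme = scheme or CVScheme()
    names = list(feature_subset) if feature_subset is not None else table.predictor_names
    if not names:
        raise SchemaError("feature_subset must be non-empty")
    X = table.feature_matrix(names)
    y = table.ddg_exp
    per_repeat: list[float] = []
    fold_labels: list[np.ndarray] = []
    selected: list[list[int]] = []
    inner_audit: list[list[dict]] = []
    for r in range(scheme.n_repeats):
        folds = make_folds(table.n_records, scheme.k_outer, scheme.repeat_seed(r))
        fold_labels.append(folds.labels)
        fold_rs = []
        sel_r: list[int] = []
        inner_r: list[dict] = []
        for f in range(scheme.k_outer):
            train, test = folds.split(f)
            inner_seed = (scheme.repeat_seed(r) + 1) * 1000 + f
            n_trees, inner = _select_n_trees(
                X[train], y[train], spec, scheme.k_inner, inner_seed, names
            )
            sel_r.append(n_trees)
            inner_r.append(
                {
                    "outer_fold": f,
                    "train_indices": train,
                    "test_indices": test,
                    # inner labels are positions within `train`; map back to
                    # table indices for the audit
                    "inner_member_indices": train,
                    "inner_labels": inner.labels,
                }
            )
            model = fit_rfr(X[train], y[train], n_trees, spec, feature_names=names)
            yhat = predict(model, X[test])
            fold_rs.append(_fold_r(yhat, y[test], r, f))
        per_repeat.append(float(np.mean(fold_rs)))
        selected.append(sel_r)
        inner_audit.append(inner_r)
        logger.debug("rfr repeat %d/%d: R=%.4f trees=%s",
                     r + 1, scheme.n_repeats, per_repeat[-1], sel_r)
    audit = {
        "fold_labels": fold_labels,
        "selected_n_trees": selected,
        "inner": inner_audit,
        "features": names,
    }
    return EvaluationResult.from_repeats(label or "rfr-stack", per_repeat, scheme, audit)


def cv_evaluate_precomputed(
    table: FeatureTable,
    scores: Sequence[float],
    label: str,
    scheme: CVScheme | None = None,
) -> EvaluationResult:
    """Evaluate a fixed per-record score vector under the shared CV layout.

    Used for single predictors and consensus baselines, which require no
    training: each outer test fold scores the restriction of ``scores`` to
    that fold against the experimental target, so the result is paired
    repeat-by-repeat (same folds) with any trained method evaluated under
    an equal scheme.
    """
    scheme = scheme or CVScheme()
    s = np.asarray(scores, dtype=float)
    if s.shape != (table.n_records,):
        raise SchemaError(
            f"scores shape {s.shape} does not match {table.n_records} records"
        )
    y = table.ddg_exp
    per_repeat: list[float] = []
    fold_labels: list[np.ndarray] = []
    for r in range(scheme.n_repeats):
        folds = make_folds(table.n_records, scheme.k_outer, scheme.repeat_seed(r))
        fold_labels.append(folds.labels)
        fold_rs = []
        for f in range(scheme.k_outer):
            _, test = folds.split(f)
            fold_rs.append(_fold_r(s[test], y[test], r, f))
        per_repeat.append(float(np.mean(fold_rs)))
    audit = {"fold_labels": fold_labels}
    return EvaluationResult.from_repeats(label, per_repeat, scheme, audit)


# ---------------------------------------------------------------------------
# Leakage firewall
# ---------------------------------------------------------------------------


def detect_firewall_violations(table: FeatureTable) -> list[tuple[str, str]]:
    """Flagged (record_id, predictor) cells lacking a leakage-safe substitute."""
    return sorted(k for k in table.firewall_flags if k not in table.firewall_substitutes)


def apply_leakage_firewall(table: FeatureTable) -> FeatureTable:
    """Replace leakage-flagged cells with their leakage-safe substitutes.

    Cells of a machine-learning constituent predictor that overlap its own
    training data would leak the experimental answer into evaluation; the
    substitutes (typically the constituent's published cross-validated
    predictions) are safe to use anywhere.  All unflagged cells are
    untouched.  Raises :class:`FirewallError` listing every flagged cell
    without a substitute.
    """
    missing = detect_firewall_violations(table)
    if missing:
        raise FirewallError(
            f"{len(missing)} leakage-flagged cell(s) lack substitutes: {missing}",
            offending=missing,
        )
    scores = table.scores.copy()
    row_of = {rid: i for i, rid in enumerate(table.record_ids)}
    col_of = {name: j for j, name in enumerate(table.predictor_names)}
    for rid, pname in table.firewall_flags:
        scores[row_of[rid], col_of[pname]] = table.firewall_substitutes[(rid, pname)]
    return FeatureTable(
        records=list(table.records),
        predictors=list(table.predictors),
        scores=scores,
        firewall_substitutes=dict(table.firewall_substitutes),
        firewall_flags=set(table.firewall_flags),
    )


# ---------------------------------------------------------------------------
# Predictor correlation and feature reduction
# ---------------------------------------------------------------------------


def predictor_correlation_matrix(
    table: FeatureTable, subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlation between predictor score columns."""
    names = list(subset) if subset is not None else table.predictor_names
    X = table.feature_matrix(names)
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise UndefinedCorrelationError(f"predictor {name!r} is constant")
    m = np.corrcoef(X, rowvar=False)
    m = np.atleast_2d(m)
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return pd.DataFrame(m, index=names, columns=names)


def select_features_by_importance(
    importances: Mapping[str, float],
    mode: str,
    value: float | int,
) -> list[str]:
    """Pick predictors by importance, ordered descending.

    ``mode="threshold"`` keeps names with importance strictly above
    ``value``; ``mode="top_k"`` keeps the ``value`` largest.  Ties are
    broken by the insertion order of ``importances`` (registry order),
    deterministically.
    """
    names = list(importances)
    vals = np.array([importances[n] for n in names], dtype=float)
    if np.any(vals < 0):
        raise TableValidationError("importances must be non-negative")
    order = sorted(range(len(names)), key=lambda i: (-vals[i], i))
    if mode == "threshold":
        return [names[i] for i in order if vals[i] > float(value)]
    if mode == "top_k":
        k = int(value)
        if k > len(names):
            raise TableValidationError(
                f"top_k = {k} exceeds the {len(names)} available features"
            )
        return [names[i] for i in order[:k]]
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Independent-data evaluation and method comparison
# ---------------------------------------------------------------------------


def train_test_evaluate(
    train: FeatureTable,
    test: FeatureTable,
    feature_subset: Sequence[str] | None = None,
    spec: StackSpec | None = None,
) -> float:
    """Train on one table, score Pearson R on an independent table.

    The leakage firewall is applied to the training table before fitting.
    For the RFR stack, the tree count is selected by an internal 4-fold CV
    on the training table.
    """
    spec = spec or StackSpec(model_kind="gpr")
    names = list(feature_subset) if feature_subset is not None else train.predictor_names
    for name in names:
        if name not in test.predictor_names:
            raise SchemaError(f"predictor {name!r} missing from the test table")
    train = apply_leakage_firewall(train)
    X_tr = train.feature_matrix(names)
    y_tr = train.ddg_exp
    if spec.model_kind == "gpr":
        model = fit_gpr(X_tr, y_tr, spec, feature_names=names)
    else:
        n_trees, _ = _select_n_trees(X_tr, y_tr, spec, 4, spec.seed, names)
        model = fit_rfr(X_tr, y_tr, n_trees, spec, feature_names=names)
    yhat = predict(model, test.feature_matrix(names))
    return pearson_r(yhat, test.ddg_exp)


def compare_methods(results: Sequence[EvaluationResult]) -> pd.DataFrame:
    """Summary plus all pairwise Wilcoxon comparisons of evaluation results.

    All results must share ``n_repeats`` and ``master_seed`` so the
    per-repeat scores are paired by common fold assignments.  Rows with
    ``row_type="method"`` carry ``mean_r`` and ``sem_r``; rows with
    ``row_type="comparison"`` carry the signed-rank statistic and
    two-sided p (``note="identical"`` when every paired difference is
    zero).
    """
    if len(results) < 1:
        raise PairingError("no results to compare")
    ref = results[0].scheme
    for res in results[1:]:
        if res.scheme.n_repeats != ref.n_repeats or res.scheme.master_seed != ref.master_seed:
            raise PairingError(
                f"{res.method_label!r} uses scheme {res.scheme}, not pairable "
                f"with {results[0].method_label!r} ({ref})"
            )
    rows: list[dict] = []
    for res in results:
        rows.append(
            {
                "row_type": "method",
                "method": res.method_label,
                "versus": "",
                "mean_r": res.mean_r,
                "sem_r": res.sem_r,
                "statistic": np.nan,
                "p_value": np.nan,
                "note": "",
            }
        )
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            a, b = results[i], results[j]
            try:
                w, p = wilcoxon_signed_rank(a.per_repeat_r, b.per_repeat_r)
                note = ""
            except DegenerateDataError:
                w, p, note = np.nan, np.nan, "identical"
            rows.append(
                {
                    "row_type": "comparison",
                    "method": a.method_label,
                    "versus": b.method_label,
                    "mean_r": a.mean_r - b.mean_r,
                    "sem_r": np.nan,
                    "statistic": w,
                    "p_value": p,
                    "note": note,
                }
            )
    return pd.DataFrame(rows)


def averaged_gini_importance(
    table: FeatureTable,
    feature_subset: Sequence[str] | None = None,
    spec: StackSpec | None = None,
    scheme: CVScheme | None = None,
    n_trees: int = 256,
) -> dict[str, float]:
    """Gini importance averaged over the outer-fold RFR fits of all repeats.

    One forest of ``n_trees`` is fit per outer training fold of every
    repeat; the per-fit normalized importances are averaged, so the result
    sums to one.  Returned in table column order (insertion order), which
    downstream tie-breaking relies on.
    """
    spec = spec or StackSpec(model_kind="rfr")
    scheme = scheme or CVScheme()
    names = list(feature_subset) if feature_subset is not None else table.predictor_names
    X = table.feature_matrix(names)
    y = table.ddg_exp
    acc = np.zeros(len(names))
    count = 0
    for r in range(scheme.n_repeats):
        folds = make_folds(table.n_records, scheme.k_outer, scheme.repeat_seed(r))
        for f in range(scheme.k_outer):
            train, _ = folds.split(f)
            model = fit_rfr(X[train], y[train], n_trees, spec, feature_names=names)
            acc += gini_importance(model)
            count += 1
    acc /= count
    return dict(zip(names, acc.tolist()))


def verify_cv_hygiene(result: EvaluationResult) -> bool:
    """Audit that every repeat's folds partition the data and, for nested
    CV, that no outer test index appears in any inner split of the same
    outer iteration.  Returns True; raises :class:`TableValidationError`
    with the first violation otherwise."""
    scheme = result.scheme
    for r, labels in enumerate(result.audit.get("fold_labels", [])):
        labels = np.asarray(labels)
        if labels.min() < 0 or labels.max() >= scheme.k_outer:
            raise TableValidationError(f"repeat {r}: fold label out of range")
        sizes = np.bincount(labels, minlength=scheme.k_outer)
        if sizes.max() - sizes.min() > 1:
            raise TableValidationError(f"repeat {r}: unbalanced folds {sizes}")
    for r, inner_r in enumerate(result.audit.get("inner", [])):
        for entry in inner_r:
            test = set(np.asarray(entry["test_indices"]).tolist())
            inner_members = set(np.asarray(entry["inner_member_indices"]).tolist())
            overlap = test & inner_members
            if overlap:
                raise TableValidationError(
                    f"repeat {r}, outer fold {entry['outer_fold']}: outer test "
                    f"indices {sorted(overlap)} leaked into the inner loop"
                )
            if len(entry["inner_labels"]) != len(entry["train_indices"]):
                raise TableValidationError(
                    f"repeat {r}, outer fold {entry['outer_fold']}: inner fold "
                    "labels do not cover the outer training set"
                )
    return True
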