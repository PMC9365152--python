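"""Random-forest regression of regional mutation burden on epigenome tracks.

The central model regresses per-window SNV counts on per-window mean
chromatin-accessibility (CA) and replication-timing (RT) signals with a
random forest (1000 trees, one third of predictors tried at each split).
Accuracy is adjusted R² on held-out windows under Monte-Carlo
cross-validation: 1000 random 80/20 window splits by default.

The paired comparison asks whether CA profiles of cancers predict
regional burden better than CA profiles of normal tissues. Both arms are
trained on identical window splits — each with its own CA profiles plus
the same shared RT profiles — and the per-split difference in held-out
adjusted R², Δadj.R² = adj.R²(cancer arm) − adj.R²(normal arm), gives a
median effect, a 95% percentile interval and an empirical p-value (the
fraction of splits falling on the opposite side of zero from the median).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of the forest and the cross-validation design.

    ``mtry_fraction`` mirrors the classic regression-forest default of
    p/3 predictors per split; ``min_node_size`` the regression default
    terminal-node size of 5. ``n_trees=1000`` and ``n_splits=1000`` are
    the full analysis settings; tests use reduced values through the
    same type.
    """

    n_trees: int = 1000
    mtry_fraction: float = 1.0 / 3.0
    seed: int = 0
    train_fraction: float = 0.8
    n_splits: int = 1000
    min_node_size: int = 5

    def __post_init__(self):
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0 < self.mtry_fraction <= 1):
            raise ValueError("mtry_fraction must be in (0, 1]")

    def reduced(self, n_trees: int = 100, n_splits: int = 100) -> "ModelSpec":
        return replace(self, n_trees=n_trees, n_splits=n_splits)


@dataclass
class FitResult:
    """A trained forest with out-of-bag predictions and residuals.

    Residuals are observed minus out-of-bag predicted burden: OOB
    predictions keep each window's own influence out of its expectation,
    so residual variance is not deflated by overfitting.
    """

    model: RandomForestRegressor
    feature_names: list[str]
    oob_prediction: np.ndarray
    residuals: np.ndarray
    oob_adj_r2: float


@dataclass
class ComparisonResult:
    """Paired MCCV output for the cancer-vs-normal predictor contrast."""

    deltas: np.ndarray
    adj_r2_cancer: np.ndarray
    adj_r2_normal: np.ndarray
    median_delta: float
    ci_low: float
    ci_high: float
    empirical_p: float
    n_splits: int
    n_crossed: float = 0.0

    @property
    def p_label(self) -> str:
        """No split crossing zero is reported below the resolution floor."""
        return f"< {1.0 / self.n_splits:g}" if self.n_crossed == 0 else f"{self.empirical_p:g}"

    def to_frame(self, cohort: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cohort": cohort,
                    "median_delta_adj_r2": self.median_delta,
                    "ci_low": self.ci_low,
                    "ci_high": self.ci_high,
                    "empirical_p": self.empirical_p,
                    "p_label": self.p_label,
                    "median_adj_r2_cancer": float(np.median(self.adj_r2_cancer)),
                    "median_adj_r2_normal": float(np.median(self.adj_r2_normal)),
                }
            ]
        )


def adjusted_r2(observed: np.ndarray, predicted: np.ndarray, p_predictors: int) -> float:
    """R² penalised for model complexity.

    ``1 - (1 - R²)(n - 1)/(n - p - 1)`` with ``R² = 1 - SSres/SStot``;
    equals plain R² at ``p = 0``. Undefined when ``n <= p + 1``.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    n = len(observed)
    if n != len(predicted):
        raise ValueError("length mismatch")
    if n <= p_predictors + 1:
        raise ValueError("adjustment undefined: need n > p_predictors + 1")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed has zero variance")
    r2 = 1.0 - float(np.sum((observed - predicted) ** 2)) / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p_predictors - 1)


def _make_forest(spec: ModelSpec, seed: int, oob: bool = False) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_features=spec.mtry_fraction,
        min_samples_leaf=spec.min_node_size,
        bootstrap=True,
        oob_score=oob,
        n_jobs=1,
        random_state=int(seed),
    )


def _as_matrix(features: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), [str(c) for c in features.columns]
    X = np.asarray(features, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def fit_forest(
    features: pd.DataFrame | np.ndarray,
    response: np.ndarray,
    spec: ModelSpec,
) -> FitResult:
    """Train the forest on all windows and return OOB-based diagnostics."""
    X, names = _as_matrix(features)
    y = np.asarray(response, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("feature rows must align with response windows")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: zero variance")
    model = _make_forest(spec, spec.seed, oob=True).fit(X, y)
    oob = np.asarray(model.oob_prediction_, dtype=float)
    p = X.shape[1]
    adj = adjusted_r2(y, oob, p) if len(y) > p + 1 else float("nan")
    return FitResult(
        model=model,
        feature_names=names,
        oob_prediction=oob,
        residuals=y - oob,
        oob_adj_r2=adj,
    )


def _split_indices(
    n: int, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    return perm[:n_train], perm[n_train:]


def mccv_adj_r2(
    features: pd.DataFrame | np.ndarray, response: np.ndarray, spec: ModelSpec
) -> np.ndarray:
    """Held-out adjusted R² across ``spec.n_splits`` random 80/20 splits."""
    X, _ = _as_matrix(features)
    y = np.asarray(response, dtype=float)
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=spec.n_splits)
    out = np.empty(spec.n_splits)
    p = X.shape[1]
    for i in range(spec.n_splits):
        tr, te = _split_indices(len(y), spec.train_fraction, rng)
        if len(te) < 10:
            raise ValueError("fewer than 10 test windows")
        m = _make_forest(spec, seeds[i]).fit(X[tr], y[tr])
        out[i] = adjusted_r2(y[te], m.predict(X[te]), p)
    return out


def mccv_compare(
    cancer_features: pd.DataFrame | np.ndarray,
    normal_features: pd.DataFrame | np.ndarray,
    shared_rt_features: pd.DataFrame | np.ndarray | None,
    response: np.ndarray,
    spec: ModelSpec,
) -> ComparisonResult:
    """Joint MCCV of the cancer-CA and normal-CA arms.

    Each split draws one random 80/20 window partition shared by both
    arms; each arm's forest uses its own CA profiles plus the shared RT
    profiles; Δadj.R² is evaluated on the identical test windows. The
    empirical p is the fraction of splits whose Δ lies strictly on the
    opposite side of zero from the median (Δ exactly 0 counts half);
    when no split crosses zero it is reported below 1/n_splits.
    """
    Xc, _ = _as_matrix(cancer_features)
    Xn, _ = _as_matrix(normal_features)
    if Xc.shape[1] == 0 or Xn.shape[1] == 0:
        raise ValueError("both arms need at least one feature")
    if shared_rt_features is not None:
        Xrt, _ = _as_matrix(shared_rt_features)
        Xc = np.hstack([Xc, Xrt])
        Xn = np.hstack([Xn, Xrt])
    y = np.asarray(response, dtype=float)
    if not (Xc.shape[0] == Xn.shape[0] == len(y)):
        raise ValueError("arms must share one window grid with the response")
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=spec.n_splits)
    r2c = np.empty(spec.n_splits)
    r2n = np.empty(spec.n_splits)
    for i in range(spec.n_splits):
        tr, te = _split_indices(len(y), spec.train_fraction, rng)
        if len(te) < 10:
            raise ValueError("fewer than 10 test windows")
        mc = _make_forest(spec, seeds[i]).fit(Xc[tr], y[tr])
        mn = _make_forest(spec, seeds[i]).fit(Xn[tr], y[tr])
        r2c[i] = adjusted_r2(y[te], mc.predict(Xc[te]), Xc.shape[1])
        r2n[i] = adjusted_r2(y[te], mn.predict(Xn[te]), Xn.shape[1])
    deltas = r2c - r2n
    med = float(np.median(deltas))
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    if med > 0:
        crossed = float(np.sum(deltas < 0) + 0.5 * np.sum(deltas == 0))
    elif med < 0:
        crossed = float(np.sum(deltas > 0) + 0.5 * np.sum(deltas == 0))
    else:  # degenerate: median exactly zero
        crossed = float(
            min(np.sum(deltas > 0), np.sum(deltas < 0)) + 0.5 * np.sum(deltas == 0)
        )
    p = max(crossed / spec.n_splits, 1.0 / spec.n_splits)
    return ComparisonResult(
        deltas=deltas,
        adj_r2_cancer=r2c,
        adj_r2_normal=r2n,
        median_delta=med,
        ci_low=float(lo),
        ci_high=float(hi),
        empirical_p=p,
        n_splits=spec.n_splits,
        n_crossed=crossed,
    )


def downsample_arms(
    cancer_ids: list[str],
    normal_ids: list[str],
    n_iter: int = 1000,
    seed: int = 0,
) -> list[tuple[list[str], list[str]]]:
    """Equalise arm sizes by subsampling the larger arm, ``n_iter`` times.

    Guards the paired comparison against the arm with more profiles
    winning by predictor count alone. Each iteration subsamples without
    replacement down to the smaller arm's size; the smaller arm is used
    whole.
    """
    if not cancer_ids or not normal_ids:
        raise ValueError("both arms need at least one profile")
    rng = np.random.default_rng(seed)
    m = min(len(cancer_ids), len(normal_ids))
    out = []
    for _ in range(n_iter):
        c = (
            list(cancer_ids)
            if len(cancer_ids) == m
            else sorted(rng.choice(cancer_ids, size=m, replace=False).tolist())
        )
        n = (
            list(normal_ids)
            if len(normal_ids) == m
            else sorted(rng.choice(normal_ids, size=m, replace=False).tolist())
        )
        out.append((c, n))
    return out
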