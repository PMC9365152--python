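"""Predictor importance: out-of-bag incMSE, permutation-refit null,
bootstrap confidence intervals, and SHAP interpretation.

incMSE is the percent increase in the forest's out-of-bag mean squared
error when one track's values are permuted — the classic
regression-forest importance measure. Raw incMSE has no calibrated null,
so significance comes from refitting the forest on randomly permuted
burden vectors: a track is called significant only when its observed
incMSE strictly exceeds every null value (empirical P below 1/n_perm;
P < 0.001 at the full 1000 permutations). Bootstrap resampling of
windows gives percentile confidence intervals for the observed incMSE.
SHAP attributions add the signed, per-window view: how much each track
pushed each window's predicted burden up or down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.utils import check_random_state

from .grid import TrackProfile
from .models import FitResult, ModelSpec, _as_matrix
from .treeshap import forest_shap_values

logger = logging.getLogger(__name__)


@dataclass
class ShapMatrix:
    """Per-window x per-track additive attributions.

    For every window, ``base_value + values[w].sum()`` equals the model
    prediction (local accuracy, exact up to float tolerance).
    """

    values: np.ndarray
    base_value: float
    track_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.track_ids)


def _oob_masks(model, n: int) -> list[np.ndarray]:
    """Out-of-bag sample mask per tree, reconstructed from each tree's
    bootstrap RNG (bootstrap draws n of n with replacement)."""
    masks = []
    for est in model.estimators_:
        rng = check_random_state(est.random_state)
        idx = rng.randint(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[idx] = False
        masks.append(mask)
    return masks


def inc_mse(
    fit: FitResult,
    features: pd.DataFrame | np.ndarray,
    response: np.ndarray,
    n_repeats: int = 3,
    seed: int = 0,
) -> pd.Series:
    """Percent increase in OOB MSE per track under value permutation.

    Per tree, each track's values are shuffled across that tree's OOB
    windows and the OOB error recomputed;
    ``incMSE = 100 * (MSE_perm - MSE_orig) / MSE_orig`` aggregated over
    trees and averaged over ``n_repeats`` permutation draws.
    """
    X, names = _as_matrix(features)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    masks = _oob_masks(fit.model, n)
    base_sse = 0.0
    base_n = 0
    for est, mask in zip(fit.model.estimators_, masks):
        pred = est.predict(X32[mask], check_input=False)
        base_sse += float(np.sum((y[mask] - pred) ** 2))
        base_n += int(mask.sum())
    mse_orig = base_sse / base_n
    out = np.zeros(p)
    for _ in range(n_repeats):
        sse = np.zeros(p)
        for est, mask in zip(fit.model.estimators_, masks):
            Xo = X32[mask]
            m = Xo.shape[0]
            # one stacked prediction call per tree: block j holds the
            # OOB rows with track j's values permuted
            stacked = np.tile(Xo, (p, 1))
            for j in range(p):
                stacked[j * m : (j + 1) * m, j] = rng.permutation(Xo[:, j])
            pred = est.predict(stacked, check_input=False).reshape(p, m)
            sse += np.sum((y[mask][None, :] - pred) ** 2, axis=1)
        out += 100.0 * (sse / base_n - mse_orig) / mse_orig
    return pd.Series(out / n_repeats, index=names, name="incMSE")


def permutation_null(
    features: pd.DataFrame | np.ndarray,
    response: np.ndarray,
    spec: ModelSpec,
    n_perm: int = 1000,
    n_repeats: int = 1,
) -> pd.DataFrame:
    """Permutation-refit null for incMSE significance.

    The burden vector is randomly reassigned across windows ``n_perm``
    times; a forest is refit to each permuted response and per-track
    null incMSE values recorded. A track is significant iff its observed
    incMSE strictly exceeds all null values; ties are non-significant.
    Returns a table (track_id, incMSE, empirical_p, significant).
    """
    from .models import fit_forest

    if n_perm < 20:
        logger.warning("n_perm=%d gives a very coarse null", n_perm)
    X, names = _as_matrix(features)
    y = np.asarray(response, dtype=float)
    rng = np.random.default_rng(spec.seed)
    obs_fit = fit_forest(X, y, spec)
    observed = inc_mse(obs_fit, X, y, n_repeats=n_repeats, seed=spec.seed).to_numpy()
    null = np.empty((n_perm, X.shape[1]))
    for b in range(n_perm):
        yp = rng.permutation(y)
        sub = ModelSpec(
            n_trees=spec.n_trees,
            mtry_fraction=spec.mtry_fraction,
            seed=int(rng.integers(0, 2**31 - 1)),
            train_fraction=spec.train_fraction,
            n_splits=spec.n_splits,
            min_node_size=spec.min_node_size,
        )
        f = fit_forest(X, yp, sub)
        null[b] = inc_mse(f, X, yp, n_repeats=n_repeats, seed=sub.seed).to_numpy()
    p = (null >= observed[None, :]).mean(axis=0)
    significant = observed > null.max(axis=0)
    return pd.DataFrame(
        {
            "track_id": names,
            "incMSE": observed,
            "empirical_p": p,
            "significant": significant,
            "null_max": null.max(axis=0),
        }
    )


def bootstrap_importance(
    features: pd.DataFrame | np.ndarray,
    response: np.ndarray,
    spec: ModelSpec,
    n_boot: int = 1000,
    n_repeats: int = 1,
) -> pd.DataFrame:
    """Percentile CIs for incMSE by resampling windows with replacement.

    Each iteration refits the forest on a bootstrap resample of windows
    and measures permutation importance on the windows left out of the
    resample. Evaluating on the resample itself would let trees match
    duplicated windows exactly (the same window lands both in-bag and
    out-of-bag), which inflates the apparent importance even of pure
    noise tracks; the out-of-resample windows are leakage-free.
    """
    from dataclasses import replace as dc_replace

    from sklearn.inspection import permutation_importance

    from .models import fit_forest

    X, names = _as_matrix(features)
    y = np.asarray(response, dtype=float)
    rng = np.random.default_rng(spec.seed)
    vals = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, len(y), len(y))
        out = np.setdiff1d(np.arange(len(y)), idx)
        sub = dc_replace(spec, seed=int(rng.integers(0, 2**31 - 1)))
        f = fit_forest(X[idx], y[idx], sub)
        if len(out) < 10:  # pathological resample; fall back to OOB incMSE
            vals[b] = inc_mse(f, X[idx], y[idx], n_repeats=n_repeats, seed=sub.seed).to_numpy()
            continue
        mse_orig = float(np.mean((y[out] - f.model.predict(X[out])) ** 2))
        pi = permutation_importance(
            f.model,
            X[out],
            y[out],
            scoring="neg_mean_squared_error",
            n_repeats=n_repeats,
            random_state=sub.seed % (2**32),
            n_jobs=1,
        )
        vals[b] = 100.0 * pi.importances_mean / mse_orig
    lo, hi = np.percentile(vals, [2.5, 97.5], axis=0)
    out = pd.DataFrame(
        {
            "track_id": names,
            "ci_low": lo,
            "ci_high": hi,
            "sd": vals.std(axis=0, ddof=1) if n_boot > 1 else np.nan,
        }
    )
    if n_boot == 1:
        logger.warning("n_boot=1: degenerate CI")
        out["degenerate"] = True
    return out


def shap_attributions(
    fit: FitResult,
    features: pd.DataFrame | np.ndarray,
    significant_only: bool = False,
    significant_tracks: list[str] | None = None,
) -> ShapMatrix:
    """Exact path-dependent SHAP values for the full-data forest.

    ``significant_only`` restricts the returned columns (attributions
    are still computed on the full model so local accuracy holds on the
    full set before selection).
    """
    X, names = _as_matrix(features)
    if names != fit.feature_names:
        raise ValueError("feature matrix misaligned with fitted model")
    values, base = forest_shap_values(fit.model, X)
    mat = ShapMatrix(values=values, base_value=float(base), track_ids=list(names))
    if significant_only:
        if significant_tracks is None:
            raise ValueError("significant_only requires significant_tracks")
        cols = [i for i, t in enumerate(names) if t in set(significant_tracks)]
        mat = ShapMatrix(
            values=values[:, cols],
            base_value=float(base),
            track_ids=[names[i] for i in cols],
        )
    return mat


def shap_track_correlation(
    shap: ShapMatrix, track: TrackProfile | np.ndarray, track_id: str | None = None
) -> tuple[float, float]:
    """Spearman correlation between a track's values and its own SHAP
    attribution column; (nan, nan) when either side is constant."""
    if isinstance(track, TrackProfile):
        values = track.values
        track_id = track_id or track.track_id
    else:
        values = np.asarray(track, dtype=float)
    if track_id not in shap.track_ids:
        raise ValueError(f"track {track_id!r} absent from attribution matrix")
    col = shap.values[:, shap.track_ids.index(track_id)]
    if np.ptp(values) == 0 or np.ptp(col) == 0:
        logger.warning("constant input: Spearman undefined for %s", track_id)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(values, col)
    return float(rho), float(p)


def rank_significant(importance: pd.DataFrame) -> pd.DataFrame:
    """Significant tracks ordered by observed incMSE (top-predictor report)."""
    sig = importance[importance["significant"]]
    return sig.sort_values("incMSE", ascending=False).reset_index(drop=True)
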