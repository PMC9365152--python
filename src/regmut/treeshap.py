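"""Exact path-dependent SHAP attributions for sklearn tree ensembles.

Computes per-window, per-feature Shapley values for a fitted
``RandomForestRegressor`` using the polynomial-time tree algorithm with
path-dependent feature perturbation: the conditional expectation for a
feature subset follows the tree, weighting unsplit branches by their
training-sample cover. Attributions satisfy local accuracy exactly —
``base_value + sum of attributions == model prediction`` for every
window — and are deterministic.

The recursion maintains the set of unique features on the current path
with, per feature, the fraction of "zero" (feature unknown) and "one"
(feature known) paths that flow through, and per subset size the
permutation weight; extending and unwinding that path gives all Shapley
terms in O(leaves x depth^2) per sample per tree.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from sklearn.ensemble import RandomForestRegressor


@njit(cache=True)
def _extend(fi, zf, of, pw, base, udepth, pzf, pof, pfi):
    fi[base + udepth] = pfi
    zf[base + udepth] = pzf
    of[base + udepth] = pof
    pw[base + udepth] = 1.0 if udepth == 0 else 0.0
    for i in range(udepth - 1, -1, -1):
        pw[base + i + 1] += pof * pw[base + i] * (i + 1.0) / (udepth + 1.0)
        pw[base + i] = pzf * pw[base + i] * (udepth - i) / (udepth + 1.0)


@njit(cache=True)
def _unwind(fi, zf, of, pw, base, udepth, path_index):
    one = of[base + path_index]
    zero = zf[base + path_index]
    nxt = pw[base + udepth]
    for i in range(udepth - 1, -1, -1):
        if one != 0.0:
            tmp = pw[base + i]
            pw[base + i] = nxt * (udepth + 1.0) / ((i + 1.0) * one)
            nxt = tmp - pw[base + i] * zero * (udepth - i) / (udepth + 1.0)
        else:
            pw[base + i] = pw[base + i] * (udepth + 1.0) / (zero * (udepth - i))
    for i in range(path_index, udepth):
        fi[base + i] = fi[base + i + 1]
        zf[base + i] = zf[base + i + 1]
        of[base + i] = of[base + i + 1]


@njit(cache=True)
def _unwound_sum(fi, zf, of, pw, base, udepth, path_index):
    one = of[base + path_index]
    zero = zf[base + path_index]
    nxt = pw[base + udepth]
    total = 0.0
    for i in range(udepth - 1, -1, -1):
        if one != 0.0:
            tmp = nxt * (udepth + 1.0) / ((i + 1.0) * one)
            total += tmp
            nxt = pw[base + i] - tmp * zero * (udepth - i) / (udepth + 1.0)
        else:
            total += pw[base + i] / zero * (udepth + 1.0) / (udepth - i)
    return total


@njit(cache=True)
def _tree_shap_sample(
    left, right, feature, threshold, value, cover,
    x, phi,
    fi, zf, of, pw,
    st_node, st_udepth, st_base, st_zf, st_of, st_fi,
):
    # explicit-stack pre-order traversal; the path buffers are laid out
    # per level so a node's region never clobbers its ancestors', and a
    # subtree is fully processed before its sibling starts (LIFO order).
    top = 0
    st_node[0] = 0
    st_udepth[0] = 0
    st_base[0] = -1
    st_zf[0] = 1.0
    st_of[0] = 1.0
    st_fi[0] = -1
    while top >= 0:
        node = st_node[top]
        udepth = st_udepth[top]
        parent_base = st_base[top]
        pzf = st_zf[top]
        pof = st_of[top]
        pfi = st_fi[top]
        top -= 1
        base = parent_base + udepth + 1
        for i in range(udepth + 1):
            fi[base + i] = fi[parent_base + i]
            zf[base + i] = zf[parent_base + i]
            of[base + i] = of[parent_base + i]
            pw[base + i] = pw[parent_base + i]
        _extend(fi, zf, of, pw, base, udepth, pzf, pof, pfi)
        if left[node] < 0:  # leaf
            for i in range(1, udepth + 1):
                w = _unwound_sum(fi, zf, of, pw, base, udepth, i)
                phi[fi[base + i]] += w * (of[base + i] - zf[base + i]) * value[node]
            continue
        f = feature[node]
        if x[f] <= threshold[node]:
            hot, cold = left[node], right[node]
        else:
            hot, cold = right[node], left[node]
        izf = 1.0
        iof = 1.0
        path_index = 0
        for i in range(1, udepth + 1):
            if fi[base + i] == f:
                path_index = i
                break
        if path_index > 0:
            izf = zf[base + path_index]
            iof = of[base + path_index]
            _unwind(fi, zf, of, pw, base, udepth, path_index)
            udepth -= 1
        # push cold first so the hot subtree (and its buffer region,
        # which cold will reuse) completes before cold is expanded
        top += 1
        st_node[top] = cold
        st_udepth[top] = udepth + 1
        st_base[top] = base
        st_zf[top] = cover[cold] / cover[node] * izf
        st_of[top] = 0.0
        st_fi[top] = f
        top += 1
        st_node[top] = hot
        st_udepth[top] = udepth + 1
        st_base[top] = base
        st_zf[top] = cover[hot] / cover[node] * izf
        st_of[top] = iof
        st_fi[top] = f


@njit(cache=True)
def _tree_shap_all(left, right, feature, threshold, value, cover, X, phis, maxdepth):
    size = (maxdepth + 2) * (maxdepth + 3) // 2
    fi = np.empty(size, dtype=np.int64)
    zf = np.empty(size, dtype=np.float64)
    of = np.empty(size, dtype=np.float64)
    pw = np.empty(size, dtype=np.float64)
    cap = 2 * (maxdepth + 2)
    st_node = np.empty(cap, dtype=np.int64)
    st_udepth = np.empty(cap, dtype=np.int64)
    st_base = np.empty(cap, dtype=np.int64)
    st_zf = np.empty(cap, dtype=np.float64)
    st_of = np.empty(cap, dtype=np.float64)
    st_fi = np.empty(cap, dtype=np.int64)
    for s in range(X.shape[0]):
        _tree_shap_sample(
            left, right, feature, threshold, value, cover,
            X[s], phis[s],
            fi, zf, of, pw,
            st_node, st_udepth, st_base, st_zf, st_of, st_fi,
        )


def _tree_arrays(tree):
    t = tree.tree_
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        t.value.reshape(-1).astype(np.float64),
        t.weighted_n_node_samples.astype(np.float64),
        int(t.max_depth),
    )


def forest_shap_values(
    model: RandomForestRegressor, X: np.ndarray
) -> tuple[np.ndarray, float]:
    """SHAP values (n_samples x n_features) and base value for a forest.

    The forest attribution is the mean of per-tree attributions; the
    base value is the mean of the trees' root means (the expected
    prediction over each tree's bootstrap sample).
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    phis = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    base = 0.0
    for est in model.estimators_:
        left, right, feat, thr, val, cover, maxd = _tree_arrays(est)
        tree_phi = np.zeros_like(phis)
        _tree_shap_all(left, right, feat, thr, val, cover, X, tree_phi, maxd)
        phis += tree_phi
        base += val[0]
    n = len(model.estimators_)
    return phis / n, base / n


def tree_conditional_expectation(tree, x: np.ndarray, subset: frozenset) -> float:
    """Path-dependent E[f(x_S)] for one tree: follow x on features in
    ``subset``, average children by training cover elsewhere.

    Exponential-cost reference used to validate the fast algorithm.
    """
    t = tree.tree_

    def rec(node: int) -> float:
        if t.children_left[node] < 0:
            return float(t.value.reshape(-1)[node])
        f = int(t.feature[node])
        if f in subset:
            nxt = (
                t.children_left[node]
                if x[f] <= t.threshold[node]
                else t.children_right[node]
            )
            return rec(int(nxt))
        wl = t.weighted_n_node_samples[t.children_left[node]]
        wr = t.weighted_n_node_samples[t.children_right[node]]
        return (wl * rec(int(t.children_left[node])) + wr * rec(int(t.children_right[node]))) / (
            wl + wr
        )

    return rec(0)


def brute_force_shap(model: RandomForestRegressor, x: np.ndarray) -> np.ndarray:
    """Exact Shapley values by subset enumeration (small p only)."""
    from itertools import combinations
    from math import factorial

    p = len(x)
    phi = np.zeros(p)
    feats = list(range(p))
    for est in model.estimators_:
        for j in feats:
            others = [f for f in feats if f != j]
            for k in range(p):
                for S in combinations(others, k):
                    w = factorial(k) * factorial(p - k - 1) / factorial(p)
                    gain = tree_conditional_expectation(
                        est, x, frozenset(S) | {j}
                    ) - tree_conditional_expectation(est, x, frozenset(S))
                    phi[j] += w * gain
    return phi / len(model.estimators_)
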