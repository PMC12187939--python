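"""Exact SHAP values for sklearn regression trees and forests.

Computes path-dependent tree SHAP: the value function is the tree's
conditional expectation E[f(x) | x_S], where splits on features outside the
coalition S are averaged over the tree's training cover (weighted node sample
counts), and splits on features inside S follow x. Shapley values of this
game are computed exactly, per leaf, by dynamic programming over the leaf's
unique path features. For a leaf whose path constrains features
U = {1..P} the contribution to feature i is

    v_L · (o_i − z_i) · Σ_k  k!(P−1−k)!/P! · e_k,

where o_j ∈ {0,1} records whether x satisfies every split on feature j along
the path, z_j is the product of cover fractions of those splits, and e_k is
the elementary sum over size-k subsets W of U\\{i} of Π_{j∈W} o_j ·
Π_{j∉W} z_j. With tree depth ≤ D this is O(leaves · D³) per sample.

The numba kernel carries the per-sample work; a pure-Python brute-force
Shapley enumeration (`shap_values_bruteforce`) serves as an independent
oracle for small trees in the test suite.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial
from typing import List, Sequence

import numpy as np
from numba import njit

__all__ = ["tree_shap_values", "forest_shap_values", "shap_values_bruteforce"]


def _leaf_structures(tree):
    """Flatten a fitted sklearn tree into per-leaf CSR path structures."""
    t = tree.tree_
    left, right = t.children_left, t.children_right
    feature, threshold = t.feature, t.threshold
    value = t.value[:, 0, 0]
    cover = t.weighted_n_node_samples

    leaf_value: List[float] = []
    uf_feat: List[int] = []
    uf_z: List[float] = []
    uf_start = [0]
    sp_thr: List[float] = []
    sp_left: List[bool] = []
    sp_start = [0]

    # path: list of (feature, threshold, went_left, cover_fraction)
    def walk(node, path):
        if left[node] == -1:  # leaf
            leaf_value.append(value[node])
            feats = {}
            for f, thr, wl, frac in path:
                feats.setdefault(f, []).append((thr, wl, frac))
            for f in sorted(feats):
                uf_feat.append(f)
                z = 1.0
                for thr, wl, frac in feats[f]:
                    z *= frac
                    sp_thr.append(thr)
                    sp_left.append(wl)
                uf_z.append(z)
                sp_start.append(len(sp_thr))
            uf_start.append(len(uf_feat))
            return
        f, thr = feature[node], threshold[node]
        for child, wl in ((left[node], True), (right[node], False)):
            frac = cover[child] / cover[node]
            path.append((f, thr, wl, frac))
            walk(child, path)
            path.pop()

    walk(0, [])
    return (
        np.asarray(leaf_value, dtype=np.float64),
        np.asarray(uf_start, dtype=np.int64),
        np.asarray(uf_feat, dtype=np.int64),
        np.asarray(uf_z, dtype=np.float64),
        np.asarray(sp_start, dtype=np.int64),
        np.asarray(sp_thr, dtype=np.float64),
        np.asarray(sp_left, dtype=np.bool_),
    )


@njit(cache=True)
def _shap_kernel(X, leaf_value, uf_start, uf_feat, uf_z,
                 sp_start, sp_thr, sp_left, fact, phi, weight):
    n_samples = X.shape[0]
    n_leaves = leaf_value.shape[0]
    max_p = 0
    for L in range(n_leaves):
        p = uf_start[L + 1] - uf_start[L]
        if p > max_p:
            max_p = p
    o = np.empty(max_p)
    z = np.empty(max_p)
    c = np.empty(max_p)
    for s in range(n_samples):
        for L in range(n_leaves):
            a = uf_start[L]
            P = uf_start[L + 1] - a
            if P == 0:
                continue
            for u in range(P):
                g = a + u
                z[u] = uf_z[g]
                f = uf_feat[g]
                ok = 1.0
                for t in range(sp_start[g], sp_start[g + 1]):
                    goes_left = X[s, f] <= sp_thr[t]
                    if goes_left != sp_left[t]:
                        ok = 0.0
                        break
                o[u] = ok
            v = leaf_value[L] * weight
            for i in range(P):
                if o[i] == z[i]:
                    continue
                c[0] = 1.0
                cnt = 0
                for j in range(P):
                    if j == i:
                        continue
                    cnt += 1
                    c[cnt] = 0.0
                    for k in range(cnt, 0, -1):
                        c[k] = c[k] * z[j] + c[k - 1] * o[j]
                    c[0] = c[0] * z[j]
                acc = 0.0
                for k in range(P):
                    acc += fact[k] * fact[P - 1 - k] / fact[P] * c[k]
                phi[s, uf_feat[a + i]] += v * (o[i] - z[i]) * acc


_FACT = np.array([float(factorial(k)) for k in range(64)])


def tree_shap_values(tree, X: np.ndarray, weight: float = 1.0) -> np.ndarray:
    """SHAP matrix (samples × features) for one fitted regression tree."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    structures = _leaf_structures(tree)
    phi = np.zeros_like(X)
    _shap_kernel(X, *structures, _FACT, phi, float(weight))
    return phi


def forest_shap_values(
    trees: Sequence, X: np.ndarray, tree_weights: Sequence[float]
) -> np.ndarray:
    """SHAP matrix of a weighted tree ensemble f(x) = Σ_t w_t·tree_t(x).

    SHAP values are additive across the ensemble, so the result is the
    weight-scaled sum of per-tree values.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros_like(X)
    for tree, w in zip(trees, tree_weights):
        if w == 0.0:
            continue
        _shap_kernel(X, *_leaf_structures(tree), _FACT, phi, float(w))
    return phi


def _conditional_expectation(tree, x: np.ndarray, coalition: frozenset) -> float:
    """E[f | x_S] walked recursively: follow x inside S, average outside."""
    t = tree.tree_
    cover = t.weighted_n_node_samples

    def rec(node):
        if t.children_left[node] == -1:
            return t.value[node, 0, 0]
        f = t.feature[node]
        lo, hi = t.children_left[node], t.children_right[node]
        if f in coalition:
            return rec(lo if x[f] <= t.threshold[node] else hi)
        return (cover[lo] * rec(lo) + cover[hi] * rec(hi)) / cover[node]

    return rec(0)


def shap_values_bruteforce(tree, X: np.ndarray) -> np.ndarray:
    """Exact Shapley values by full subset enumeration (oracle, small trees).

    Features never used by the tree are dummy players with value 0 and do
    not affect the others, so enumeration runs over the tree's feature set.
    """
    t = tree.tree_
    used = sorted(set(int(f) for f in t.feature if f >= 0))
    M = len(used)
    phi = np.zeros_like(np.asarray(X, dtype=np.float64))
    for s, x in enumerate(np.asarray(X, dtype=np.float64)):
        for i in used:
            others = [f for f in used if f != i]
            total = 0.0
            for k in range(M):
                w = factorial(k) * factorial(M - 1 - k) / factorial(M)
                for combo in combinations(others, k):
                    with_i = _conditional_expectation(
                        tree, x, frozenset(combo) | {i})
                    without = _conditional_expectation(tree, x, frozenset(combo))
                    total += w * (with_i - without)
            phi[s, i] = total
    return phi
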