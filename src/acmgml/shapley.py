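"""Shapley-value feature attributions for binary-feature classifiers.

Attribution of feature i for an input row x is the Shapley value of i in
the coalitional game v(S) = E_b[f(x_S, b_{~S})], the expected model output
when features in S take x's values and the rest are drawn from a background
sample.  For the 17-bit evidence vectors used here, features take only two
values, so for up to ``exact_limit`` non-constant features the game can be
solved exactly: the model is evaluated once on every attainable mixed
pattern and the coalition sum is pure arithmetic over cached predictions.
Above the limit a seeded permutation-sampling estimator is used.

Constant features (identical in the evaluation rows and the background)
carry exactly zero attribution by the null-player axiom and are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Callable, Sequence

import numpy as np


@dataclass
class ShapleyResult:
    feature_names: list[str]
    #: (n_rows, n_features) signed attributions
    values: np.ndarray
    method: str

    def mean_abs(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)


def _pack_bits(rows: np.ndarray) -> np.ndarray:
    weights = (1 << np.arange(rows.shape[1], dtype=np.int64))
    return rows.astype(np.int64) @ weights


def _exact_binary(predict: Callable[[np.ndarray], np.ndarray],
                  X_eval: np.ndarray, X_bg: np.ndarray,
                  nc: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Exact Shapley values over the non-constant columns ``nc``.

    Predictions for all 2^p attainable patterns are cached once; coalition
    sums are then integer-bitmask arithmetic over (eval, background) pairs.
    """
    p = len(nc)
    # cache model output for every pattern of the non-constant block
    patterns = ((np.arange(1 << p)[:, None] >> np.arange(p)) & 1).astype(int)
    full = np.tile(template, (1 << p, 1))
    full[:, nc] = patterns
    cache = np.asarray(predict(full), dtype=float)

    x_codes = _pack_bits(X_eval[:, nc])            # (n_eval,)
    b_codes = _pack_bits(X_bg[:, nc])              # (n_bg,)
    xg = x_codes[:, None]                          # broadcast over pairs
    bg = b_codes[None, :]

    n_eval = X_eval.shape[0]
    phi = np.zeros((n_eval, X_eval.shape[1]))
    # Shapley kernel weights w(s) = s!(p-s-1)!/p!
    w = np.array([1.0 / (p * comb(p - 1, s)) for s in range(p)])
    others = np.arange(p)
    for j_local, j in enumerate(nc):
        rest = others[others != j_local]
        bit_j = 1 << int(j_local)
        for sub in range(1 << (p - 1)):
            mask = 0
            s = 0
            for k_idx, k in enumerate(rest):
                if sub >> k_idx & 1:
                    mask |= 1 << int(k)
                    s += 1
            keep = mask
            mixed_without = (xg & keep) | (bg & ~keep)
            mixed_with = (mixed_without & ~bit_j) | (xg & bit_j)
            delta = cache[mixed_with] - cache[mixed_without]   # (n_eval, n_bg)
            phi[:, j] += w[s] * delta.mean(axis=1)
    return phi


def _sampled(predict: Callable[[np.ndarray], np.ndarray],
             X_eval: np.ndarray, X_bg: np.ndarray, nc: np.ndarray,
             n_permutations: int, rng: np.random.Generator) -> np.ndarray:
    """Permutation-sampling Shapley estimator (antithetic over order)."""
    n_eval, p_all = X_eval.shape
    n_bg = X_bg.shape[0]
    phi = np.zeros((n_eval, p_all))
    for _ in range(n_permutations):
        perm = rng.permutation(nc)
        bg_idx = rng.integers(0, n_bg, size=n_eval)
        current = X_bg[bg_idx].copy()
        prev = np.asarray(predict(current), dtype=float)
        for j in perm:
            current[:, j] = X_eval[:, j]
            cur = np.asarray(predict(current), dtype=float)
            phi[:, j] += cur - prev
            prev = cur
    return phi / n_permutations


def shapley_values(predict: Callable[[np.ndarray], np.ndarray],
                   X_eval: np.ndarray,
                   X_background: np.ndarray,
                   feature_names: Sequence[str] | None = None,
                   exact_limit: int = 12,
                   n_permutations: int = 100,
                   seed: int = 0) -> ShapleyResult:
    """Per-row Shapley attributions of ``predict`` over the evaluation rows.

    ``predict`` maps an (n, p) feature matrix to a scalar per row (for a
    classifier, the positive-class score).  Exact coalition enumeration is
    used when at most ``exact_limit`` features are non-constant, otherwise
    seeded permutation sampling with ``n_permutations`` draws.
    """
    X_eval = np.asarray(X_eval)
    X_bg = np.asarray(X_background)
    if X_eval.ndim != 2 or X_bg.ndim != 2 or X_eval.shape[1] != X_bg.shape[1]:
        raise ValueError("evaluation and background matrices must share width")
    p_all = X_eval.shape[1]
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(p_all)]
    if len(names) != p_all:
        raise ValueError("feature_names length mismatch")

    stacked = np.vstack([X_eval, X_bg])
    nonconstant = np.where(stacked.min(axis=0) != stacked.max(axis=0))[0]
    template = X_bg[0].copy()

    if len(nonconstant) == 0:
        values = np.zeros((X_eval.shape[0], p_all))
        method = "exact"
    elif len(nonconstant) <= exact_limit and np.isin(stacked, (0, 1)).all():
        values = _exact_binary(predict, X_eval, X_bg, nonconstant, template)
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        values = _sampled(predict, X_eval, X_bg, nonconstant,
                          n_permutations, rng)
        method = "sampled"
    return ShapleyResult(feature_names=names, values=values, method=method)
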