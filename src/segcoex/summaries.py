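"""Dissimilarity, set-intersection, enrichment and correlation statistics.

Utilities used to summarize an expression study: the Morisita-Horn
dissimilarity between sample profiles (the input to ordination methods
such as NMDS, which themselves are out of scope here), exclusive
intersection counts over named gene sets (the numbers behind an UpSet
plot), a one-sample chi-squared enrichment test against a platform-wide
proportion, and the t statistic associated with a Pearson correlation.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix
from .errors import DataError


def morisita_horn(x, y) -> float:
    """Morisita-Horn dissimilarity between two nonnegative profiles.

        1 - 2 * sum(x_i * y_i) / ((sum(x_i^2)/X^2 + sum(y_i^2)/Y^2) * X * Y)

    with X = sum(x), Y = sum(y). Symmetric, in [0, 1], and scale-invariant
    (x and c*x are equivalent). Not a metric: the triangle inequality can
    fail.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("morisita_horn expects two equal-length 1-D profiles")
    if (x < 0).any() or (y < 0).any():
        raise DataError("profiles must be nonnegative")
    X, Y = x.sum(), y.sum()
    if X <= 0 or Y <= 0:
        raise DataError("profiles must have positive totals")
    # normalize first (exact by scale invariance; avoids over/underflow)
    p, q = x / X, y / Y
    sim = 2.0 * float(p @ q) / (float(p @ p) + float(q @ q))
    return float(min(max(1.0 - sim, 0.0), 1.0))


def dissimilarity_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Symmetric sample x sample Morisita-Horn dissimilarity matrix."""
    values = matrix.data.to_numpy(dtype=float)
    samples = matrix.sample_ids
    k = len(samples)
    out = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        d = morisita_horn(values[:, i], values[:, j])
        out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=samples, columns=samples)


def exclusive_intersections(sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive intersection sizes over named sets (UpSet-style counts).

    For every non-empty combination of set names, counts the elements
    belonging to exactly those sets and no others; rows with zero count
    are omitted. Counts over all patterns sum to the size of the union.
    """
    if not sets:
        raise DataError("at least one named set is required")
    names = list(sets)
    membership: Counter[tuple[str, ...]] = Counter()
    for element in set().union(*sets.values()):
        pattern = tuple(n for n in names if element in sets[n])
        membership[pattern] += 1
    rows = [
        {"sets": pattern, "degree": len(pattern), "count": count}
        for pattern, count in membership.items()
    ]
    df = pd.DataFrame(rows, columns=["sets", "degree", "count"])
    return df.sort_values(["count", "degree"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)


def enrichment_chisq(
    k_obs: int, n_subset: int, K_total: int, N_total: int
) -> tuple[float, float, bool]:
    """One-sample goodness-of-fit chi-squared against a platform proportion.

    Tests whether ``k_obs`` of ``n_subset`` elements falling in a category
    is compatible with the platform-wide proportion ``K_total / N_total``:
    a two-cell (in-category / not) goodness-of-fit statistic on 1 df.

    Returns (chi2, p, low_expected_flag) where the flag marks an expected
    cell below 1.
    """
    if not (0 <= k_obs <= n_subset):
        raise DataError("need 0 <= k_obs <= n_subset")
    if not (0 < K_total < N_total):
        raise DataError("need 0 < K_total < N_total")
    p_cat = K_total / N_total
    expected = np.array([n_subset * p_cat, n_subset * (1.0 - p_cat)])
    observed = np.array([k_obs, n_subset - k_obs], dtype=float)
    low_expected = bool((expected < 1.0).any())
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p, low_expected


def t_from_r(r: float, df: int) -> tuple[float, float]:
    """t statistic and two-sided p for a Pearson correlation on ``df`` df.

        t = r * sqrt(df) / sqrt(1 - r^2)
    """
    if not -1.0 < r < 1.0:
        raise DataError("|r| must be < 1")
    if df < 1:
        raise DataError("df must be >= 1")
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return float(t), p
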