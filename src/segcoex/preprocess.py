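"""Normalization and expression-detection calls.

Raw intensities from the different samples are made comparable by quantile
normalization; elements are then called *expressed* when they exceed the
empirical distribution of the background/random probes carried on the
platform. Downstream correlation and differential testing run on log2
values.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import rankdata

from .datatypes import ExpressionMatrix, SampleDesign
from .errors import DataError

logger = logging.getLogger(__name__)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples so each shares the same value distribution.

    Every sample's sorted value vector is replaced by the across-sample
    mean of sorted vectors; within-sample ranks are preserved, and tied
    values receive the mean of the normalized values at their tied ranks.
    The operation is idempotent.
    """
    if matrix.n_samples < 2:
        raise DataError("quantile normalization requires at least 2 samples")
    values = matrix.data.to_numpy(dtype=float)
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = mean_sorted
        # average assigned values over ties within the sample
        ranks_min = rankdata(col, method="min").astype(int)
        ranks_max = rankdata(col, method="max").astype(int)
        tied = ranks_min != ranks_max
        if tied.any():
            sorted_cumsum = np.concatenate([[0.0], np.cumsum(mean_sorted)])
            lo, hi = ranks_min[tied] - 1, ranks_max[tied]
            assigned[tied] = (sorted_cumsum[hi] - sorted_cumsum[lo]) / (hi - lo)
        out[:, j] = assigned
    return matrix.with_values(out)


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(value + offset) on a linear-scale matrix; sets scale to log2."""
    if matrix.scale != "linear":
        raise DataError("log2_transform expects a linear-scale matrix")
    values = matrix.data.to_numpy(dtype=float)
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise DataError(
            f"negative value at element {matrix.element_ids[r]!r}, "
            f"sample {matrix.sample_ids[c]!r}; cannot log-transform"
        )
    if (values + offset <= 0).any():
        raise DataError("values + offset must be strictly positive")
    return matrix.with_values(np.log2(values + offset), scale="log2")


def detect_expressed(
    matrix: ExpressionMatrix,
    design: SampleDesign | None = None,
    alpha: float = 0.01,
    mode: str = "all_replicates",
) -> set[str]:
    """Call elements expressed above the background probe distribution.

    Per sample, the detection threshold is the empirical (1 - alpha)
    quantile (linear interpolation) of the background probe values in that
    sample; an element is expressed in a sample when its value strictly
    exceeds the threshold.

    mode
        ``"all_replicates"`` (default): an element is returned when it is
        expressed in *all* replicate samples of at least one condition
        (requires ``design``). ``"any_sample"``: expressed in at least one
        sample, no design needed.

    Background elements are never returned.
    """
    if not matrix.background_ids:
        raise DataError(
            "matrix has no background probe ids; skip detection or provide them"
        )
    if mode not in ("all_replicates", "any_sample"):
        raise DataError(f"unknown detection mode {mode!r}")
    if mode == "all_replicates" and design is None:
        raise DataError("mode='all_replicates' requires a sample design")

    bg_rows = matrix.data.loc[sorted(matrix.background_ids)].to_numpy(dtype=float)
    if alpha >= 1.0:
        thresholds = np.full(matrix.n_samples, -np.inf)
    else:
        thresholds = np.quantile(bg_rows, 1.0 - alpha, axis=0, method="linear")
    values = matrix.data.to_numpy(dtype=float)
    above = values > thresholds[np.newaxis, :]

    elem_ids = matrix.element_ids
    candidates = [i for i, e in enumerate(elem_ids) if e not in matrix.background_ids]
    sample_pos = {s: j for j, s in enumerate(matrix.sample_ids)}

    detected: set[str] = set()
    if mode == "any_sample":
        for i in candidates:
            if above[i].any():
                detected.add(elem_ids[i])
        return detected

    cond_cols = {
        c: [sample_pos[s] for s in design.samples_of(c) if s in sample_pos]
        for c in design.conditions
    }
    cond_cols = {c: cols for c, cols in cond_cols.items() if cols}
    for i in candidates:
        for cols in cond_cols.values():
            if above[i, cols].all():
                detected.add(elem_ids[i])
                break
    return detected
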