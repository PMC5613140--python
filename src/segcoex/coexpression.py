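"""Thresholded co-expression network construction.

For every pair of elements the Spearman rank correlation rho and its
two-sided p-value (t approximation) are computed; p-values are Bonferroni
adjusted over the number of tested pairs. An edge is retained when

    rho >= rho_min   AND   p_adj <= p_max   AND   MIC >= mic_min

where the MIC (maximal information coefficient) confirmation step can be
disabled. The correlation rule is signed: strong negative correlations do
not form edges. Because both rho and the MIC grid search depend only on
ranks, the network is invariant under strictly monotone per-element
transformations of the data.

The MIC here is computed by exhaustive search over axis-aligned grids with
cell-count product bounded by B = max(n^b_exponent, 4), which is exact and
deterministic for the small sample counts (n of a few dozen) this design
targets.
"""

from __future__ import annotations

import itertools
import logging
import math

import networkx as nx
import numpy as np
from scipy import stats

from .datatypes import ExpressionMatrix
from .errors import DataError

logger = logging.getLogger(__name__)

_TINY_P = float(np.nextafter(0, 1))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Returns NaN (with a logged notice) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("spearman_rho expects two equal-length 1-D vectors")
    if len(x) < 3:
        raise DataError("spearman_rho requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("spearman_rho: constant vector; correlation undefined")
        return float("nan")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def rho_pvalue(rho: float, n: int) -> float:
    """Two-sided p-value for a Spearman rho via the t approximation.

    t = rho * sqrt((n - 2) / (1 - rho^2)) with n - 2 degrees of freedom.
    |rho| = 1 returns the smallest representable positive p.
    """
    if n < 4:
        raise DataError("rho_pvalue requires n >= 4")
    if not -1.0 <= rho <= 1.0:
        raise DataError(f"invalid correlation {rho}")
    if abs(rho) >= 1.0:
        logger.info("rho_pvalue: |rho| = 1; returning smallest positive p")
        return _TINY_P
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(min(max(p, _TINY_P), 1.0))


# --------------------------------------------------------------------- MIC

def _cut_positions(sorted_vals: np.ndarray) -> np.ndarray:
    """Admissible split points: between consecutive distinct values."""
    return np.nonzero(np.diff(sorted_vals) != 0)[0] + 1


def _max_mi_for_grid(cum: np.ndarray, xcuts: np.ndarray, ycuts: np.ndarray,
                     n_xbins: int, n_ybins: int, n: int) -> float:
    """Maximum mutual information (bits) over all placements of the grid.

    ``cum[i, j]`` counts points among the first ``i`` in x-order whose
    y-order position is <= ``j``.
    """
    if len(xcuts) < n_xbins - 1 or len(ycuts) < n_ybins - 1:
        return 0.0
    xcombos = np.array(list(itertools.combinations(xcuts.tolist(), n_xbins - 1)), dtype=int)
    ycombos = np.array(list(itertools.combinations(ycuts.tolist(), n_ybins - 1)), dtype=int)
    # boundaries including 0 and n: shape (A, n_xbins + 1), (B, n_ybins + 1)
    A, Bc = len(xcombos), len(ycombos)
    xb = np.concatenate([np.zeros((A, 1), int), xcombos, np.full((A, 1), n)], axis=1)
    yb = np.concatenate([np.zeros((Bc, 1), int), ycombos, np.full((Bc, 1), n)], axis=1)
    # cell counts: shape (A, B, n_xbins, n_ybins)
    M = cum[xb[:, None, :, None], yb[None, :, None, :]]  # (A, B, nx+1, ny+1)
    counts = (M[:, :, 1:, 1:] - M[:, :, :-1, 1:] - M[:, :, 1:, :-1] + M[:, :, :-1, :-1])
    row = counts.sum(axis=3, keepdims=True)
    col = counts.sum(axis=2, keepdims=True)
    counts = counts.astype(float)
    term = np.zeros_like(counts)
    mask = counts > 0
    denom = np.broadcast_to(row * col, counts.shape)[mask]
    term[mask] = counts[mask] / n * np.log2(counts[mask] * n / denom)
    mi = term.sum(axis=(2, 3))
    return float(mi.max())


def mic(x, y, b_exponent: float = 0.6) -> float:
    """Maximal information coefficient by exhaustive grid search.

    Maximum over axis-aligned grids (r x c cells, r*c <= B with
    B = max(n^b_exponent, 4)) of the empirical mutual information,
    normalized by log2(min(r, c)). Deterministic; intended for small n
    (up to a few dozen samples). A constant vector yields 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise DataError("mic expects equal-length vectors")
    if n < 4:
        raise DataError("mic requires n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    B = max(n ** b_exponent, 4.0)

    xorder = np.argsort(x, kind="mergesort")
    xs = x[xorder]
    ys_in_xorder_yrank = stats.rankdata(y, method="ordinal")[xorder]
    y_sorted = np.sort(y, kind="mergesort")
    # cumulative table over (x-order prefix, y-rank prefix)
    ind = np.zeros((n, n), dtype=np.int32)
    ind[np.arange(n), ys_in_xorder_yrank - 1] = 1
    cum = np.zeros((n + 1, n + 1), dtype=np.int32)
    cum[1:, 1:] = np.cumsum(np.cumsum(ind, axis=0), axis=1)

    xcuts = _cut_positions(xs)
    # y cut positions must fall between distinct y values in y-sorted order
    ycuts = _cut_positions(y_sorted)

    best = 0.0
    c = 2
    while c * 2 <= B:
        r = 2
        while r * c <= B:
            mi_max = _max_mi_for_grid(cum, xcuts, ycuts, c, r, n)
            best = max(best, mi_max / math.log2(min(r, c)))
            r += 1
        c += 1
    return float(min(best, 1.0))


# ----------------------------------------------------------------- network

def build_network(
    matrix: ExpressionMatrix,
    elements: list[str] | set[str] | None = None,
    rho_min: float = 0.8,
    p_max: float = 1e-9,
    mic_min: float = 0.6,
    use_mic: bool = True,
    mic_b_exponent: float = 0.6,
    bonferroni_family: int | None = None,
) -> nx.Graph:
    """Build the thresholded co-expression network.

    All unordered pairs of the selected elements are tested; the Bonferroni
    multiplier defaults to the number of tested pairs (pairs involving a
    constant vector are skipped and not counted). When ``use_mic`` is true,
    an edge passing the correlation rule is kept only if its MIC clears
    ``mic_min``; the MIC is evaluated only for those candidate edges, which
    is equivalent to the AND of the three filters.

    Node set = all selected elements (isolated nodes retained).
    """
    if matrix.n_samples < 4:
        raise DataError("build_network requires at least 4 samples")
    if elements is None:
        ids = matrix.gene_ids()
    else:
        wanted = set(elements)
        ids = [e for e in matrix.element_ids if e in wanted]
        missing = wanted - set(ids)
        if missing:
            raise DataError(f"elements not in matrix: {sorted(missing)}")
    if len(ids) < 2:
        raise DataError("build_network requires at least 2 elements")

    values = matrix.data.loc[ids].to_numpy(dtype=float)
    n = values.shape[1]
    const = np.ptp(values, axis=1) == 0
    if const.any():
        logger.info("build_network: skipping %d constant element(s)", const.sum())
    live = np.nonzero(~const)[0]
    k = len(live)

    g = nx.Graph()
    g.add_nodes_from(ids)
    if k < 2:
        return g

    ranks = np.vstack([stats.rankdata(values[i], method="average") for i in live])
    rho = np.corrcoef(ranks)
    np.clip(rho, -1.0, 1.0, out=rho)

    m = bonferroni_family if bonferroni_family is not None else k * (k - 1) // 2
    iu, ju = np.triu_indices(k, 1)
    r = rho[iu, ju]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p_raw = np.where(np.abs(r) >= 1.0, _TINY_P, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    p_raw = np.clip(p_raw, _TINY_P, 1.0)
    p_adj = np.minimum(1.0, p_raw * m)

    keep = (r >= rho_min) & (p_adj <= p_max)
    for idx in np.nonzero(keep)[0]:
        a, b = live[iu[idx]], live[ju[idx]]
        mic_val = None
        if use_mic:
            mic_val = mic(values[a], values[b], b_exponent=mic_b_exponent)
            if mic_val < mic_min:
                continue
        g.add_edge(ids[a], ids[b], rho=float(r[idx]), p_adj=float(p_adj[idx]), mic=mic_val)
    return g
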