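"""Moderated-t differential expression with family-wise error control.

Each non-reference condition is contrasted against the reference on log2
values. Per-element variances are shrunk toward a common prior by the
standard empirical-Bayes scheme: the residual variances s_g^2 (pooled over
the two groups, d_g = n1 + n2 - 2 residual df) are modeled as draws from a
scaled inverse-chi-square prior with hyperparameters (d0, s0^2), giving the
posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and a moderated t = log2FC / (s~_g * sqrt(1/n1 + 1/n2)) on d0 + d_g
degrees of freedom. The hyperparameters are estimated by moment-matching
the log-variances: with z_g = log(s_g^2) and
e_g = z_g - digamma(d_g/2) + log(d_g/2),

    var(e) - trigamma(d_g/2) = trigamma(d0/2)        -> d0
    mean(e) + digamma(d0/2) - log(d0/2) = log(s0^2)  -> s0^2

which is deterministic given the data. d0 = 0 recovers the ordinary
pooled-variance two-sample t exactly; an infinite d0 (no excess spread in
the observed variances) fixes every variance at s0^2 with normal-theory
p-values.

Raw p-values are Bonferroni adjusted over the elements tested in the
contrast; an element is called up (down) when p_adj <= fwer and
log2FC > fc_min (< -fc_min), the fold-change rule being strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .datatypes import ExpressionMatrix, SampleDesign
from .errors import DataError, DesignError

DEFAULT_FWER = 0.05
DEFAULT_FC_MIN = 2.0


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = float(_trigamma(x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df_resid: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled inverse-chi-square prior.

    Elements with zero sample variance are excluded from the fit. Returns
    ``d0 = inf`` when the observed log-variances are no more dispersed than
    sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if len(positive) < 2:
        raise DataError("need at least 2 positive variances to estimate the prior")
    z = np.log(positive)
    e = z - digamma(df_resid / 2.0) + math.log(df_resid / 2.0)
    evar = float(np.var(e, ddof=1)) - float(_trigamma(df_resid / 2.0))
    if evar <= 0:
        # no excess spread beyond sampling: homoscedastic limit, where the
        # arithmetic mean is the natural pooled estimate
        d0 = math.inf
        s0_2 = float(np.mean(positive))
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = math.exp(float(np.mean(e)) + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return d0, s0_2


@dataclass
class DEResult:
    """Tidy per-element, per-contrast differential-expression table.

    ``table`` columns: element_id, condition, log2fc, t_stat, df_total,
    p_raw, p_adj, call (up / down / none). ``d0``/``s0_2`` record the
    variance-prior hyperparameters per condition.
    """

    table: pd.DataFrame
    reference: str
    fwer: float
    fc_min: float
    priors: dict[str, tuple[float, float]]


def log2_fold_change(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    condition: str,
    reference: str | None = None,
) -> pd.Series:
    """Mean log2 value in ``condition`` minus mean in the reference."""
    if matrix.scale != "log2":
        raise DataError("log2_fold_change expects a log2-scale matrix")
    reference = reference or design.reference_condition
    for label in (condition, reference):
        if label not in design.conditions:
            raise DesignError(f"unknown condition {label!r}")
    cond_samples = [s for s in design.samples_of(condition) if s in matrix.data.columns]
    ref_samples = [s for s in design.samples_of(reference) if s in matrix.data.columns]
    if len(cond_samples) < 2 or len(ref_samples) < 2:
        raise DesignError("both conditions need at least 2 samples in the matrix")
    lfc = matrix.data[cond_samples].mean(axis=1) - matrix.data[ref_samples].mean(axis=1)
    lfc.name = f"log2fc_{condition}_vs_{reference}"
    return lfc


def moderated_t(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    condition: str,
    reference: str | None = None,
    d0: float | str = "estimate",
) -> pd.DataFrame:
    """Moderated two-group t statistics for one contrast.

    Returns a DataFrame indexed by element id with columns log2fc, t_stat,
    df_total, p_raw, plus attrs ``d0`` and ``s0_2``. ``d0`` may be a fixed
    prior df (0 gives the ordinary pooled t) or ``"estimate"``.
    """
    reference = reference or design.reference_condition
    lfc = log2_fold_change(matrix, design, condition, reference)
    cond_samples = [s for s in design.samples_of(condition) if s in matrix.data.columns]
    ref_samples = [s for s in design.samples_of(reference) if s in matrix.data.columns]
    n1, n2 = len(cond_samples), len(ref_samples)
    df_resid = n1 + n2 - 2
    if df_resid < 1:
        raise DataError("zero residual degrees of freedom")

    x = matrix.data[cond_samples].to_numpy(dtype=float)
    y = matrix.data[ref_samples].to_numpy(dtype=float)
    ss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if d0 == "estimate":
        d0_val, s0_2 = estimate_variance_prior(s2, df_resid)
    else:
        d0_val = float(d0)
        if d0_val < 0:
            raise DataError("d0 must be nonnegative")
        if d0_val > 0:
            # moment-consistent s0^2 on the log scale for the given d0
            e = np.log(s2[s2 > 0]) - digamma(df_resid / 2.0) + math.log(df_resid / 2.0)
            if math.isinf(d0_val):
                s0_2 = float(np.mean(s2[s2 > 0]))
            else:
                s0_2 = math.exp(float(np.mean(e)) + float(digamma(d0_val / 2.0))
                                - math.log(d0_val / 2.0))
        else:
            s0_2 = float("nan")

    if math.isinf(d0_val):
        s2_post = np.full_like(s2, s0_2)
        df_total = math.inf
    elif d0_val == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (d0_val * s0_2 + df_resid * s2) / (d0_val + df_resid)
        df_total = d0_val + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc.to_numpy() / se
    if math.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p_raw = np.clip(p_raw, np.nextafter(0, 1), 1.0)

    out = pd.DataFrame(
        {
            "log2fc": lfc.to_numpy(),
            "t_stat": t,
            "df_total": df_total,
            "p_raw": p_raw,
        },
        index=matrix.data.index,
    )
    out.attrs["d0"] = d0_val
    out.attrs["s0_2"] = s0_2
    return out


def differential_expression(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    elements: list[str] | set[str] | None = None,
    fwer: float = DEFAULT_FWER,
    fc_min: float = DEFAULT_FC_MIN,
    d0: float | str = "estimate",
) -> DEResult:
    """All non-reference contrasts with Bonferroni FWER control.

    ``elements`` restricts testing (e.g. to expressed elements); the
    Bonferroni family per contrast is the number of elements tested.
    """
    design.validate_against(matrix)
    if elements is not None:
        wanted = set(elements)
        sub = matrix.data.loc[[e for e in matrix.element_ids if e in wanted]]
        matrix = ExpressionMatrix(sub, matrix.scale,
                                  matrix.background_ids & frozenset(sub.index))
    reference = design.reference_condition
    frames = []
    priors: dict[str, tuple[float, float]] = {}
    m = matrix.n_elements
    for condition in design.conditions:
        if condition == reference:
            continue
        stats_df = moderated_t(matrix, design, condition, reference, d0=d0)
        priors[condition] = (stats_df.attrs["d0"], stats_df.attrs["s0_2"])
        p_adj = np.minimum(1.0, stats_df["p_raw"].to_numpy() * m)
        call = np.where(
            (p_adj <= fwer) & (stats_df["log2fc"].to_numpy() > fc_min), "up",
            np.where((p_adj <= fwer) & (stats_df["log2fc"].to_numpy() < -fc_min),
                     "down", "none"),
        )
        frame = stats_df.reset_index(names="element_id")
        frame.insert(1, "condition", condition)
        frame["p_adj"] = p_adj
        frame["call"] = call
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    return DEResult(table=table, reference=reference, fwer=fwer, fc_min=fc_min,
                    priors=priors)


def de_sets(result: DEResult) -> pd.DataFrame:
    """Per-condition up/down sets and a summary row.

    Returns a DataFrame with one row per condition: up_genes / down_genes
    (sorted tuples), counts, and the |log2FC| range over called elements.
    """
    rows = []
    for condition, grp in result.table.groupby("condition", sort=False):
        up = tuple(sorted(grp.loc[grp["call"] == "up", "element_id"]))
        down = tuple(sorted(grp.loc[grp["call"] == "down", "element_id"]))
        called = grp[grp["call"] != "none"]
        lfc_abs = called["log2fc"].abs()
        rows.append({
            "condition": condition,
            "n_up": len(up),
            "n_down": len(down),
            "up_genes": up,
            "down_genes": down,
            "abs_lfc_min": float(lfc_abs.min()) if len(called) else float("nan"),
            "abs_lfc_max": float(lfc_abs.max()) if len(called) else float("nan"),
        })
    return pd.DataFrame(rows)


def percent_regulated(up_count: int, down_count: int, total_on_chip: int) -> float:
    """Percentage of regulated elements among all on the platform (2 dp)."""
    if total_on_chip <= 0:
        raise DataError("total_on_chip must be positive")
    if up_count < 0 or down_count < 0:
        raise DataError("counts must be nonnegative")
    return round(100.0 * (up_count + down_count) / total_on_chip, 2)
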