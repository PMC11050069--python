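"""Per-cohort normalization and moderated differential testing.

The workflow mirrors the classical microarray-era linear-model analysis:
quantile normalization to equalise sample distributions, then a two-group
empirical-Bayes moderated t-test in which the per-gene residual variance is
shrunk towards a prior fitted across all genes. Counts and intensity
platforms share the same test after a platform-specific transform
(``log2(count + 0.5)`` for counts).

The moderated statistic for gene g is

    t_g = lfc_g / (s_tilde_g * sqrt(1/n1 + 1/n2)),
    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

with ``lfc_g`` the polyploid-minus-diploid mean difference on the log2
scale, ``s_g^2`` the pooled within-group variance on ``d_g`` degrees of
freedom, and the prior ``(d0, s0^2)`` estimated by matching moments of the
scaled-F distribution of the observed variances. p-values are two-sided
from a t distribution with ``d0 + d_g`` degrees of freedom and are
BH-adjusted per cohort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import DIPLOID, PLATFORM_COUNTS, POLYPLOID, ExpressionDataset
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: intensity matrices whose maximum exceeds this are assumed unlogged
UNLOGGED_INTENSITY_MAX = 30.0

#: pseudo-count added to raw counts before log2
COUNT_OFFSET = 0.5

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NONE = "none"

RESULT_COLUMNS = ["gene_id", "lfc", "t", "p", "fdr", "direction"]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force every column to share one empirical distribution.

    The shared distribution is the vector of row-rank means: sort each
    column, average across columns at each rank, and hand the rank-mean
    vector back to each column in its original order. Ties within a column
    are broken by row order (stable sort), which keeps the transform
    deterministic and idempotent.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValidationError("quantile_normalize expects a 2-D matrix")
    if matrix.shape[1] < 2:
        raise ValidationError("quantile_normalize needs at least 2 columns")
    if not np.isfinite(matrix).all():
        raise ValidationError("quantile_normalize: non-finite entries")
    order = np.argsort(matrix, axis=0, kind="stable")
    rank_means = np.sort(matrix, axis=0).mean(axis=1)
    out = np.empty_like(matrix)
    for j in range(matrix.shape[1]):
        out[order[:, j], j] = rank_means
    return out


def prepare(dataset: ExpressionDataset) -> pd.DataFrame:
    """Transform a cohort to the common log2 scale and quantile-normalize.

    Counts go through ``log2(count + 0.5)``; intensities are taken as
    already log-scaled unless the matrix maximum exceeds
    ``UNLOGGED_INTENSITY_MAX`` (linear-scale microarray exports), in which
    case ``log2(x + 1)`` is applied first.
    """
    values = dataset.matrix.to_numpy(dtype=float)
    if dataset.platform == PLATFORM_COUNTS:
        values = np.log2(values + COUNT_OFFSET)
    elif values.max() > UNLOGGED_INTENSITY_MAX:
        logger.info(
            "dataset %s: intensity max %.1f > %.0f, applying log2(x+1)",
            dataset.name,
            values.max(),
            UNLOGGED_INTENSITY_MAX,
        )
        values = np.log2(values + 1.0)
    normalized = quantile_normalize(values)
    return pd.DataFrame(
        normalized, index=dataset.matrix.index, columns=dataset.matrix.columns
    )


# ---------------------------------------------------------------------------
# empirical-Bayes variance prior
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit the scaled-F prior (d0, s0^2) for observed gene variances.

    Moments are matched on ``log(s2)``: the excess variance of ``log(s2)``
    over the trigamma term of the residual degrees of freedom determines the
    prior degrees of freedom d0. If there is no excess spread (variances
    essentially equal) the prior degenerates to d0 = +inf, i.e. a fully
    pooled variance; a notice is logged.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        logger.info("variance prior: too few positive variances, pooling fully")
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        logger.info("variance prior: no excess spread, using pooled variance")
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(
        np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return d0, s0_sq


# ---------------------------------------------------------------------------
# moderated t-test
# ---------------------------------------------------------------------------

def moderated_t_test(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated t-test for every gene (row) of ``matrix``.

    Parameters
    ----------
    matrix
        Log-scale expression, genes x samples (typically from :func:`prepare`).
    groups
        Sample id -> ``'diploid'`` / ``'polyploid'``.
    prior_df
        Override the fitted prior degrees of freedom; ``0`` recovers the
        ordinary pooled two-sample t-test, ``None`` (default) fits the
        prior from the data.

    Returns
    -------
    DataFrame with columns ``gene_id, lfc, t, p, fdr, direction`` (direction
    is filled with ``'none'``; threshold calls happen in :func:`select_degs`).
    """
    dip = [s for s in matrix.columns if groups.get(s) == DIPLOID]
    pol = [s for s in matrix.columns if groups.get(s) == POLYPLOID]
    if len(dip) < 2 or len(pol) < 2:
        raise ValidationError(
            f"moderated t-test needs >= 2 samples per group "
            f"(diploid={len(dip)}, polyploid={len(pol)})"
        )
    x_dip = matrix[dip].to_numpy(dtype=float)
    x_pol = matrix[pol].to_numpy(dtype=float)
    n1, n2 = x_pol.shape[1], x_dip.shape[1]
    lfc = x_pol.mean(axis=1) - x_dip.mean(axis=1)
    ss = (
        ((x_pol - x_pol.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        + ((x_dip - x_dip.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    )
    df_resid = n1 + n2 - 2
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2, df_resid)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_variance_prior(s2, df_resid)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    scale = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(scale > 0, lfc / np.where(scale > 0, scale, 1.0), 0.0)
    # zero residual variance with zero lfc: t = 0, p = 1 by definition
    degenerate = (scale == 0) & (lfc != 0)
    if degenerate.any():
        t[degenerate] = np.sign(lfc[degenerate]) * np.inf
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    fdr = benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "gene_id": matrix.index,
            "lfc": lfc,
            "t": t,
            "p": p,
            "fdr": fdr,
            "direction": DIRECTION_NONE,
        }
    ).reset_index(drop=True)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (delegates to statsmodels)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DEG calls
# ---------------------------------------------------------------------------

def select_degs(
    results: pd.DataFrame,
    p_cut: float = 0.05,
    fdr_cut: float = 0.1,
) -> tuple[list[str], list[str]]:
    """Call up/down DEGs at strict ``p < p_cut`` and ``fdr < fdr_cut``.

    Mutates the ``direction`` column of ``results`` in place and returns
    the (up, down) gene id lists. Genes with lfc exactly 0 are never called.
    """
    significant = (results["p"] < p_cut) & (results["fdr"] < fdr_cut)
    up_mask = significant & (results["lfc"] > 0)
    down_mask = significant & (results["lfc"] < 0)
    results["direction"] = DIRECTION_NONE
    results.loc[up_mask, "direction"] = DIRECTION_UP
    results.loc[down_mask, "direction"] = DIRECTION_DOWN
    return (
        results.loc[up_mask, "gene_id"].tolist(),
        results.loc[down_mask, "gene_id"].tolist(),
    )


def run_cohort(
    dataset: ExpressionDataset,
    p_cut: float = 0.05,
    fdr_cut: float = 0.1,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Full per-cohort analysis: prepare -> moderated t -> DEG calls."""
    normalized = prepare(dataset)
    results = moderated_t_test(normalized, dataset.sample_groups, prior_df=prior_df)
    select_degs(results, p_cut=p_cut, fdr_cut=fdr_cut)
    return results
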