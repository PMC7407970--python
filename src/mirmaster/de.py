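"""Size-factor normalization, a VST stand-in, and negative-binomial
differential expression with Benjamini-Hochberg adjustment.

The DE test is a deliberately simple per-feature NB Wald test: size-factor
normalization (median-of-ratios), a pooled method-of-moments dispersion
estimate, and a two-sided Wald test on the log2 ratio of normalized group
means.  It is not a DESeq2 clone (no shrinkage, no outlier handling); it
exists to provide calibrated p-values and fold changes on count matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "size_factors",
    "vst_like_transform",
    "bh_adjust",
    "nb_differential_expression",
]

_DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample (column).

    For each feature with a strictly positive geometric mean across samples,
    compute count / geometric-mean; the size factor of a sample is the median
    of those ratios over usable features.

    Raises
    ------
    ValueError
        If no feature is positive in every sample (suggests adding a
        pseudocount upstream).
    """
    mat = np.asarray(counts, dtype=float)
    if mat.size == 0:
        raise ValueError("empty count matrix")
    with np.errstate(divide="ignore"):
        log_geo = np.log(mat).mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; add a pseudocount "
            "or filter samples before computing size factors"
        )
    ratios = mat[usable] / np.exp(log_geo[usable])[:, None]
    factors = np.median(ratios, axis=0)
    if np.any(factors <= 0):
        raise ValueError("non-positive size factor; check input counts")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def vst_like_transform(counts: pd.DataFrame, factors: pd.Series | np.ndarray) -> pd.DataFrame:
    """Normalized log transform ``log2(count / factor + 1)``.

    A deterministic stand-in for a fitted variance-stabilizing transform:
    monotone in counts within each sample and finite everywhere.
    """
    f = np.asarray(factors, dtype=float)
    if np.any(f <= 0):
        raise ValueError("size factors must be positive")
    mat = np.asarray(counts, dtype=float)
    out = np.log2(mat / f[None, :] + 1.0)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are passed through and do not count toward the number of
    tests.  Output is clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


def _pooled_dispersion(norm: np.ndarray, groups: np.ndarray, inv_s: np.ndarray) -> np.ndarray:
    """Method-of-moments NB dispersion per feature, pooled across groups.

    On normalized counts y = K/s with K ~ NB(mean s*q, dispersion a):
    Var(y) ~= q * E[1/s] + a * q^2, so a ~= (S^2 - q*mean(1/s)) / q^2.
    Estimates are computed within each group and pooled with (n_g - 1)
    weights, then floored for stability.
    """
    n_feat = norm.shape[0]
    num = np.zeros(n_feat)
    den = 0.0
    for g in (0, 1):
        cols = groups == g
        n_g = int(cols.sum())
        y = norm[:, cols]
        q = y.mean(axis=1)
        s2 = y.var(axis=1, ddof=1)
        mean_inv_s = inv_s[cols].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            a_g = (s2 - q * mean_inv_s) / (q * q)
        a_g = np.where(np.isfinite(a_g), a_g, 0.0)
        num += (n_g - 1) * a_g
        den += n_g - 1
    return np.maximum(num / den, _DISPERSION_FLOOR)


def nb_differential_expression(counts: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-feature NB Wald test between two groups of samples.

    Parameters
    ----------
    counts : DataFrame
        Raw counts, features x samples.
    groups : array-like of {0, 1} or bool
        One label per sample column; 1/True marks the "tumor" (numerator)
        group.  log2FoldChange is positive when the group-1 normalized mean
        exceeds the group-0 mean.

    Returns
    -------
    DataFrame with columns feature, baseMean, log2FoldChange, pvalue, padj.
    Features with all-zero counts get NaN statistics and are excluded from
    the BH adjustment.
    """
    g = np.asarray(groups)
    if g.dtype == bool:
        g = g.astype(int)
    if set(np.unique(g)) - {0, 1}:
        raise ValueError("groups must be binary (0/1 or bool)")
    if g.shape[0] != counts.shape[1]:
        raise ValueError("one group label per sample column required")
    n1 = int((g == 1).sum())
    n0 = int((g == 0).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs >= 2 samples (dispersion unidentifiable)")

    s = size_factors(counts).to_numpy()
    inv_s = 1.0 / s
    mat = np.asarray(counts, dtype=float)
    norm = mat * inv_s[None, :]

    base_mean = norm.mean(axis=1)
    nonzero = mat.sum(axis=1) > 0

    disp = _pooled_dispersion(norm, g, inv_s)

    q1 = norm[:, g == 1].mean(axis=1)
    q0 = norm[:, g == 0].mean(axis=1)
    eps = 1e-12
    with np.errstate(divide="ignore"):
        lfc = np.log2(np.maximum(q1, eps)) - np.log2(np.maximum(q0, eps))

    # Var(q_hat_g) = (q * sum(1/s_j in g) + n_g * a * q^2) / n_g^2
    sum_inv1 = inv_s[g == 1].sum()
    sum_inv0 = inv_s[g == 0].sum()
    var_q1 = (q1 * sum_inv1 + n1 * disp * q1 * q1) / (n1 * n1)
    var_q0 = (q0 * sum_inv0 + n0 * disp * q0 * q0) / (n0 * n0)
    ln2sq = np.log(2.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = var_q1 / (np.maximum(q1, eps) ** 2 * ln2sq) + var_q0 / (
            np.maximum(q0, eps) ** 2 * ln2sq
        )
        wald = lfc / np.sqrt(se2)
    wald = np.where(se2 > 0, wald, 0.0)
    # t reference with the pooled residual df keeps small-sample type I close
    # to nominal (normal reference is anti-conservative at moderate n)
    df = n1 + n0 - 2
    pval = 2.0 * stats.t.sf(np.abs(wald), df=df)

    lfc = np.where(nonzero, lfc, np.nan)
    pval = np.where(nonzero, pval, np.nan)
    padj = bh_adjust(pval)

    return pd.DataFrame(
        {
            "feature": counts.index,
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "pvalue": pval,
            "padj": padj,
        }
    )
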