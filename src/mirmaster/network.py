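"""ARACNe-style mutual-information network inference.

Pairwise MI between rank-transformed expression profiles is estimated with
adaptive partitioning: the unit rank square is split recursively into
quadrants, stopping when a chi-square test cannot reject local uniformity.
Edges are kept above a permutation-null MI threshold, pruned with the data
processing inequality (DPI), and aggregated over bootstrap resamples into a
consensus network with a Poisson support test.

Conventions
-----------
* MI is reported in nats and is exactly 0 for a constant input vector.
* Rank ties are broken by average rank then stable input order, so the
  estimator is deterministic and invariant under strictly monotone
  transforms of either argument.
* Inside bootstrap resamples a seeded sub-ulp jitter is added before
  ranking so that duplicated samples do not produce rank-aligned runs
  (which would inflate MI under independence).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

__all__ = [
    "mutual_information",
    "mi_threshold",
    "dpi_prune",
    "bootstrap_consensus",
    "node_degree",
]

# chi-square critical value, p=0.05, 3 df
_CHI2_CRIT = 7.814727903251179
_MIN_LEAF = 8


@njit(cache=True)
def _mi_from_ranks(rx, ry):  # pragma: no cover - exercised via mutual_information
    n = rx.shape[0]
    idx = np.arange(n)
    cap = 4 * n + 64
    stack = np.empty((cap, 7), dtype=np.int64)
    stack[0, 0] = 0
    stack[0, 1] = n
    stack[0, 2] = 0
    stack[0, 3] = n
    stack[0, 4] = 0
    stack[0, 5] = n
    stack[0, 6] = 1  # the first split is unconditional
    top = 1
    mi = 0.0
    scratch = np.empty(n, dtype=np.int64)
    while top > 0:
        top -= 1
        s = stack[top, 0]
        e = stack[top, 1]
        xl = stack[top, 2]
        xh = stack[top, 3]
        yl = stack[top, 4]
        yh = stack[top, 5]
        force = stack[top, 6]
        npts = e - s
        if npts == 0:
            continue
        wx = xh - xl
        wy = yh - yl
        if npts < _MIN_LEAF or wx < 2 or wy < 2:
            mi += (npts / n) * np.log((npts / n) / ((wx / n) * (wy / n)))
            continue
        xm = xl + wx // 2
        ym = yl + wy // 2
        c0 = 0
        c1 = 0
        c2 = 0
        c3 = 0
        for i in range(s, e):
            q = (0 if rx[idx[i]] < xm else 1) + (0 if ry[idx[i]] < ym else 2)
            if q == 0:
                c0 += 1
            elif q == 1:
                c1 += 1
            elif q == 2:
                c2 += 1
            else:
                c3 += 1
        exp = npts / 4.0
        chi2 = ((c0 - exp) ** 2 + (c1 - exp) ** 2 + (c2 - exp) ** 2 + (c3 - exp) ** 2) / exp
        if force == 1 or chi2 > _CHI2_CRIT:
            off0 = 0
            off1 = c0
            off2 = c0 + c1
            off3 = c0 + c1 + c2
            p0 = off0
            p1 = off1
            p2 = off2
            p3 = off3
            for i in range(s, e):
                q = (0 if rx[idx[i]] < xm else 1) + (0 if ry[idx[i]] < ym else 2)
                if q == 0:
                    scratch[p0] = idx[i]
                    p0 += 1
                elif q == 1:
                    scratch[p1] = idx[i]
                    p1 += 1
                elif q == 2:
                    scratch[p2] = idx[i]
                    p2 += 1
                else:
                    scratch[p3] = idx[i]
                    p3 += 1
            for i in range(npts):
                idx[s + i] = scratch[i]
            counts = (c0, c1, c2, c3)
            offs = (off0, off1, off2, off3)
            xlo = (xl, xm, xl, xm)
            xhi = (xm, xh, xm, xh)
            ylo = (yl, yl, ym, ym)
            yhi = (ym, ym, yh, yh)
            for q in range(4):
                if counts[q] > 0:
                    stack[top, 0] = s + offs[q]
                    stack[top, 1] = s + offs[q] + counts[q]
                    stack[top, 2] = xlo[q]
                    stack[top, 3] = xhi[q]
                    stack[top, 4] = ylo[q]
                    stack[top, 5] = yhi[q]
                    stack[top, 6] = 0
                    top += 1
        else:
            mi += (npts / n) * np.log((npts / n) / ((wx / n) * (wy / n)))
    if mi < 0.0:
        mi = 0.0
    return mi


def _ranks(x: np.ndarray) -> np.ndarray:
    """0-based dense ranks; ties broken by stable input order."""
    return np.argsort(np.argsort(x, kind="stable"), kind="stable").astype(np.int64)


def mutual_information(x, y) -> float:
    """Adaptive-partitioning MI estimate between two profiles, in nats."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if xv.shape[0] < _MIN_LEAF:
        raise ValueError(f"need at least {_MIN_LEAF} samples")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return 0.0  # constant vector carries no information, by convention
    return float(_mi_from_ranks(_ranks(xv), _ranks(yv)))


def mi_threshold(n_samples: int, p_value: float = 1e-4, n_null: int = 1000,
                 seed: int = 0) -> float:
    """(1 - p_value) quantile of MI between independent vectors of length n.

    The null is built by estimating MI between pairs of independently drawn
    uniform vectors (equivalent to permuting one profile against another,
    since the estimator is rank-based).
    """
    if not 0 < p_value < 1:
        raise ValueError("p_value must be in (0, 1)")
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    for i in range(n_null):
        null[i] = mutual_information(rng.random(n_samples), rng.random(n_samples))
    return float(np.quantile(null, 1.0 - p_value))


def _norm_edge(u, v):
    return (u, v) if u <= v else (v, u)


def dpi_prune(edge_weights, tolerance: float = 0.0):
    """Data processing inequality pruning on a weighted undirected graph.

    For every closed triangle the minimum-weight edge is marked for removal
    if its weight is strictly below ``(1 - tolerance)`` times *both* other
    edges.  Marks are collected against the input graph and applied at the
    end, so the result does not depend on triangle visiting order.

    Parameters
    ----------
    edge_weights : mapping of (u, v) -> weight
        Undirected edges; (u, v) and (v, u) are the same edge.
    tolerance : float >= 0

    Returns
    -------
    set of normalized (u, v) tuples that survive pruning.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    w = {}
    adj: dict = {}
    for (u, v), mi in edge_weights.items():
        if u == v:
            raise ValueError("self-loop in edge list")
        key = _norm_edge(u, v)
        w[key] = float(mi)
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    doomed = set()
    keep_factor = 1.0 - tolerance
    for u, v in w:
        common = adj[u] & adj[v]
        for t in common:
            e1 = (u, v)
            e2 = _norm_edge(u, t)
            e3 = _norm_edge(v, t)
            trio = sorted(((w[e1], e1), (w[e2], e2), (w[e3], e3)))
            w_min, e_min = trio[0]
            if w_min < keep_factor * trio[1][0] and w_min < keep_factor * trio[2][0]:
                doomed.add(e_min)
    return set(w) - doomed


def _bootstrap_network(xm: np.ndarray, ym: np.ndarray, threshold: float,
                       tolerance: float, rng: np.random.Generator):
    """Thresholded + DPI-pruned miRNA-gene edges for one sample matrix.

    xm: miRNAs x samples, ym: genes x samples (values already resampled).
    Returns dict (i_mirna, j_gene) -> mi.
    """
    n_mir, n = xm.shape
    n_gene = ym.shape[0]
    rx = np.empty_like(xm, dtype=np.int64)
    ry = np.empty_like(ym, dtype=np.int64)
    # jitter breaks ties from duplicated bootstrap columns independently per
    # feature; magnitude is irrelevant (rank-based estimator)
    for i in range(n_mir):
        rx[i] = _ranks(xm[i] + rng.random(n) * 1e-9)
    for j in range(n_gene):
        ry[j] = _ranks(ym[j] + rng.random(n) * 1e-9)
    edges = {}
    for i in range(n_mir):
        xi = rx[i]
        for j in range(n_gene):
            mi = _mi_from_ranks(xi, ry[j])
            if mi > threshold:
                edges[(i, j)] = mi
    if not edges or tolerance >= 1.0:
        return edges
    # close triangles on the regulator side only (miRNA-gene-miRNA with an
    # on-demand miRNA-miRNA MI): gene-gene closures would prune sibling
    # targets of a single strong regulator, which are direct edges
    closure: dict = {}
    by_gene: dict = {}
    for (i, j) in edges:
        by_gene.setdefault(j, []).append(i)
    weights = {(("m", i), ("g", j)): mi for (i, j), mi in edges.items()}
    for j, mirs in by_gene.items():
        for a, b in itertools.combinations(sorted(mirs), 2):
            key = (a, b)
            if key not in closure:
                closure[key] = _mi_from_ranks(rx[a], rx[b])
            weights[(("m", a), ("m", b))] = closure[key]
    kept = dpi_prune(weights, tolerance)
    return {
        (u[1], v[1]): mi
        for (u, v), mi in (((("m", i), ("g", j)), mi) for (i, j), mi in edges.items())
        if _norm_edge(u, v) in kept
    }


def bootstrap_consensus(
    mirna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    n_boot: int = 100,
    threshold: float | None = None,
    mi_p: float = 1e-4,
    tolerance: float = 0.0,
    consensus_alpha: float = 0.05,
    seed: int = 0,
    n_null: int = 1000,
) -> pd.DataFrame:
    """Bootstrap-consensus miRNA-gene network.

    Per bootstrap: resample samples with replacement, estimate MI for every
    miRNA-gene pair, keep pairs above ``threshold`` (permutation-derived when
    not given), apply DPI.  Consensus keeps edges whose bootstrap support
    exceeds a Poisson tail cutoff at Bonferroni-corrected
    ``consensus_alpha``; with ``n_boot == 1`` the single bootstrap network is
    returned as-is.  Edge MI is the mean over supporting bootstraps and the
    ``direction_sign`` column carries the sign of the Spearman correlation on
    the original (non-resampled) matrix.

    Both matrices must be features x samples on identical sample columns,
    already normalized/transformed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if list(mirna_expr.columns) != list(mrna_expr.columns):
        raise ValueError("miRNA and mRNA matrices must share sample columns")
    n = mirna_expr.shape[1]
    if n < _MIN_LEAF:
        raise ValueError(f"need at least {_MIN_LEAF} shared samples")

    rng = np.random.default_rng(seed)
    if threshold is None:
        threshold = mi_threshold(n, p_value=mi_p, n_null=n_null,
                                 seed=int(rng.integers(2**31)))

    xm_full = np.asarray(mirna_expr, dtype=float)
    ym_full = np.asarray(mrna_expr, dtype=float)

    support: dict = {}
    mi_sum: dict = {}
    for _ in range(n_boot):
        cols = rng.integers(0, n, n)
        edges = _bootstrap_network(xm_full[:, cols], ym_full[:, cols],
                                   threshold, tolerance, rng)
        for e, mi in edges.items():
            support[e] = support.get(e, 0) + 1
            mi_sum[e] = mi_sum.get(e, 0.0) + mi

    if not support:
        return pd.DataFrame(
            columns=["mirna", "gene", "mi", "support", "direction_sign"]
        )

    if n_boot == 1:
        kept = set(support)
    else:
        mu = sum(support.values()) / len(support)
        alpha = consensus_alpha / len(support)  # Bonferroni
        # smallest support whose Poisson(mean-support) tail is significant;
        # unanimous edges always qualify (with a clean network mu approaches
        # n_boot and the pure tail test would reject everything)
        k_poisson = int(stats.poisson.isf(alpha, mu)) + 1
        k_required = min(k_poisson, n_boot)
        kept = {e for e, k in support.items() if k >= k_required}

    mir_ids = list(mirna_expr.index)
    gene_ids = list(mrna_expr.index)
    rows = []
    rank_cache_m: dict = {}
    rank_cache_g: dict = {}
    for (i, j) in sorted(kept):
        if i not in rank_cache_m:
            rank_cache_m[i] = _ranks(xm_full[i]).astype(float)
        if j not in rank_cache_g:
            rank_cache_g[j] = _ranks(ym_full[j]).astype(float)
        rho = np.corrcoef(rank_cache_m[i], rank_cache_g[j])[0, 1]
        sign = 0 if not np.isfinite(rho) or rho == 0 else (1 if rho > 0 else -1)
        rows.append(
            (mir_ids[i], gene_ids[j], mi_sum[(i, j)] / support[(i, j)],
             support[(i, j)], sign)
        )
    return pd.DataFrame(rows, columns=["mirna", "gene", "mi", "support",
                                       "direction_sign"])


def node_degree(network: pd.DataFrame):
    """Per-node link counts: (miRNA degrees, gene degrees) as Series."""
    if network.empty:
        empty = pd.Series(dtype=int)
        return empty.rename("degree"), empty.rename("degree")
    mir = network.groupby("mirna").size().sort_values(ascending=False)
    gene = network.groupby("gene").size().sort_values(ascending=False)
    return mir.rename("degree"), gene.rename("degree")
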