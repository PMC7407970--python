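"""Stage-consistency filter: miRNAs upregulated in every clinical stage and
positively correlated with stage."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STAGES",
    "stage_to_ordinal",
    "spearman_stage_correlation",
    "filter_consistent_upregulated",
]

STAGES = ("I", "II", "III", "IV")
# sub-stages (IIa/IIb...) collapse to the parent stage
_ORDINAL = {"I": 1, "II": 2, "III": 3, "IV": 4}


def stage_to_ordinal(stage) -> float:
    """Map a clinical stage label to 1-4; unparseable labels become NaN."""
    if stage is None or (isinstance(stage, float) and np.isnan(stage)):
        return np.nan
    s = str(stage).strip().upper()
    if s.startswith("STAGE"):
        s = s[5:].strip()
    s = s.rstrip("ABC")
    return float(_ORDINAL.get(s, np.nan))


def spearman_stage_correlation(expr, stages):
    """Spearman rho and t-approximation p between expression and stage.

    Ties get average ranks; samples with missing stage are excluded by the
    caller.  Returns (nan, nan) when either vector is constant.
    """
    x = np.asarray(expr, dtype=float)
    s = np.asarray(stages, dtype=float)
    if x.shape != s.shape:
        raise ValueError("expr and stages must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples with a stage")
    if np.ptp(s) == 0 or np.ptp(x) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, s)
    return float(rho), float(p)


def filter_consistent_upregulated(
    stage_de: dict,
    correlations: pd.DataFrame,
    fdr_cutoff: float = 0.05,
    lfc_cutoff: float = 0.5,
    corr_p_cutoff: float = 0.05,
):
    """Select miRNAs passing every per-stage DE test and the stage trend.

    Parameters
    ----------
    stage_de : mapping of stage label ("I".."IV") -> DE table
        Each table needs columns feature, log2FoldChange, padj.
    correlations : DataFrame indexed by miRNA with columns rho, p.

    Returns
    -------
    (ids, audit) : sorted list of consistent miRNA ids and the full audit
    table with per-stage statistics.  A miRNA missing from any stage table
    fails (treated as not significant there).
    """
    if set(stage_de) != set(STAGES):
        raise ValueError(f"exactly four stage tables required: {STAGES}")
    per_stage = {}
    all_ids = set()
    for st in STAGES:
        tab = stage_de[st].set_index("feature")
        per_stage[st] = tab
        all_ids |= set(tab.index)
    all_ids |= set(correlations.index)

    rows = []
    for mid in sorted(all_ids):
        row = {"mirna": mid}
        ok = True
        for st in STAGES:
            tab = per_stage[st]
            if mid in tab.index:
                lfc = tab.at[mid, "log2FoldChange"]
                fdr = tab.at[mid, "padj"]
            else:
                lfc, fdr = np.nan, np.nan
            row[f"lfc_{st}"] = lfc
            row[f"fdr_{st}"] = fdr
            if not (np.isfinite(fdr) and fdr <= fdr_cutoff
                    and np.isfinite(lfc) and lfc >= lfc_cutoff):
                ok = False
        if mid in correlations.index:
            rho = correlations.at[mid, "rho"]
            p = correlations.at[mid, "p"]
        else:
            rho, p = np.nan, np.nan
        row["spearman_rho"] = rho
        row["spearman_p"] = p
        if not (np.isfinite(rho) and rho > 0 and np.isfinite(p) and p <= corr_p_cutoff):
            ok = False
        row["consistent"] = ok
        rows.append(row)
    audit = pd.DataFrame(rows)
    ids = sorted(audit.loc[audit.consistent, "mirna"])
    return ids, audit


def stage_correlation_table(expr: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Spearman stage correlation for every feature over tumor samples.

    expr is features x samples (normalized scale); metadata needs sample_id,
    condition and stage columns.  Normal samples and samples without a
    parseable stage are excluded.
    """
    meta = metadata.set_index("sample_id")
    tumor = [s for s in expr.columns
             if s in meta.index and meta.at[s, "condition"] == "tumor"]
    ords = np.array([stage_to_ordinal(meta.at[s, "stage"]) for s in tumor])
    keep = np.isfinite(ords)
    cols = [s for s, k in zip(tumor, keep) if k]
    if len(cols) < 3:
        raise ValueError("need at least 3 tumor samples with a stage")
    ords = ords[keep]
    out = []
    for fid, vals in expr[cols].iterrows():
        rho, p = spearman_stage_correlation(vals.to_numpy(), ords)
        out.append((fid, rho, p))
    return pd.DataFrame(out, columns=["feature", "rho", "p"]).set_index("feature")
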