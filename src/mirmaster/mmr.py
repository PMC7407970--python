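"""Master-regulator inference: regulons, a DE-derived gene signature,
normalized enrichment scores against a size-matched gene-sampling null, and
FDR-thresholded regulator calls.

The NES convention follows the repression readout: by default a regulon is
scored by the signed signature values of its targets (weights only), so a
*negative* NES means the regulon's targets are downregulated in tumors
relative to chance.  Mode-weighted scoring (contribution ``weight * mode *
z``) is available via ``mode_weighted=True`` and measures regulator
*activity* instead; for repressive regulons with downregulated targets the
two conventions differ only in sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "Regulon",
    "gene_signature",
    "build_regulons",
    "raw_score",
    "enrichment_nes",
    "score_regulons",
    "call_master_regulators",
]


def raw_score(weights, modes, z) -> float:
    """Weighted-mean enrichment: sum(w * m * z) / sqrt(sum(w^2))."""
    w = np.asarray(weights, float)
    m = np.asarray(modes, float)
    zv = np.asarray(z, float)
    return float(np.sum(w * m * zv) / np.sqrt(np.sum(w * w)))

_Z_CAP = 10.0


@dataclass
class Regulon:
    mirna: str
    targets: list          # gene ids
    modes: np.ndarray      # +/-1 per target
    weights: np.ndarray    # [0, 1] per target

    def __post_init__(self):
        if len(self.targets) != len(set(self.targets)):
            raise ValueError("duplicate targets in regulon")
        self.modes = np.asarray(self.modes, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isin(self.modes, (-1.0, 1.0))):
            raise ValueError("modes must be -1 or +1")
        if np.any((self.weights < 0) | (self.weights > 1)):
            raise ValueError("weights must lie in [0, 1]")

    def __len__(self):
        return len(self.targets)


def gene_signature(de: pd.DataFrame) -> pd.Series:
    """Signed z-scores from a DE table: sign(lfc) * |probit(p/2)|, capped.

    Features with missing p or fold change are dropped; p = 0 saturates at
    the cap (+-10).
    """
    tab = de.dropna(subset=["pvalue", "log2FoldChange"])
    p = np.clip(tab["pvalue"].to_numpy(float), 0.0, 1.0)
    with np.errstate(divide="ignore"):
        mag = np.abs(stats.norm.ppf(p / 2.0))
    mag = np.minimum(mag, _Z_CAP)
    z = np.sign(tab["log2FoldChange"].to_numpy(float)) * mag
    return pd.Series(z, index=tab["feature"].to_numpy(), name="z")


def build_regulons(network: pd.DataFrame, min_size: int = 10):
    """One regulon per miRNA with at least ``min_size`` targets.

    mode = the network's direction_sign (zero signs fall back to +1);
    weight = bootstrap support / max support over the whole network.
    """
    if network.empty:
        return []
    max_support = float(network["support"].max())
    regulons = []
    for mirna, grp in network.groupby("mirna", sort=True):
        if len(grp) < min_size:
            continue
        modes = grp["direction_sign"].to_numpy(float)
        modes = np.where(modes == 0, 1.0, modes)
        regulons.append(
            Regulon(
                mirna=str(mirna),
                targets=list(grp["gene"]),
                modes=modes,
                weights=grp["support"].to_numpy(float) / max_support,
            )
        )
    return regulons


def enrichment_nes(regulon: Regulon, signature: pd.Series, n_null: int = 1000,
                   seed: int = 0, mode_weighted: bool = False):
    """NES and empirical two-sided p for one regulon against a signature.

    raw = sum(w * m * z) / sqrt(sum(w^2)) over targets found in the
    signature (m = mode when ``mode_weighted`` else 1).  The null draws
    ``n_null`` size-matched gene sets from the signature (without
    replacement within each draw) and reuses the regulon's weight/mode
    pattern; nes = (raw - mean) / sd of the null.
    """
    present = [t in signature.index for t in regulon.targets]
    if not any(present):
        raise ValueError(f"regulon {regulon.mirna} has no overlap with the signature")
    targets = [t for t, ok in zip(regulon.targets, present) if ok]
    w = regulon.weights[np.asarray(present)]
    m = regulon.modes[np.asarray(present)] if mode_weighted else np.ones(len(targets))
    zvals = signature.loc[targets].to_numpy(float)
    denom = np.sqrt(np.sum(w * w))
    raw = raw_score(w, m, zvals)

    rng = np.random.default_rng(seed)
    all_z = signature.to_numpy(float)
    n_genes = all_z.size
    k = len(targets)
    if k > n_genes:
        raise ValueError("regulon larger than signature")
    # size-matched random gene sets, one row per null draw
    pick = np.argsort(rng.random((n_null, n_genes)), axis=1)[:, :k]
    null = (all_z[pick] * (w * m)[None, :]).sum(axis=1) / denom
    mu = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate null (constant signature?)")
    nes = (raw - mu) / sd
    p = (1.0 + np.sum(np.abs(null - mu) >= abs(raw - mu))) / (n_null + 1.0)
    return float(nes), float(p)


def score_regulons(regulons, signature: pd.Series, n_null: int = 1000,
                   seed: int = 0, mode_weighted: bool = False) -> pd.DataFrame:
    """Score every regulon; returns mirna, nes, pvalue, fdr, regulon_size."""
    rng = np.random.default_rng(seed)
    rows = []
    for reg in regulons:
        sub = int(rng.integers(2**31))
        try:
            nes, p = enrichment_nes(reg, signature, n_null=n_null, seed=sub,
                                    mode_weighted=mode_weighted)
        except ValueError:
            continue
        rows.append((reg.mirna, nes, p, len(reg)))
    calls = pd.DataFrame(rows, columns=["mirna", "nes", "pvalue", "regulon_size"])
    calls["fdr"] = bh_adjust(calls["pvalue"]) if len(calls) else []
    return calls[["mirna", "nes", "pvalue", "fdr", "regulon_size"]]


def call_master_regulators(calls: pd.DataFrame, fdr_cutoff: float = 0.05):
    """miRNA ids whose BH-adjusted enrichment p is at most ``fdr_cutoff``."""
    if calls.empty:
        return []
    sig = calls.loc[calls["fdr"] <= fdr_cutoff, "mirna"]
    return sorted(sig)
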