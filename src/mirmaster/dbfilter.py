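"""Target-database evidence filter for inferred networks."""

from __future__ import annotations

import pandas as pd

from .synthetic import EdgeSet

__all__ = ["normalize_identifier", "filter_by_databases", "read_edge_set"]


def normalize_identifier(name: str) -> str:
    """Shared namespace: lowercase, species prefix "hsa-" stripped."""
    s = str(name).strip().lower()
    if s.startswith("hsa-"):
        s = s[4:]
    return s


def read_edge_set(path, name=None) -> EdgeSet:
    df = pd.read_csv(path, sep="\t")
    pairs = frozenset(
        (normalize_identifier(m), normalize_identifier(g))
        for m, g in zip(df["mirna"], df["gene"])
    )
    return EdgeSet(name=name or str(path), pairs=pairs)


def filter_by_databases(network: pd.DataFrame, dbs, allow_empty: bool = False) -> pd.DataFrame:
    """Keep network edges present in the union of the supplied databases.

    Adds an ``evidence`` column listing the supporting database names per
    edge.  An empty database list is rejected unless ``allow_empty`` is set
    (in which case the network passes through with empty evidence).
    """
    dbs = list(dbs)
    if not dbs and not allow_empty:
        raise ValueError(
            "no databases supplied; the filter would discard every edge "
            "(pass allow_empty=True to skip filtering)"
        )
    if network.empty:
        out = network.copy()
        out["evidence"] = pd.Series(dtype=str)
        return out
    norm_pairs = [
        (normalize_identifier(m), normalize_identifier(g))
        for m, g in zip(network["mirna"], network["gene"])
    ]
    if not dbs:
        out = network.copy()
        out["evidence"] = ""
        return out
    evidence = []
    keep = []
    for pair in norm_pairs:
        names = [db.name for db in dbs if pair in db.pairs]
        keep.append(bool(names))
        evidence.append(",".join(names))
    out = network.loc[keep].copy()
    out["evidence"] = [e for e, k in zip(evidence, keep) if k]
    return out.reset_index(drop=True)
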