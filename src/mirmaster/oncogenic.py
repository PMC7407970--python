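"""Oncogenic Activity: tally driver-gene targets by role and regulation
direction, then score each regulator.

Oe = (UONC + DTSG) - ONCTSG
Ae = (DONC + UTSG) - ONCTSG
OA = (Oe - Ae) / T,  T = UONC + DTSG + DONC + UTSG + ONCTSG

Dual-role genes count once, in ONCTSG and T only, which keeps the
subtraction well-defined and bounds OA to [-1, 1].  Direction comes from the
pooled tumor-vs-normal log2 fold change; exactly-zero or missing fold
changes exclude the target from the tally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

__all__ = [
    "DriverTally",
    "classify_target_direction",
    "tally_driver_targets",
    "oncogenic_activity",
    "classify_mmr",
    "round_half_away",
    "oa_table",
]


@dataclass(frozen=True)
class DriverTally:
    uonc: int = 0   # upregulated oncogene targets
    dtsg: int = 0   # downregulated TSG targets
    donc: int = 0   # downregulated oncogene targets
    utsg: int = 0   # upregulated TSG targets
    onctsg: int = 0  # dual-role targets

    def __post_init__(self):
        for f in ("uonc", "dtsg", "donc", "utsg", "onctsg"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")

    @property
    def t(self) -> int:
        return self.uonc + self.dtsg + self.donc + self.utsg + self.onctsg


def classify_target_direction(log2fc):
    """"up" / "down" from a fold change; zero or missing -> None."""
    if log2fc is None or (isinstance(log2fc, float) and not math.isfinite(log2fc)):
        return None
    if log2fc > 0:
        return "up"
    if log2fc < 0:
        return "down"
    return None


def tally_driver_targets(targets, roles, log2fc) -> DriverTally:
    """Count a regulator's driver targets by role and direction.

    Parameters
    ----------
    targets : iterable of gene ids (a regulon's target list)
    roles : mapping gene -> {oncogene, tsg, dual, none}; missing = none
    log2fc : mapping gene -> pooled tumor-vs-normal fold change

    Genes with role none are ignored; dual genes increment only ONCTSG
    (direction irrelevant, but a defined direction is still required).
    """
    uonc = dtsg = donc = utsg = onctsg = 0
    for g in targets:
        role = roles.get(g, "none")
        if role == "none":
            continue
        direction = classify_target_direction(log2fc.get(g))
        if direction is None:
            continue
        if role == "dual":
            onctsg += 1
        elif role == "oncogene":
            if direction == "up":
                uonc += 1
            else:
                donc += 1
        elif role == "tsg":
            if direction == "up":
                utsg += 1
            else:
                dtsg += 1
        else:
            raise ValueError(f"unknown role {role!r} for gene {g}")
    return DriverTally(uonc, dtsg, donc, utsg, onctsg)


def oncogenic_activity(tally: DriverTally):
    """(Oe, Ae, OA) for a tally; OA is an exact Fraction, None when T = 0."""
    oe = (tally.uonc + tally.dtsg) - tally.onctsg
    ae = (tally.donc + tally.utsg) - tally.onctsg
    if tally.t == 0:
        return oe, ae, None
    return oe, ae, Fraction(oe - ae, tally.t)


def classify_mmr(oa) -> str:
    """oncogenic if OA > 0, suppressor if OA < 0, else neutral.

    An undefined OA (no driver targets) is neutral-by-absence.
    """
    if oa is None:
        return "neutral"
    if oa > 0:
        return "oncogenic"
    if oa < 0:
        return "suppressor"
    return "neutral"


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (table-reporting convention)."""
    scale = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def oa_table(regulons, roles, log2fc) -> pd.DataFrame:
    """Per-regulator tally, effects, OA (2 decimals) and class."""
    rows = []
    for reg in regulons:
        targets = reg.targets if hasattr(reg, "targets") else list(reg[1])
        name = reg.mirna if hasattr(reg, "mirna") else reg[0]
        tally = tally_driver_targets(targets, roles, log2fc)
        oe, ae, oa = oncogenic_activity(tally)
        rows.append(
            {
                "mirna": name,
                "UONC": tally.uonc,
                "DTSG": tally.dtsg,
                "DONC": tally.donc,
                "UTSG": tally.utsg,
                "ONCTSG": tally.onctsg,
                "T": tally.t,
                "Oe": oe,
                "Ae": ae,
                "OA": float("nan") if oa is None else round_half_away(float(oa), 2),
                "class": classify_mmr(oa),
            }
        )
    return pd.DataFrame(rows)
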