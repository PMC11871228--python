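"""Subregion assignment from water-mass fractions.

Four subregions are defined by fraction thresholds: the TSW-dominated
region (TSWR, excluded from CDW/KSSW analyses), the CDW-dominated region
(CDWR), the CDW–KSSW mixing region (C-KMR) and the KSSW-dominated region
(KSSWR).  The threshold clauses overlap, so they are evaluated in a
fixed precedence order TSWR -> C-KMR -> CDWR -> KSSWR; C-KMR fires
before CDWR/KSSWR because it is the most specific clause (two-sided on
both fractions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SUBREGIONS = ("TSWR", "CDWR", "C_KMR", "KSSWR")


@dataclass(frozen=True)
class RegionThresholds:
    """Fraction thresholds for the four subregion clauses (all inclusive as noted)."""

    tswr_tsw_min: float = 0.55       # TSWR: f_tsw >= this
    ckmr_cdw_lo: float = 0.40        # C-KMR: lo <= f_cdw <= hi
    ckmr_cdw_hi: float = 0.90
    ckmr_kssw_lo: float = 0.05       #        lo <= f_kssw <= hi
    ckmr_kssw_hi: float = 0.15
    cdwr_cdw_min: float = 0.40       # CDWR: f_cdw > this and f_kssw <= max
    cdwr_kssw_max: float = 0.10
    ksswr_cdw_max: float = 0.90      # KSSWR: f_cdw < this and f_kssw > min
    ksswr_kssw_min: float = 0.05


@dataclass
class SubregionLabel:
    label: str
    rule_applied: str


def classify(
    f_cdw: float, f_tsw: float, f_kssw: float, thresholds: RegionThresholds | None = None
) -> SubregionLabel:
    """Assign exactly one subregion label to an on-simplex fraction triple."""
    th = thresholds or RegionThresholds()
    f = np.array([f_cdw, f_tsw, f_kssw])
    if abs(f.sum() - 1.0) > 1e-6 or np.any(f < -1e-9) or np.any(f > 1 + 1e-9):
        raise ValueError(f"fractions off the simplex: {tuple(f)}")
    if f_tsw >= th.tswr_tsw_min:
        return SubregionLabel("TSWR", f"f_tsw >= {th.tswr_tsw_min}")
    if th.ckmr_cdw_lo <= f_cdw <= th.ckmr_cdw_hi and th.ckmr_kssw_lo <= f_kssw <= th.ckmr_kssw_hi:
        return SubregionLabel(
            "C_KMR",
            f"{th.ckmr_cdw_lo} <= f_cdw <= {th.ckmr_cdw_hi} and "
            f"{th.ckmr_kssw_lo} <= f_kssw <= {th.ckmr_kssw_hi}",
        )
    if f_cdw > th.cdwr_cdw_min and f_kssw <= th.cdwr_kssw_max:
        return SubregionLabel("CDWR", f"f_cdw > {th.cdwr_cdw_min} and f_kssw <= {th.cdwr_kssw_max}")
    if f_cdw < th.ksswr_cdw_max and f_kssw > th.ksswr_kssw_min:
        return SubregionLabel("KSSWR", f"f_cdw < {th.ksswr_cdw_max} and f_kssw > {th.ksswr_kssw_min}")
    return SubregionLabel("UNCLASSIFIED", "no clause matched")


DEFAULT_SUMMARY_COLS = (
    "sum_pb", "b_frac", "d_frac", "a_frac",
    "f_cdw", "f_tsw", "f_kssw",
    "nox_umolL", "dip_umolL", "nox_init", "dip_init",
)


def subregion_summary(
    table: pd.DataFrame, value_cols: tuple[str, ...] = DEFAULT_SUMMARY_COLS
) -> pd.DataFrame:
    """Per-subregion count, mean and SD of the requested columns.

    Rows for empty subregions carry count 0 and NaN statistics;
    single-station subregions get NaN SDs.
    """
    cols = [c for c in value_cols if c in table.columns]
    rows = []
    for sub in SUBREGIONS + ("UNCLASSIFIED",):
        grp = table[table["subregion"] == sub]
        row: dict = {"subregion": sub, "n": len(grp)}
        for c in cols:
            row[f"{c}_mean"] = grp[c].mean() if len(grp) else np.nan
            row[f"{c}_sd"] = grp[c].std(ddof=1) if len(grp) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
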