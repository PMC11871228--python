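"""Lipid-biomarker community metrics.

The sum of brassicasterol (diatoms), dinosterol (dinoflagellates) and
C37 alkenones (haptophytes) is used as a proxy of total phytoplankton
biomass (sum_pb, ng/L), and each biomarker's share of the sum as the
contribution of its group to the community (B/sum_pb, D/sum_pb,
A/sum_pb).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class CommunityMetrics:
    """sum_pb and the three group fractions; fractions are NaN when sum_pb = 0."""

    sum_pb: float
    b_frac: float
    d_frac: float
    a_frac: float


def community_metrics(b: float, d: float, a: float) -> CommunityMetrics:
    """Total biomarker biomass and per-group shares.

    Zero is a true non-detect and contributes zero; a station with all
    three at zero has sum_pb 0 and undefined (NaN) fractions — zero
    biomass carries no community information.
    """
    vals = (b, d, a)
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
        if all(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
            return CommunityMetrics(math.nan, math.nan, math.nan, math.nan)
        raise ValueError("either all three biomarker concentrations or none must be present")
    if any(v < 0 for v in vals):
        raise ValueError(f"negative biomarker concentration in {vals}")
    total = b + d + a
    if total == 0:
        return CommunityMetrics(0.0, math.nan, math.nan, math.nan)
    return CommunityMetrics(total, b / total, d / total, a / total)


@dataclass
class OutlierRule:
    """Stations excluded from fraction–response regressions (kept elsewhere).

    ``ids`` names stations explicitly (e.g. an extreme-biomass station);
    ``sum_pb_threshold`` flags any station above it. Empty rule flags
    nothing.
    """

    ids: tuple[str, ...] = ()
    sum_pb_threshold: float | None = None


def flag_outliers(table: pd.DataFrame, rule: OutlierRule | None = None) -> pd.Series:
    """Boolean flags, aligned with ``table``, for regression exclusion.

    Requires ``station_id`` and ``sum_pb`` columns when the respective
    rule component is set.
    """
    rule = rule or OutlierRule()
    flags = pd.Series(False, index=table.index, name="outlier_flag")
    if rule.ids:
        flags |= table["station_id"].astype(str).isin([str(i) for i in rule.ids])
    if rule.sum_pb_threshold is not None:
        flags |= table["sum_pb"] > rule.sum_pb_threshold
    return flags
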