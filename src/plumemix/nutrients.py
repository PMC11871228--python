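"""Preformed (initial) nutrients from conservative water-mass mixing.

Given the mixing fractions of the three end-members, the preformed
concentration of a conservative tracer is the fraction-weighted mean of
the end-member values: ``nox_init = sum(f_i * NOx_i)`` and likewise for
DIP.  The measured-minus-preformed anomaly separates biology from
physics: measured below preformed implies uptake by phytoplankton,
measured above preformed implies production by organic-matter
mineralization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .endmember import EndMemberSet, MixingResult

logger = logging.getLogger(__name__)

#: measured DIP below this detection limit is replaced by the floor value
DIP_DETECTION_LIMIT = 0.02
DIP_FLOOR = 0.01

#: anomaly magnitudes below these thresholds (umol/L) count as neutral;
#: chosen near analytical precision, configurable per call
NOX_ANOMALY_THRESHOLD = 0.5
DIP_ANOMALY_THRESHOLD = 0.05


@dataclass
class PreformedNutrients:
    """Conservative-mixing nutrient predictions for one station."""

    nox_init: float
    dip_init: float

    @property
    def np_init(self) -> float:
        """Molar N/P of the preformed pool (NaN when dip_init is 0)."""
        return self.nox_init / self.dip_init if self.dip_init > 0 else math.nan


@dataclass
class NutrientAnomaly:
    """Measured minus preformed, tagged as consumption/production/neutral.

    ``tag`` follows the NO_x anomaly (the primary uptake signal);
    ``tag_dip`` carries the phosphate equivalent.
    """

    d_nox: float
    d_dip: float
    tag: str
    tag_dip: str


def preformed_concentration(result: MixingResult, ems: EndMemberSet) -> PreformedNutrients:
    """Preformed NO_x and DIP from the station's mixing fractions.

    Linear in the fractions, hence bounded by the end-member values
    (convexity on the simplex).
    """
    if not result.in_triangle:
        raise ValueError("no fractions: station was outside the mixing triangle")
    f = result.fractions
    return PreformedNutrients(nox_init=float(f @ ems.nox), dip_init=float(f @ ems.dip))


def apply_dip_floor(
    dip_measured: float, detection_limit: float = DIP_DETECTION_LIMIT, floor: float = DIP_FLOOR
) -> float:
    """Replace sub-detection-limit DIP with the floor value (0.01 umol/L).

    Missing (NaN) input propagates unchanged.
    """
    if dip_measured is None or (isinstance(dip_measured, float) and math.isnan(dip_measured)):
        return math.nan
    if dip_measured < 0:
        raise ValueError(f"negative DIP concentration: {dip_measured}")
    return floor if dip_measured < detection_limit else dip_measured


def np_ratio(nox: float, dip: float) -> float:
    """Molar N/P; NaN with a warning when DIP is zero."""
    if dip == 0:
        logger.warning("N/P undefined: DIP is zero")
        return math.nan
    if dip < 0 or nox < 0:
        raise ValueError("negative nutrient concentration")
    return nox / dip


def _tag(delta: float, threshold: float) -> str:
    if delta < -threshold:
        return "consumption"
    if delta > threshold:
        return "production"
    return "neutral"


def nutrient_anomaly(
    measured_nox: float,
    measured_dip: float,
    preformed: PreformedNutrients,
    nox_threshold: float = NOX_ANOMALY_THRESHOLD,
    dip_threshold: float = DIP_ANOMALY_THRESHOLD,
) -> NutrientAnomaly:
    """Signed measured-minus-preformed deltas with qualitative tags."""
    d_nox = measured_nox - preformed.nox_init
    d_dip = measured_dip - preformed.dip_init
    return NutrientAnomaly(
        d_nox=d_nox,
        d_dip=d_dip,
        tag=_tag(d_nox, nox_threshold),
        tag_dip=_tag(d_dip, dip_threshold),
    )
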