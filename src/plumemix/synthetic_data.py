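"""Synthetic cruise generator with known ground truth.

Emulates a ~60-station surface survey of a river-plume / upwelling
coastal margin: water-mass fractions vary smoothly in space (river
plume high nearshore and to the north, warm strait water in the
southeast, subsurface oceanic water upwelling along the coast), T/S
follow conservative mixing plus observation noise, nutrients are
preformed values minus a biomass-proportional uptake, total biomarker
biomass peaks where the river and upwelled water masses mix, and the
community fractions respond linearly to the water-mass fractions.  The
generative links are this module's constructions — calibrated to the
qualitative behaviour of such systems, not measured facts — and every
coefficient is exposed on :class:`ScenarioConfig`.

The returned truth table enables parameter-recovery scoring: true
fractions, preformed nutrients, biomass and community fractions and the
true subregion label of every station.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .endmember import EndMemberSet, bundled_endmembers
from .nutrients import apply_dip_floor
from .regionalization import RegionThresholds, classify

LON_RANGE = (120.0, 124.0)
LAT_RANGE = (26.6, 32.5)


@dataclass
class ScenarioConfig:
    """Defaults are the study conditions the generator emulates."""

    season: str = "spring"
    n_stations: int = 60
    endmembers: EndMemberSet | None = None
    seed: int = 1

    # observation noise on the conservative tracers
    sigma_T: float = 0.05            # degC
    sigma_S: float = 0.05

    # nutrient uptake: umol/L removed per ng/L of total biomarker biomass
    alpha_nox: float = 0.002
    alpha_dip: float = 0.000125      # alpha_nox / 16 (Redfield-like)
    sigma_nox: float = 0.3           # umol/L measurement noise
    sigma_dip: float = 0.02

    # biomass field: baseline + peak inside the CDW/KSSW mixing window
    pb_baseline: float = 150.0       # ng/L
    pb_peak: float = 2400.0          # ng/L
    sigma_pb: float = 40.0
    pb_min: float = 20.0
    window_cdw: tuple[float, float] = (0.40, 0.90)
    window_kssw: tuple[float, float] = (0.05, 0.15)

    # community structure: linear response to water-mass fractions
    b_intercept: float = 0.55
    slope_b_kssw: float = 0.5        # dB/df_kssw
    slope_b_cdw: float = -0.25       # dB/df_cdw
    d_intercept: float = 0.35       # dinosterol share mirrors with opposite signs
    sigma_b: float = 0.01            # measurement-repeatability SDs of the shares
    sigma_d: float = 0.02
    sigma_a: float = 0.02

    # ancillary fields
    tsm_base: float = 3.0            # mg/L; increases with river fraction
    tsm_slope: float = 40.0
    sigma_tsm: float = 1.0
    chla_per_pb: float = 0.0025      # ug/L per ng/L of biomass
    sigma_chla: float = 0.2

    thresholds: RegionThresholds = field(default_factory=RegionThresholds)

    def __post_init__(self) -> None:
        if self.n_stations < 3:
            raise ValueError("need at least 3 stations")
        for name in ("sigma_T", "sigma_S", "sigma_nox", "sigma_dip", "sigma_pb",
                     "sigma_b", "sigma_d", "sigma_a", "sigma_tsm", "sigma_chla"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def resolve_endmembers(self) -> EndMemberSet:
        return self.endmembers or bundled_endmembers(self.season)


def _smooth_window(x: np.ndarray, lo: float, hi: float, sharpness: float) -> np.ndarray:
    """Smooth indicator of [lo, hi]: product of two sigmoids, ~1 inside."""
    return 1.0 / (1.0 + np.exp(-(x - lo) / sharpness)) / (1.0 + np.exp((x - hi) / sharpness))


def _fraction_fields(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Softmax of three smooth spatial trends -> (n, 3) simplex points.

    u is scaled longitude (0 west, 1 east), v scaled latitude (0 south,
    1 north).  River water dominates nearshore/north, strait water the
    southeast, upwelled subsurface water the central coast.
    """
    g_cdw = 2.1 * v - 0.5 * u + 0.3 * np.sin(3.0 * v + 1.0)
    g_tsw = -1.5 * v + 2.9 * u - 1.25 + 0.3 * np.sin(3.0 * u)
    g_kssw = 0.15 - 6.0 * (v - 0.5) ** 2 - 3.0 * u + 0.25 * np.sin(4.0 * v)
    g = np.column_stack([g_cdw, g_tsw, g_kssw])
    g -= g.max(axis=1, keepdims=True)
    e = np.exp(g)
    return e / e.sum(axis=1, keepdims=True)


def generate_cruise(config: ScenarioConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one cruise: (station table, truth table).

    Fully deterministic for a fixed ``config.seed``.  The station table
    passes :func:`plumemix.io_config.read_station_table` validation when
    round-tripped through CSV.
    """
    cfg = config or ScenarioConfig()
    ems = cfg.resolve_endmembers()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_stations

    lon = rng.uniform(*LON_RANGE, n)
    lat = rng.uniform(*LAT_RANGE, n)
    u = (lon - LON_RANGE[0]) / (LON_RANGE[1] - LON_RANGE[0])
    v = (lat - LAT_RANGE[0]) / (LAT_RANGE[1] - LAT_RANGE[0])
    f = _fraction_fields(u, v)

    T = f @ ems.T + cfg.sigma_T * rng.standard_normal(n)
    S = f @ ems.S + cfg.sigma_S * rng.standard_normal(n)

    # biomass peaks where river and upwelled water mix
    w = _smooth_window(f[:, 0], *cfg.window_cdw, 0.035) * _smooth_window(f[:, 2], *cfg.window_kssw, 0.012)
    sum_pb_true = cfg.pb_baseline + cfg.pb_peak * w
    sum_pb = np.maximum(cfg.pb_min, sum_pb_true + cfg.sigma_pb * rng.standard_normal(n))

    # preformed nutrients minus biomass-proportional uptake
    nox_init = f @ ems.nox
    dip_init = f @ ems.dip
    nox_meas = np.maximum(0.0, nox_init - cfg.alpha_nox * sum_pb + cfg.sigma_nox * rng.standard_normal(n))
    dip_meas = np.maximum(0.0, dip_init - cfg.alpha_dip * sum_pb + cfg.sigma_dip * rng.standard_normal(n))
    dip_meas = np.array([apply_dip_floor(x) for x in dip_meas])

    # community fractions linear in the water-mass fractions
    b_true = cfg.b_intercept + cfg.slope_b_kssw * f[:, 2] + cfg.slope_b_cdw * f[:, 0]
    d_true = cfg.d_intercept - cfg.slope_b_kssw * f[:, 2] - cfg.slope_b_cdw * f[:, 0]
    a_true = 1.0 - b_true - d_true
    comm_true = np.column_stack([b_true, d_true, a_true])
    noise = np.column_stack([
        cfg.sigma_b * rng.standard_normal(n),
        cfg.sigma_d * rng.standard_normal(n),
        cfg.sigma_a * rng.standard_normal(n),
    ])
    comm = np.clip(comm_true + noise, 1e-4, None)
    comm /= comm.sum(axis=1, keepdims=True)

    tsm = np.maximum(0.1, cfg.tsm_base + cfg.tsm_slope * f[:, 0] + cfg.sigma_tsm * rng.standard_normal(n))
    chla = np.maximum(0.05, cfg.chla_per_pb * sum_pb + cfg.sigma_chla * rng.standard_normal(n))

    ids = [f"s{i + 1:02d}" for i in range(n)]
    stations = pd.DataFrame({
        "station_id": ids,
        "lon": lon,
        "lat": lat,
        "depth_m": np.full(n, 5.0),
        "season": cfg.season,
        "temperature_C": T,
        "salinity": S,
        "nox_umolL": nox_meas,
        "dip_umolL": dip_meas,
        "tsm_mgL": tsm,
        "chla_ugL": chla,
        "brassicasterol_ngL": comm[:, 0] * sum_pb,
        "dinosterol_ngL": comm[:, 1] * sum_pb,
        "alkenones_ngL": comm[:, 2] * sum_pb,
    })

    truth = pd.DataFrame({
        "station_id": ids,
        "f_cdw_true": f[:, 0],
        "f_tsw_true": f[:, 1],
        "f_kssw_true": f[:, 2],
        "nox_init_true": nox_init,
        "dip_init_true": dip_init,
        "sum_pb_true": sum_pb_true,
        "b_frac_true": b_true,
        "d_frac_true": d_true,
        "a_frac_true": a_true,
        "subregion_true": [
            classify(*frac, cfg.thresholds).label for frac in f
        ],
    })
    return stations, truth


def recovery_report(truth: pd.DataFrame, estimated: pd.DataFrame) -> dict:
    """Score pipeline estimates against generator truth.

    Reports MAE/RMSE of the fractions, the subregion confusion matrix
    and label accuracy over stations the pipeline could solve.
    """
    if set(truth["station_id"]) != set(estimated["station_id"]):
        raise ValueError("station id mismatch between truth and estimates")
    merged = truth.merge(estimated, on="station_id")
    solv = merged[merged["in_triangle"]] if "in_triangle" in merged else merged

    out: dict = {"n_stations": int(len(merged)), "n_solvable": int(len(solv))}
    errors = {}
    for frac in ("f_cdw", "f_tsw", "f_kssw"):
        e = solv[frac] - solv[f"{frac}_true"]
        errors[frac] = {"mae": float(e.abs().mean()), "rmse": float(np.sqrt((e**2).mean()))}
    out["fraction_errors"] = errors
    out["fraction_mae"] = float(np.mean([errors[f]["mae"] for f in errors]))

    if "subregion" in solv:
        conf = pd.crosstab(solv["subregion_true"], solv["subregion"])
        agree = (solv["subregion_true"] == solv["subregion"]).mean()
        out["subregion_confusion"] = conf.to_dict()
        out["subregion_accuracy"] = float(agree)
    return out
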