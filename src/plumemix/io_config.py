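"""Station-table IO, pipeline configuration and the end-to-end driver.

The station table is a plain CSV (comma, UTF-8, "." decimal, mandatory
header, case-insensitive column names).  Missing cells are missing
values — never zero; a literal 0 in a biomarker column is a true
non-detect.  ``run_pipeline`` chains the stages: unmix -> preformed
nutrients -> community metrics -> subregion classification -> flux ->
statistics, and is a pure function of (table, config, seed).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import biomarkers, flux as flux_mod, nutrients, regionalization, stats as stats_mod
from .biomarkers import OutlierRule
from .endmember import EndMemberSet, MCMCConfig, bundled_endmembers, load_endmember_set, unmix_cruise
from .regionalization import RegionThresholds

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("station_id", "temperature_C", "salinity")

NUMERIC_COLUMNS = (
    "lon", "lat", "depth_m", "temperature_C", "salinity",
    "nox_umolL", "dip_umolL", "tsm_mgL", "chla_ugL",
    "brassicasterol_ngL", "dinosterol_ngL", "alkenones_ngL",
)

ALL_COLUMNS = ("station_id",) + NUMERIC_COLUMNS[:3] + ("season",) + NUMERIC_COLUMNS[3:]

_NON_NEGATIVE = NUMERIC_COLUMNS[5:]  # concentrations


@dataclass
class StationRecord:
    """One station's hydrographic, nutrient and biomarker measurements.

    Missing measurements are NaN (``None`` is accepted and normalized).
    """

    station_id: str
    temperature_C: float
    salinity: float
    lon: float = math.nan
    lat: float = math.nan
    depth_m: float = math.nan
    season: str = ""
    nox_umolL: float = math.nan
    dip_umolL: float = math.nan
    tsm_mgL: float = math.nan
    chla_ugL: float = math.nan
    brassicasterol_ngL: float = math.nan
    dinosterol_ngL: float = math.nan
    alkenones_ngL: float = math.nan

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name in ("station_id", "season"):
                continue
            v = getattr(self, f.name)
            setattr(self, f.name, math.nan if v is None else float(v))
        if not (-2 < self.temperature_C < 40):
            raise ValueError(f"station {self.station_id}: temperature {self.temperature_C} outside (-2, 40) degC")
        if not (0 < self.salinity < 41):
            raise ValueError(f"station {self.station_id}: salinity {self.salinity} outside (0, 41)")
        if not math.isnan(self.depth_m) and self.depth_m <= 0:
            raise ValueError(f"station {self.station_id}: depth must be > 0")
        for name in _NON_NEGATIVE:
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"station {self.station_id}: {name} = {v} is negative")


def read_station_table(path: str | Path) -> list[StationRecord]:
    """Read a station CSV into validated records, preserving row order.

    Column names are matched case-insensitively; unknown columns are
    ignored.  Empty cells become NaN.  A missing mandatory column or an
    unparsable numeric cell raises with the offending name / row number.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    lower_map = {c.lower(): c for c in raw.columns}
    canon = {name.lower(): name for name in ALL_COLUMNS}
    for col in MANDATORY_COLUMNS:
        if col.lower() not in lower_map:
            raise ValueError(f"missing mandatory column: {col}")

    records: list[StationRecord] = []
    for i, row in raw.iterrows():
        kwargs: dict[str, Any] = {}
        for low, name in canon.items():
            if low not in lower_map:
                continue
            cell = row[lower_map[low]]
            if name in ("station_id", "season"):
                kwargs[name] = "" if pd.isna(cell) else str(cell).strip()
            elif pd.isna(cell) or str(cell).strip() == "":
                kwargs[name] = math.nan
            else:
                try:
                    kwargs[name] = float(cell)
                except ValueError as exc:
                    raise ValueError(f"row {i + 2}: cannot parse {name}={cell!r}") from exc
        records.append(StationRecord(**kwargs))
    logger.info("read %d stations from %s", len(records), path)
    return records


def records_to_frame(records: Sequence[StationRecord]) -> pd.DataFrame:
    cols = list(ALL_COLUMNS)
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


def write_results_table(records: Sequence | pd.DataFrame, path: str | Path) -> None:
    """Write records (DataFrame, dataclasses or dicts) to CSV.

    Floats keep 6 significant digits; NaN serializes as an empty cell so
    a round trip restores missingness.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r) for r in records]
        df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.6g", na_rep="")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back an annotated results CSV (empty cells -> NaN)."""
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """Everything the pipeline needs besides the station table itself."""

    endmembers: EndMemberSet | str | Path | None = None
    season: str = "spring"
    method: str = "exact"                       # 'exact' or 'mcmc'
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    triangle_tol: float = 0.03
    thresholds: RegionThresholds = field(default_factory=RegionThresholds)
    dip_detection_limit: float = nutrients.DIP_DETECTION_LIMIT
    nox_anomaly_threshold: float = nutrients.NOX_ANOMALY_THRESHOLD
    dip_anomaly_threshold: float = nutrients.DIP_ANOMALY_THRESHOLD
    outlier_rule: OutlierRule = field(default_factory=OutlierRule)
    v_diatom: float = flux_mod.V_DIATOM
    v_dino: float = flux_mod.V_DINO
    flux_k: float = flux_mod.K_FLUX
    seed: int = 42

    def __post_init__(self) -> None:
        if self.triangle_tol < 0:
            raise ValueError("triangle_tol must be >= 0")

    def resolve_endmembers(self) -> EndMemberSet:
        if isinstance(self.endmembers, EndMemberSet):
            return self.endmembers
        if self.endmembers is None:
            return bundled_endmembers(self.season)
        return load_endmember_set(self.endmembers)


@dataclass
class PipelineResult:
    table: pd.DataFrame
    report: dict


def annotate_stations(records: Sequence[StationRecord], config: PipelineConfig) -> pd.DataFrame:
    """Per-station stages: unmixing, nutrients, biomarkers, subregion, flux."""
    ems = config.resolve_endmembers()
    df = records_to_frame(records)

    mcmc = dataclasses.replace(config.mcmc, seed=config.seed)
    results = unmix_cruise(records, ems, method=config.method, tol=config.triangle_tol, mcmc=mcmc)
    solvable = [r.in_triangle for r in results]
    if not any(solvable):
        raise ValueError("no solvable stations")

    for name, attr in (("f_cdw", "f_cdw"), ("f_tsw", "f_tsw"), ("f_kssw", "f_kssw"),
                       ("sd_cdw", "sd_cdw"), ("sd_tsw", "sd_tsw"), ("sd_kssw", "sd_kssw")):
        df[name] = [getattr(r, attr) if r.in_triangle else math.nan for r in results]
    df["in_triangle"] = solvable
    df["converged"] = [r.converged for r in results]

    # nutrients: floor measured DIP, then preformed values and anomalies
    df["dip_umolL"] = [
        nutrients.apply_dip_floor(v, config.dip_detection_limit) for v in df["dip_umolL"]
    ]
    nox_init, dip_init, np_init, np_meas, d_nox, d_dip, tags = [], [], [], [], [], [], []
    for r, row in zip(results, df.itertuples()):
        if not r.in_triangle:
            for lst in (nox_init, dip_init, np_init, np_meas, d_nox, d_dip):
                lst.append(math.nan)
            tags.append("")
            continue
        pre = nutrients.preformed_concentration(r, ems)
        nox_init.append(pre.nox_init)
        dip_init.append(pre.dip_init)
        np_init.append(pre.np_init)
        np_meas.append(
            nutrients.np_ratio(row.nox_umolL, row.dip_umolL)
            if not (math.isnan(row.nox_umolL) or math.isnan(row.dip_umolL) or row.dip_umolL == 0)
            else math.nan
        )
        if math.isnan(row.nox_umolL) or math.isnan(row.dip_umolL):
            d_nox.append(math.nan)
            d_dip.append(math.nan)
            tags.append("")
        else:
            an = nutrients.nutrient_anomaly(
                row.nox_umolL, row.dip_umolL, pre,
                config.nox_anomaly_threshold, config.dip_anomaly_threshold,
            )
            d_nox.append(an.d_nox)
            d_dip.append(an.d_dip)
            tags.append(an.tag)
    df["nox_init"], df["dip_init"], df["np_init"] = nox_init, dip_init, np_init
    df["np_measured"] = np_meas
    df["d_nox"], df["d_dip"], df["anomaly_tag"] = d_nox, d_dip, tags

    # biomarkers
    cms = [
        biomarkers.community_metrics(b, d, a)
        for b, d, a in zip(df["brassicasterol_ngL"], df["dinosterol_ngL"], df["alkenones_ngL"])
    ]
    df["sum_pb"] = [c.sum_pb for c in cms]
    df["b_frac"] = [c.b_frac for c in cms]
    df["d_frac"] = [c.d_frac for c in cms]
    df["a_frac"] = [c.a_frac for c in cms]
    df["outlier_flag"] = biomarkers.flag_outliers(df, config.outlier_rule)

    # subregions (solvable stations only)
    labels, rules = [], []
    for r in results:
        if not r.in_triangle:
            labels.append(None)
            rules.append("")
            continue
        lab = regionalization.classify(r.f_cdw, r.f_tsw, r.f_kssw, config.thresholds)
        labels.append(lab.label)
        rules.append(lab.rule_applied)
    df["subregion"] = labels
    df["rule_applied"] = rules

    # flux
    fe = [
        flux_mod.lipid_flux(b, d, config.v_diatom, config.v_dino, config.flux_k)
        if not (math.isnan(b) or math.isnan(d))
        else flux_mod.FluxEstimate(math.nan, math.nan, math.nan, config.v_diatom, config.v_dino, config.flux_k)
        for b, d in zip(df["brassicasterol_ngL"], df["dinosterol_ngL"])
    ]
    df["flux_diatom"] = [f.flux_diatom for f in fe]
    df["flux_dino"] = [f.flux_dino for f in fe]
    df["flux_total"] = [f.flux_total for f in fe]
    return df


def _regression_mask(df: pd.DataFrame) -> pd.Series:
    """Stations entering fraction-response regressions: solvable, not
    TSW-dominated, not flagged outliers, with community data."""
    return (
        df["in_triangle"]
        & (df["subregion"] != "TSWR")
        & ~df["outlier_flag"]
        & df["b_frac"].notna()
    )


def _fit_to_dict(fit: stats_mod.ModelFit) -> dict:
    return {
        "model": fit.model,
        "coefficients": [float(c) for c in fit.coefficients],
        "r2": fit.r2,
        "rmse": fit.rmse,
        "p_value": fit.p_value,
        "slope_ci95": [float(v) for v in fit.slope_ci95()],
        "selection_conflict": fit.selection_conflict,
    }


def build_report(df: pd.DataFrame, config: PipelineConfig) -> dict:
    """Summary statistics, regression selections, group tests and RDA."""
    report: dict = {
        "n_stations": int(len(df)),
        "n_excluded_triangle": int((~df["in_triangle"]).sum()),
        "n_outlier_flagged": int(df["outlier_flag"].sum()),
        "mean_posterior_sd": {
            "f_cdw": float(df.loc[df["in_triangle"], "sd_cdw"].mean()),
            "f_tsw": float(df.loc[df["in_triangle"], "sd_tsw"].mean()),
            "f_kssw": float(df.loc[df["in_triangle"], "sd_kssw"].mean()),
        },
    }

    summary = regionalization.subregion_summary(df[df["in_triangle"]])
    report["subregion_summary"] = summary.to_dict(orient="records")
    report["subregion_flux"] = flux_mod.subregion_flux(df[df["in_triangle"]]).to_dict(orient="records")

    mask = _regression_mask(df)
    sub = df[mask]
    regressions = {}
    for resp in ("sum_pb", "b_frac", "d_frac", "a_frac"):
        for pred in ("f_cdw", "f_kssw"):
            data = sub[[pred, resp]].dropna()
            if len(data) >= 4 and np.ptp(data[pred].to_numpy()) > 0:
                fit = stats_mod.select_regression(data[pred], data[resp])
                regressions[f"{resp}_vs_{pred}"] = _fit_to_dict(fit)
    report["regressions"] = regressions

    corr = {}
    for meas, init in (("nox_umolL", "nox_init"), ("dip_umolL", "dip_init")):
        data = df.loc[df["in_triangle"], [meas, init]].dropna()
        if len(data) >= 3:
            rho, p = stats_mod.spearman(data[init], data[meas])
            corr[f"{meas}_vs_{init}"] = {"rho": rho, "p_value": p}
    report["spearman"] = corr

    # subregion group tests on the biomass/community variables
    tests: dict = {}
    grouped = df[df["in_triangle"] & df["subregion"].isin(("CDWR", "C_KMR", "KSSWR"))]
    for var in ("sum_pb", "b_frac", "d_frac", "a_frac"):
        groups = [g[var].dropna().to_numpy() for _, g in grouped.groupby("subregion") if g[var].notna().sum() >= 2]
        if len(groups) >= 2 and sum(len(g) for g in groups) >= 3:
            entry: dict = {}
            try:
                entry["shapiro_p"] = [stats_mod.shapiro_wilk(g).p_value for g in groups if 3 <= len(g) <= 5000]
                entry["levene_p"] = stats_mod.levene(groups).p_value
            except ValueError:
                pass
            kw = stats_mod.kruskal_wallis(groups)
            entry.update({"kw_statistic": kw.statistic, "kw_p": kw.p_value, "group_ns": list(kw.group_ns)})
            tests[var] = entry
    report["group_tests"] = tests

    # RDA of biomarker responses on hydrographic predictors
    resp_cols = ["sum_pb", "b_frac", "d_frac", "a_frac"]
    expl_cols = ["temperature_C", "salinity", "f_cdw", "f_kssw", "nox_umolL", "dip_umolL", "tsm_mgL", "chla_ugL"]
    rda_input = df.loc[df["in_triangle"], resp_cols + expl_cols].dropna()
    if len(rda_input) > len(expl_cols) + 1:
        r = stats_mod.rda(rda_input[resp_cols], rda_input[expl_cols])
        report["rda"] = {
            "constrained_fraction": r.constrained_fraction,
            "axis_fractions": [float(a) for a in r.axis_fractions],
            "top_contributors": list(r.contributions.index[:2]),
            "contributions": {k: float(v) for k, v in r.contributions.items()},
            "n_used": r.n_used,
        }
    return report


def run_pipeline(
    stations: str | Path | Sequence[StationRecord], config: PipelineConfig | None = None
) -> PipelineResult:
    """Run every stage on a station table (path or records).

    Deterministic for a fixed (table, config, seed).
    """
    config = config or PipelineConfig()
    records = read_station_table(stations) if isinstance(stations, (str, Path)) else list(stations)
    logger.info("pipeline start: %d stations, season=%s, method=%s", len(records), config.season, config.method)
    table = annotate_stations(records, config)
    report = build_report(table, config)
    logger.info(
        "pipeline done: %d solvable, %d excluded", int(table["in_triangle"].sum()),
        int((~table["in_triangle"]).sum()),
    )
    return PipelineResult(table=table, report=report)
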