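"""Three end-member water-mass mixing from temperature and salinity.

A coastal surface sample is modelled as a conservative mixture of three
water masses — Changjiang Diluted Water (CDW), Taiwan Strait Water (TSW)
and Kuroshio Subsurface Water (KSSW) — whose characteristic temperature
and salinity define the vertices of a mixing triangle on the T–S plane.
The mixing fractions ``(f_cdw, f_tsw, f_kssw)`` solve

    f1 + f2 + f3 = 1
    f1*T1 + f2*T2 + f3*T3 = T_obs
    f1*S1 + f2*S2 + f3*S3 = S_obs

i.e. they are the barycentric coordinates of the observation in the
end-member triangle.  Two solvers are provided:

* :func:`solve_exact` — the unique linear-algebra solution, no
  uncertainty.
* :func:`solve_bayesian` — a random-walk Metropolis sampler over the
  probability simplex with a flat Dirichlet(1,1,1) prior, Gaussian
  observation error on T and S, and Gaussian uncertainty on the
  end-member T/S values (Table-style mean ± SD).  Because the model is
  linear-Gaussian in the end-member values for fixed fractions, those
  nuisance parameters are marginalized in closed form: the likelihood
  variance becomes ``sigma_obs**2 + sum(f_i**2 * sigma_i**2)``, leaving
  a 2-D posterior over the softmax-transformed simplex.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

WATER_MASSES = ("CDW", "TSW", "KSSW")

__all__ = [
    "WATER_MASSES",
    "EndMember",
    "EndMemberSet",
    "MixingResult",
    "MCMCConfig",
    "load_endmember_set",
    "bundled_endmembers",
    "barycentric_coordinates",
    "solve_exact",
    "in_mixing_triangle",
    "solve_bayesian",
    "unmix_cruise",
    "mean_posterior_sd",
]


@dataclass(frozen=True)
class EndMember:
    """One water mass: T/S mean ± SD plus its nutrient signature."""

    name: str
    temperature_C: float
    temperature_sd: float
    salinity: float
    salinity_sd: float
    nox_umolL: float
    dip_umolL: float
    layer: str = "surface"
    season: str = "spring"
    source_station: str = ""
    lon: float | None = None
    lat: float | None = None
    depth_m: float | None = None

    def __post_init__(self) -> None:
        if self.name not in WATER_MASSES:
            raise ValueError(f"unknown water mass {self.name!r}; expected one of {WATER_MASSES}")
        if self.temperature_sd <= 0 or self.salinity_sd <= 0:
            raise ValueError(f"end-member {self.name}: SDs must be > 0")
        if self.nox_umolL < 0 or self.dip_umolL < 0:
            raise ValueError(f"end-member {self.name}: nutrient values must be >= 0")


@dataclass(frozen=True)
class EndMemberSet:
    """The three end-members (CDW, TSW, KSSW order) for one season/layer."""

    members: tuple[EndMember, EndMember, EndMember]
    season: str = "spring"

    def __post_init__(self) -> None:
        names = tuple(m.name for m in self.members)
        if sorted(names) != sorted(WATER_MASSES):
            raise ValueError(f"need exactly one of each {WATER_MASSES}, got {names}")
        # keep canonical CDW, TSW, KSSW order
        ordered = tuple(sorted(self.members, key=lambda m: WATER_MASSES.index(m.name)))
        object.__setattr__(self, "members", ordered)
        if abs(self.triangle_area()) <= 1e-6:
            raise ValueError("collinear end-members: T-S triangle is degenerate")

    def __getitem__(self, name: str) -> EndMember:
        for m in self.members:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def T(self) -> np.ndarray:
        return np.array([m.temperature_C for m in self.members])

    @property
    def S(self) -> np.ndarray:
        return np.array([m.salinity for m in self.members])

    @property
    def T_sd(self) -> np.ndarray:
        return np.array([m.temperature_sd for m in self.members])

    @property
    def S_sd(self) -> np.ndarray:
        return np.array([m.salinity_sd for m in self.members])

    @property
    def nox(self) -> np.ndarray:
        return np.array([m.nox_umolL for m in self.members])

    @property
    def dip(self) -> np.ndarray:
        return np.array([m.dip_umolL for m in self.members])

    def triangle_area(self) -> float:
        """Signed area of the end-member triangle in (degC x salinity) units."""
        t, s = [m.temperature_C for m in self.members], [m.salinity for m in self.members]
        return 0.5 * ((t[1] - t[0]) * (s[2] - s[0]) - (t[2] - t[0]) * (s[1] - s[0]))

    def with_inflated_sds(self, factor: float) -> "EndMemberSet":
        """Copy with all end-member T/S SDs multiplied by ``factor``."""
        members = tuple(
            replace(m, temperature_sd=m.temperature_sd * factor, salinity_sd=m.salinity_sd * factor)
            for m in self.members
        )
        return EndMemberSet(members=members, season=self.season)


@dataclass
class MixingResult:
    """Water-mass fractions for one station, with posterior SDs if sampled."""

    f_cdw: float
    f_tsw: float
    f_kssw: float
    sd_cdw: float = 0.0
    sd_tsw: float = 0.0
    sd_kssw: float = 0.0
    in_triangle: bool = True
    converged: bool = True
    method: str = "exact"

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.f_cdw, self.f_tsw, self.f_kssw])

    @property
    def sds(self) -> np.ndarray:
        return np.array([self.sd_cdw, self.sd_tsw, self.sd_kssw])


@dataclass
class MCMCConfig:
    """Random-walk Metropolis settings for :func:`solve_bayesian`.

    ``sigma_T_obs``/``sigma_S_obs`` are the Gaussian observation-error
    SDs on temperature (degC) and salinity; summer surface temperature is
    less conservative (direct heating), so a larger ``sigma_T_obs`` can
    be configured for summer scenarios.
    """

    n_chains: int = 4
    n_iter: int = 5000
    burn_in: int = 1000
    seed: int = 42
    sigma_T_obs: float = 0.05
    sigma_S_obs: float = 0.05
    step_size: float = 1.7          # ~2.4/sqrt(d) for the shaped 2-D proposal
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in or self.burn_in < 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


# ---------------------------------------------------------------------------
# end-member configuration files

_EM_KEYS = {"name", "season", "layer", "T_mean", "T_sd", "S_mean", "S_sd", "NOx", "DIP"}


def _member_from_dict(d: dict) -> EndMember:
    missing = _EM_KEYS - d.keys()
    if missing:
        raise ValueError(f"end-member entry missing keys: {sorted(missing)}")
    return EndMember(
        name=d["name"],
        season=d["season"],
        layer=d["layer"],
        temperature_C=float(d["T_mean"]),
        temperature_sd=float(d["T_sd"]),
        salinity=float(d["S_mean"]),
        salinity_sd=float(d["S_sd"]),
        nox_umolL=float(d["NOx"]),
        dip_umolL=float(d["DIP"]),
        source_station=str(d.get("station", "")),
        lon=d.get("lon"),
        lat=d.get("lat"),
        depth_m=d.get("depth"),
    )


def load_endmember_set(path: str | Path) -> EndMemberSet:
    """Read an end-member set from a YAML or JSON file.

    The file holds ``season`` and a three-entry ``members`` list with keys
    name/season/layer/T_mean/T_sd/S_mean/S_sd/NOx/DIP (+ optional
    station/lon/lat/depth).
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    members = tuple(_member_from_dict(d) for d in data["members"])
    return EndMemberSet(members=members, season=data.get("season", members[0].season))


def bundled_endmembers(season: str, layer: str = "surface") -> EndMemberSet:
    """Load the packaged end-member set for ``season`` ('spring'/'summer')."""
    if season not in ("spring", "summer"):
        raise ValueError(f"season must be 'spring' or 'summer', got {season!r}")
    if layer != "surface":
        raise ValueError("only surface end-member sets are bundled; pass a config file for other layers")
    ref = resources.files("plumemix.data").joinpath(f"endmembers_{season}_surface.yaml")
    data = yaml.safe_load(ref.read_text())
    members = tuple(_member_from_dict(d) for d in data["members"])
    return EndMemberSet(members=members, season=data["season"])


# ---------------------------------------------------------------------------
# exact solver

def barycentric_coordinates(temperature_C: float, salinity: float, ems: EndMemberSet) -> np.ndarray:
    """Raw (possibly negative) barycentric coordinates of (T, S)."""
    A = np.vstack([np.ones(3), ems.T, ems.S])
    b = np.array([1.0, temperature_C, salinity])
    return np.linalg.solve(A, b)


def in_mixing_triangle(
    temperature_C: float, salinity: float, ems: EndMemberSet, tol: float = 0.03
) -> bool:
    """True iff every barycentric coordinate lies in [-tol, 1 + tol].

    Stations outside the end-member ranges (beyond ``tol``) are excluded
    from the mixing analysis.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    f = barycentric_coordinates(temperature_C, salinity, ems)
    eps = 1e-9  # float slack so exact vertices pass at tol = 0
    return bool(np.all(f >= -tol - eps) and np.all(f <= 1 + tol + eps))


def solve_exact(
    temperature_C: float, salinity: float, ems: EndMemberSet, tol: float = 0.03
) -> MixingResult:
    """Unique mixing-fraction solution from end-member means.

    Within ``tol`` of the triangle, small negative fractions are clipped
    to [0, 1] and the triple renormalized to sum to one.  Outside, the
    raw barycentric coordinates are returned with ``in_triangle=False``
    so the caller can log why the station is excluded.
    """
    f = barycentric_coordinates(temperature_C, salinity, ems)
    eps = 1e-9
    inside = bool(np.all(f >= -tol - eps) and np.all(f <= 1 + tol + eps))
    if inside:
        f = np.clip(f, 0.0, 1.0)
        f = f / f.sum()
    return MixingResult(
        f_cdw=float(f[0]), f_tsw=float(f[1]), f_kssw=float(f[2]),
        in_triangle=inside, converged=True, method="exact",
    )


# ---------------------------------------------------------------------------
# Bayesian sampler

def _softmax3(z: np.ndarray) -> np.ndarray:
    """Map (k, 2) chain states to (k, 3) simplex points (third logit 0)."""
    logits = np.concatenate([z, np.zeros((z.shape[0], 1))], axis=1)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def _log_post(z: np.ndarray, T_obs: float, S_obs: float, ems: EndMemberSet, cfg: MCMCConfig) -> np.ndarray:
    """Marginal log-posterior over fractions for each chain state (k, 2)."""
    f = _softmax3(z)
    # flat Dirichlet prior on f + softmax Jacobian = sum(log f_i)
    lp = np.sum(np.log(np.maximum(f, 1e-300)), axis=1)
    var_T = cfg.sigma_T_obs**2 + f**2 @ ems.T_sd**2
    var_S = cfg.sigma_S_obs**2 + f**2 @ ems.S_sd**2
    lp -= 0.5 * ((T_obs - f @ ems.T) ** 2 / var_T + np.log(var_T))
    lp -= 0.5 * ((S_obs - f @ ems.S) ** 2 / var_S + np.log(var_S))
    return lp


def _proposal_shape(z0: np.ndarray, T_obs: float, S_obs: float, ems: EndMemberSet, cfg: MCMCConfig) -> np.ndarray:
    """Cholesky factor of the inverse log-posterior Hessian at the mode
    (identity fallback when the curvature is not positive definite)."""
    h = 1e-4
    H = np.empty((2, 2))

    def lp(z):
        return float(_log_post(z[np.newaxis, :], T_obs, S_obs, ems, cfg)[0])

    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h
            ej = np.eye(2)[j] * h
            H[i, j] = (lp(z0 + ei + ej) - lp(z0 + ei - ej) - lp(z0 - ei + ej) + lp(z0 - ei - ej)) / (4 * h * h)
    try:
        cov = np.linalg.inv(-H)
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return np.eye(2)


def _rhat(samples: np.ndarray) -> float:
    """Gelman–Rubin potential-scale-reduction for (chains, draws) samples."""
    m, n = samples.shape
    if m < 2:
        return 1.0
    chain_means = samples.mean(axis=1)
    chain_vars = samples.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(math.sqrt(var_hat / W))


def solve_bayesian(
    temperature_C: float,
    salinity: float,
    ems: EndMemberSet,
    cfg: MCMCConfig | None = None,
) -> MixingResult:
    """Posterior water-mass fractions by random-walk Metropolis.

    The chain lives on the 2-D softmax transform of the simplex; the
    Gaussian end-member nuisances are integrated out analytically, so
    the target is the exact marginal posterior of the fractions.
    Convergence is declared when the Gelman–Rubin statistic is below
    ``cfg.rhat_threshold`` for all three fractions; a non-converged run
    still returns its posterior summaries, flagged ``converged=False``.
    """
    cfg = cfg or MCMCConfig()
    rng = np.random.default_rng(cfg.seed)

    # start chains near the exact solution, jittered
    f0 = solve_exact(temperature_C, salinity, ems, tol=1.0).fractions
    f0 = np.clip(f0, 1e-3, None)
    f0 /= f0.sum()
    z0 = np.log(f0[:2] / f0[2])

    # Laplace-shaped proposal: the posterior is strongly anisotropic in
    # softmax space near the simplex edges, so scale the random walk by
    # the inverse Hessian of the log-posterior at the mode
    L = _proposal_shape(z0, temperature_C, salinity, ems, cfg)
    z = z0 + 0.5 * rng.standard_normal((cfg.n_chains, 2)) @ L.T

    lp = _log_post(z, temperature_C, salinity, ems, cfg)
    kept = cfg.n_iter - cfg.burn_in
    samples = np.empty((cfg.n_chains, kept, 3))
    step = cfg.step_size
    accepted_window = 0
    for it in range(cfg.n_iter):
        prop = z + step * rng.standard_normal((cfg.n_chains, 2)) @ L.T
        lp_prop = _log_post(prop, temperature_C, salinity, ems, cfg)
        accept = np.log(rng.random(cfg.n_chains)) < lp_prop - lp
        z[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        if it < cfg.burn_in:
            # adapt toward ~30% acceptance during burn-in only, so the
            # kept samples come from a fixed-step chain
            accepted_window += int(accept.sum())
            if (it + 1) % 100 == 0:
                rate = accepted_window / (100 * cfg.n_chains)
                step *= math.exp(rate - 0.3)
                accepted_window = 0
        else:
            samples[:, it - cfg.burn_in, :] = _softmax3(z)

    flat = samples.reshape(-1, 3)
    mean, sd = flat.mean(axis=0), flat.std(axis=0, ddof=1)
    rhats = [_rhat(samples[:, :, i]) for i in range(3)]
    converged = all(r < cfg.rhat_threshold for r in rhats)
    if not converged:
        logger.warning(
            "MCMC not converged at (T=%.3f, S=%.3f): R-hat=%s", temperature_C, salinity,
            [round(r, 3) for r in rhats],
        )
    return MixingResult(
        f_cdw=float(mean[0]), f_tsw=float(mean[1]), f_kssw=float(mean[2]),
        sd_cdw=float(sd[0]), sd_tsw=float(sd[1]), sd_kssw=float(sd[2]),
        in_triangle=True, converged=converged, method="mcmc",
    )


# ---------------------------------------------------------------------------
# cruise-level driver

def unmix_cruise(
    records: Sequence,
    ems: EndMemberSet,
    method: str = "exact",
    tol: float = 0.03,
    mcmc: MCMCConfig | None = None,
) -> list[MixingResult]:
    """Solve the mixing model for every station of a cruise.

    ``records`` may be StationRecord-like objects (with ``temperature_C``
    and ``salinity`` attributes) or (T, S) pairs.  Stations outside the
    mixing triangle at tolerance ``tol`` are returned with
    ``in_triangle=False`` and are never silently dropped.  For the MCMC
    method each station gets a distinct, deterministic seed derived from
    ``mcmc.seed``.
    """
    if len(records) == 0:
        raise ValueError("no stations to unmix")
    if method not in ("exact", "mcmc"):
        raise ValueError(f"unknown method {method!r}")
    mcmc = mcmc or MCMCConfig()
    results: list[MixingResult] = []
    n_excluded = 0
    for i, rec in enumerate(records):
        if hasattr(rec, "temperature_C"):
            T, S = rec.temperature_C, rec.salinity
        else:
            T, S = rec
        exact = solve_exact(T, S, ems, tol=tol)
        if not exact.in_triangle:
            n_excluded += 1
            sid = getattr(rec, "station_id", f"#{i}")
            logger.warning("station %s excluded: (T=%.3f, S=%.3f) outside mixing triangle", sid, T, S)
            results.append(exact)
            continue
        if method == "exact":
            results.append(exact)
        else:
            station_cfg = replace(mcmc, seed=(mcmc.seed + 1009 * i) % (2**31 - 1))
            results.append(solve_bayesian(T, S, ems, station_cfg))
    logger.info("unmixed %d stations (%d excluded) with method=%s", len(records), n_excluded, method)
    return results


def mean_posterior_sd(results: Iterable[MixingResult]) -> np.ndarray | None:
    """Mean posterior SD per fraction over solvable stations (None if none)."""
    sds = [r.sds for r in results if r.in_triangle]
    if not sds:
        return None
    return np.mean(sds, axis=0)
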