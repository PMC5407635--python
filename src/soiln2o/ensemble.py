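"""Monte-Carlo propagation of input uncertainty through the simulator.

Two inputs are perturbed, mirroring the uncertainty treatment of the
point-scale assessment: the mineral-N fertilization amounts (multiplier
PDF with mean 1 and *variance* 0.2) and the initial passive:total SOC
ratio (multiplier PDF with mean 1 and *standard deviation* 0.2).  The
asymmetry between the two dispersion conventions is deliberate and kept
as stated; both are configurable.

The default multiplier family is a normal truncated below at 0.01 (no
negative fertilizer), with the pre-truncation parameters adjusted so the
*post-truncation* mean and dispersion match the stated values exactly.
A log-normal family (naturally positive, closed-form moment match) is
available as an alternative.

Each replicate's multipliers are drawn from a stream keyed by (master
seed, point id, replicate index), so ensemble results are independent of
execution order and batch composition.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import optimize
from scipy.stats import truncnorm

from .derive import DerivedInputs
from .params import CropParams, SimParams
from .simulate import SimulationError, run_batch
from .synthgen import SoilPoint, WeatherSeries

__all__ = [
    "MultiplierSet", "EnsembleSummary", "RunLedger",
    "sample_multipliers", "run_ensemble", "summarize_distribution",
]


class EnsembleError(RuntimeError):
    pass


@dataclass(frozen=True)
class MultiplierSet:
    replicate: int
    fert_multiplier: float
    ptr_multiplier: float

    def __post_init__(self) -> None:
        if self.fert_multiplier <= 0 or self.ptr_multiplier <= 0:
            raise ValueError("multipliers must be positive")


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-point statistics over the replicate annual N2O-N fluxes."""

    point_id: str
    n_reps: int
    mean: float
    median: float
    sd: float
    q1: float
    q3: float

    @property
    def two_sigma(self) -> float:
        return 2.0 * self.sd

    @property
    def cv(self) -> float:
        return self.sd / self.mean if self.mean > 0 else float("nan")

    def validate(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles out of order")
        if self.sd < 0:
            raise ValueError("negative sd")


@dataclass
class RunLedger:
    """Exact bookkeeping of simulator invocations (one per batch element)."""

    runs: int = 0
    points: int = 0

    def record(self, n_runs: int, n_points: int = 1) -> None:
        self.runs += int(n_runs)
        self.points += int(n_points)

    @staticmethod
    def planned(n_points: int, n_reps: int) -> int:
        return int(n_points) * int(n_reps)


# ---------------------------------------------------------------------------
# Multiplier sampling
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _truncnorm_params(mean: float, sd: float, lower: float
                      ) -> tuple[float, float]:
    """Pre-truncation (mu, sigma) whose lower-truncated normal has the
    requested post-truncation mean and sd."""

    def moments(x):
        mu, sigma = x
        sigma = abs(sigma)
        a = (lower - mu) / sigma
        m, v = truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.fsolve(moments, x0=[mean, sd], full_output=False,
                          xtol=1e-13)
    mu, sigma = float(sol[0]), abs(float(sol[1]))
    resid = moments((mu, sigma))
    if max(abs(r) for r in resid) > 1e-8:
        raise EnsembleError(
            f"truncated-normal moment match failed for mean={mean}, sd={sd}")
    return mu, sigma


def sample_multipliers(n: int, mean: float = 1.0, dispersion: float = 0.2,
                       dispersion_kind: str = "variance", seed: int = 0,
                       family: str = "truncnorm",
                       lower: float = 0.01) -> np.ndarray:
    """Draw ``n`` positive multipliers with exact stated moments.

    ``dispersion_kind`` selects whether ``dispersion`` is a variance or
    a standard deviation.  The truncated-normal family corrects its
    pre-truncation parameters so the realized (post-truncation) moments
    match; the log-normal family matches in closed form.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion_kind == "variance":
        sd = float(np.sqrt(dispersion))
    elif dispersion_kind == "sd":
        sd = float(dispersion)
    else:
        raise ValueError(f"unknown dispersion_kind {dispersion_kind!r} "
                         "(expected 'variance' or 'sd')")
    if sd == 0.0:
        return np.full(n, mean)
    rng = np.random.default_rng(seed)
    if family == "truncnorm":
        mu, sigma = _truncnorm_params(mean, sd, lower)
        a = (lower - mu) / sigma
        u = rng.random(n)
        return truncnorm.ppf(u, a, np.inf, loc=mu, scale=sigma)
    if family == "lognormal":
        s2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - s2 / 2.0
        return rng.lognormal(mu, np.sqrt(s2), n)
    raise ValueError(f"unknown multiplier family {family!r}")


def _point_seed(master_seed: int, point_id: str, stream: int) -> list[int]:
    return [int(master_seed) & 0x7FFFFFFF,
            zlib.crc32(point_id.encode()) & 0x7FFFFFFF, stream]


def replicate_multipliers(point_id: str, n_reps: int, seed: int,
                          fert_dispersion: float = 0.2,
                          fert_kind: str = "variance",
                          ptr_dispersion: float = 0.2,
                          ptr_kind: str = "sd",
                          family: str = "truncnorm") -> list[MultiplierSet]:
    """The deterministic multiplier table for one point's ensemble."""
    fm = sample_multipliers(n_reps, 1.0, fert_dispersion, fert_kind,
                            seed=_point_seed(seed, point_id, 1), family=family)
    pm = sample_multipliers(n_reps, 1.0, ptr_dispersion, ptr_kind,
                            seed=_point_seed(seed, point_id, 2), family=family)
    return [MultiplierSet(r, float(fm[r]), float(pm[r]))
            for r in range(n_reps)]


# ---------------------------------------------------------------------------
# Ensemble execution
# ---------------------------------------------------------------------------

def summarize_distribution(values) -> tuple[float, float, float, float, float]:
    """(mean, median, q1, q3, sd) with linear-interpolation quantiles and
    sample (n-1) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return float(v.mean()), float(med), float(q1), float(q3), sd


def run_ensemble(point: SoilPoint, derived: DerivedInputs,
                 weather: WeatherSeries,
                 params: SimParams | None = None,
                 n_reps: int = 50, seed: int = 0,
                 fert_dispersion: float = 0.2, fert_kind: str = "variance",
                 ptr_dispersion: float = 0.2, ptr_kind: str = "sd",
                 family: str = "truncnorm",
                 calendar: dict[str, CropParams] | None = None,
                 spinup_years: int = 1,
                 ledger: RunLedger | None = None,
                 return_values: bool = False):
    """Run ``n_reps`` perturbed simulations of one point and summarize.

    Replicate r scales every mineral-N event by its fertilizer
    multiplier and the initial passive:total ratio by its PTR multiplier
    (clamped inside (0, 1)); the per-replicate annual flux is the mean
    over post-spin-up years.  All replicates advance together as one
    batch, which is bit-identical to running them one at a time.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    params = params or SimParams()
    mults = replicate_multipliers(point.point_id, n_reps, seed,
                                  fert_dispersion, fert_kind,
                                  ptr_dispersion, ptr_kind, family)
    derived_reps = [replace(derived,
                            ptr=float(np.clip(derived.ptr * m.ptr_multiplier,
                                              1e-3, 0.999)))
                    for m in mults]
    fmul = np.array([m.fert_multiplier for m in mults])
    try:
        res = run_batch(derived_reps, [weather] * n_reps, params, calendar,
                        clay=np.full(n_reps, point.clay),
                        ph=np.full(n_reps, point.ph),
                        fert_multipliers=fmul)
    except SimulationError as exc:
        bad = _find_failing_replicate(derived_reps, weather, params, calendar,
                                      point, fmul)
        m = mults[bad] if bad is not None else None
        raise EnsembleError(
            f"replicate {bad} of point {point.point_id} failed "
            f"(multipliers {m}): {exc}") from exc
    if ledger is not None:
        ledger.record(res.n_runs, n_points=1)

    annual = res.annual_n2o[spinup_years:].mean(axis=0)   # (n_reps,)
    mean, med, q1, q3, sd = summarize_distribution(annual)
    summ = EnsembleSummary(point_id=point.point_id, n_reps=n_reps,
                           mean=mean, median=med, sd=sd, q1=q1, q3=q3)
    summ.validate()
    if return_values:
        return summ, annual
    return summ


def _find_failing_replicate(derived_reps, weather, params, calendar, point,
                            fmul) -> int | None:
    for r, d in enumerate(derived_reps):
        try:
            run_batch([d], [weather], params, calendar,
                      clay=np.array([point.clay]), ph=np.array([point.ph]),
                      fert_multipliers=fmul[r:r + 1])
        except SimulationError:
            return r
    return None
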