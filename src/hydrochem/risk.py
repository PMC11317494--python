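"""USEPA non-carcinogenic health risk for drinking-water ingestion.

Chronic daily intake for the oral route,

    CDI = C·IR·ED / (BW·AT) · EF        [mg/kg/day]

with cohort defaults: adults IR 2.2 L/d, ED 70 y, BW 70 kg, AT 25550 d;
children IR 1.8 L/d, ED 6 y, BW 15 kg, AT 2190 d; EF 350 d/y for both.
Hazard quotient HQ = CDI/RfD and hazard index HI = Σ HQ, with 1 as the
safety threshold.  Because ED·365 = AT for both cohorts, CDI is linear in C
with per-unit-concentration coefficients 0.030137 (adult) and 0.11507
(child); the child:adult HQ ratio at equal concentration is therefore
exactly (1.8/15)/(2.2/70) ≈ 3.82.

The Monte Carlo layer propagates uncertainty in concentration and in the
exposure factors through the same equations, drawing from truncated-normal
(or lognormal) distributions and summarising the HQ distribution.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, UndefinedQuantityError, ValidationError

#: Oral reference doses, mg/kg/day.
DEFAULT_RFD: Mapping[str, float] = MappingProxyType({"Mn": 0.024, "Fe": 0.7, "NO3": 1.6})

RISK_ELEMENTS = tuple(DEFAULT_RFD)
COHORTS = ("adult", "child")


@dataclass(frozen=True)
class ExposureParams:
    cohort: str
    ir: float      # intake rate, L/day
    ed: float      # exposure duration, years
    bw: float      # body weight, kg
    ef: float      # exposure frequency, days/year
    at_nc: float   # averaging time (non-carcinogenic), days

    def __post_init__(self):
        for name in ("ir", "ed", "bw", "ef", "at_nc"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")

    @classmethod
    def default(cls, cohort: str) -> "ExposureParams":
        if cohort == "adult":
            return cls(cohort="adult", ir=2.2, ed=70.0, bw=70.0, ef=350.0, at_nc=25550.0)
        if cohort == "child":
            return cls(cohort="child", ir=1.8, ed=6.0, bw=15.0, ef=350.0, at_nc=2190.0)
        raise ConfigError(f"unknown cohort {cohort!r}")


@dataclass(frozen=True)
class RfdTable:
    rfd: Mapping[str, float] = field(default_factory=lambda: DEFAULT_RFD)

    def __post_init__(self):
        for el, v in self.rfd.items():
            if v <= 0:
                raise ConfigError(f"RfD for {el} must be positive, got {v}")

    def __getitem__(self, element: str) -> float:
        try:
            return self.rfd[element]
        except KeyError:
            raise ConfigError(f"no oral RfD registered for element {element!r}") from None


@dataclass(frozen=True)
class RiskResult:
    cohort: str
    cdi: Mapping[str, float]
    hq: Mapping[str, float]
    hi: float
    at_risk: bool


def cdi_oral(c: float, params: ExposureParams) -> float:
    """Chronic daily intake, mg/kg/day, for concentration ``c`` in mg/L."""
    if c < 0:
        raise ValidationError(f"negative concentration {c}")
    return c * params.ir * params.ed / (params.bw * params.at_nc) * params.ef


def hq_oral(c: float, element: str, params: ExposureParams,
            rfd: RfdTable | None = None) -> float:
    """Hazard quotient HQ = CDI/RfD for one element."""
    return cdi_oral(c, params) / (rfd or RfdTable())[element]


def hazard_index(hqs: Mapping[str, float]) -> tuple[float, bool]:
    """HI = Σ HQ and the HI > 1 at-risk flag."""
    if not hqs:
        raise UndefinedQuantityError("hazard index of an empty HQ set")
    hi = float(sum(hqs.values()))
    return hi, hi > 1.0


def risk_assessment(concentrations: Mapping[str, float], cohort: str,
                    rfd: RfdTable | None = None,
                    params: ExposureParams | None = None) -> RiskResult:
    """Deterministic CDI/HQ/HI for one cohort from element concentrations (mg/L)."""
    params = params or ExposureParams.default(cohort)
    rfd = rfd or RfdTable()
    cdi = {el: cdi_oral(c, params) for el, c in concentrations.items()}
    hq = {el: cdi[el] / rfd[el] for el in cdi}
    hi, flag = hazard_index(hq)
    return RiskResult(cohort=cohort, cdi=cdi, hq=hq, hi=hi, at_risk=flag)


# ---------------------------------------------------------------------------
# Monte Carlo layer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistSpec:
    """Distribution of one input: truncated normal (default) or lognormal.

    ``sd`` may be given directly or via ``cv`` (sd = cv·mean).  Truncation
    bounds apply to the truncated-normal family; concentrations and exposure
    factors are bounded below at 0 so no draw is unphysical.
    """

    mean: float
    sd: float | None = None
    cv: float | None = None
    family: str = "truncnorm"
    lower: float = 0.0
    upper: float = float("inf")

    def resolved_sd(self) -> float:
        if self.sd is not None:
            return self.sd
        if self.cv is not None:
            return self.cv * self.mean
        raise ConfigError("distribution needs sd or cv")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        sd = self.resolved_sd()
        if sd < 0 or self.mean < 0:
            raise ConfigError(f"invalid distribution (mean {self.mean}, sd {sd})")
        if sd == 0:
            return np.full(n, self.mean)
        if self.family == "truncnorm":
            a = (self.lower - self.mean) / sd
            b = (self.upper - self.mean) / sd
            return stats.truncnorm.rvs(a, b, loc=self.mean, scale=sd, size=n, random_state=rng)
        if self.family == "lognormal":
            # parameterised by the arithmetic mean and sd of the variable
            sigma2 = np.log1p((sd / self.mean) ** 2)
            mu = np.log(self.mean) - sigma2 / 2.0
            return rng.lognormal(mu, np.sqrt(sigma2), size=n)
        raise ConfigError(f"unknown distribution family {self.family!r}")

    @classmethod
    def fit(cls, values: Sequence[float], family: str = "truncnorm") -> "DistSpec":
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ConfigError("need at least 2 values to fit a concentration distribution")
        return cls(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), family=family)


@dataclass(frozen=True)
class McConfig:
    """Monte Carlo settings: iteration count, seed, and exposure-factor CVs.

    The exposure-factor spreads are assumptions, not measured values: intake
    rate CV 20 %, body weight CV 15 %, exposure frequency CV 5 %; ED, AT and
    RfD are fixed.  All are overridable per cohort via ``factor_overrides``
    (mapping factor name → :class:`DistSpec`).
    """

    n_iter: int = 10_000
    seed: int = 0
    ir_cv: float = 0.20
    bw_cv: float = 0.15
    ef_cv: float = 0.05
    conc_family: str = "truncnorm"
    factor_overrides: Mapping[str, DistSpec] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_iter < 1:
            raise ConfigError(f"n_iter must be >= 1, got {self.n_iter}")


@dataclass(frozen=True)
class McSummary:
    element: str
    cohort: str
    n_iter: int
    seed: int
    mean: float
    median: float
    p5: float
    p95: float
    prob_hq_gt_1: float


def mc_simulate_hq(element: str, cohort: str,
                   concentrations: Sequence[float] | DistSpec,
                   config: McConfig | None = None,
                   rfd: RfdTable | None = None) -> McSummary:
    """Simulated oral-HQ distribution for one element × cohort.

    ``concentrations`` is either a list of observed values (a truncated
    normal is fitted to their mean/sd) or an explicit :class:`DistSpec`.
    Deterministic under a fixed seed: the stream is keyed on
    (seed, element, cohort) so summaries do not depend on call order.
    """
    config = config or McConfig()
    rfd_v = (rfd or RfdTable())[element]
    base = ExposureParams.default(cohort)
    conc = concentrations if isinstance(concentrations, DistSpec) else DistSpec.fit(
        concentrations, family=config.conc_family)

    key = zlib.crc32(f"{element}:{cohort}".encode()) % (2**31)
    rng = np.random.default_rng([config.seed, key])
    n = config.n_iter
    ov = config.factor_overrides
    c = conc.sample(rng, n)
    ir = ov.get("ir", DistSpec(mean=base.ir, cv=config.ir_cv)).sample(rng, n)
    bw = ov.get("bw", DistSpec(mean=base.bw, cv=config.bw_cv)).sample(rng, n)
    ef = ov.get("ef", DistSpec(mean=base.ef, cv=config.ef_cv, upper=365.0)).sample(rng, n)
    hq = c * ir * base.ed / (bw * base.at_nc) * ef / rfd_v
    return McSummary(
        element=element, cohort=cohort, n_iter=n, seed=config.seed,
        mean=float(hq.mean()), median=float(np.median(hq)),
        p5=float(np.percentile(hq, 5)), p95=float(np.percentile(hq, 95)),
        prob_hq_gt_1=float((hq > 1.0).mean()),
    )


def mc_campaign(concentrations: Mapping[str, Sequence[float]],
                config: McConfig | None = None,
                rfd: RfdTable | None = None) -> list[McSummary]:
    """Run the simulation for every element × cohort combination."""
    out = []
    for el, values in concentrations.items():
        for cohort in COHORTS:
            out.append(mc_simulate_hq(el, cohort, values, config=config, rfd=rfd))
    return out


def risk_table(samples, cohorts: Sequence[str] = COHORTS,
               elements: Sequence[str] = RISK_ELEMENTS,
               rfd: RfdTable | None = None) -> pd.DataFrame:
    """Per-sample deterministic CDI/HQ/HI table across cohorts."""
    rows = []
    for s in samples:
        for cohort in cohorts:
            conc = {el: s.ion(el, default=0.0) for el in elements}
            r = risk_assessment(conc, cohort, rfd=rfd)
            row: dict[str, object] = {"site_id": s.site_id, "cohort": cohort,
                                      "hi": r.hi, "at_risk": r.at_risk}
            for el in elements:
                row[f"cdi_{el}"] = r.cdi[el]
                row[f"hq_{el}"] = r.hq[el]
            rows.append(row)
    return pd.DataFrame(rows)


def mc_summary_frame(summaries: Sequence[McSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
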