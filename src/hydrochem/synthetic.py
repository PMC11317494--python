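"""Synthetic monitoring-campaign generator and the packaged site-mean fixture.

The fixture is the seven-site mean physicochemical table of a year-long
lower-Danube monitoring campaign (85 samples over 7 sites), transcribed with
its FAO irrigation and WHO drinking guideline columns.  The generator
re-creates full campaigns around those means: each site's samples are drawn
from a latent-factor model in which a shared "salinity" factor drives the
major ions with positive loadings (reproducing the dense positive inter-ion
correlation block of real river chemistry) while pH, CO3 and the trace
metals stay mostly independent.  Draws are clipped to the campaign's printed
parameter ranges, and an optional electroneutrality step re-solves the HCO3
residual whenever a draw's charge-balance error leaves the ±5 % QA band.

Within-site coefficients of variation are assumptions (5–15 % by parameter),
chosen so that draws stay inside the printed ranges; they are configuration,
not data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import date
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, ValidationError
from .samples import (
    DEFAULT_EQUIVALENT_WEIGHTS,
    MAJOR_ANIONS,
    MAJOR_CATIONS,
    WaterSample,
    to_meq,
)

SITE_IDS = ("S1", "S2", "S3", "S4", "S5", "S6", "S7")

#: Seven-site mean table (parameter → per-site values S1..S7) plus guideline
#: columns.  Units: mg/L except pH (—), T (°C), EC (µS/cm).
_FIXTURE_ROWS: Mapping[str, tuple[float, ...]] = MappingProxyType(
    {
        "Ca": (54.45, 54.15, 54.41, 53.93, 53.59, 53.72, 53.11),
        "Mg": (16.13, 15.59, 15.7, 15.31, 15.25, 14.76, 14.5),
        "Na": (16.56, 16.68, 16.56, 15.63, 15.87, 15.57, 15.27),
        "K": (2.58, 2.69, 2.6, 2.5, 2.74, 2.64, 2.57),
        "Cl": (24.5, 24.25, 24.17, 22.92, 22.5, 22.33, 22.23),
        "SO4": (37.25, 37.08, 37.08, 36.67, 35.08, 35.0, 34.85),
        "HCO3": (195.42, 188.33, 193.33, 190.83, 190.0, 188.33, 181.15),
        "CO3": (9.17, 10.08, 8.08, 10.42, 8.75, 9.17, 10.2),
        "NO3": (8.37, 7.86, 8.11, 8.04, 7.13, 7.35, 7.28),
        "Fe": (0.6, 0.58, 0.57, 0.6, 0.63, 0.53, 0.65),
        "Mn": (0.07, 0.06, 0.07, 0.05, 0.07, 0.05, 0.05),
        "T": (14.53, 14.06, 14.93, 14.48, 15.51, 15.44, 16.21),
        "EC": (467.92, 466.67, 462.08, 464.58, 463.75, 464.17, 451.15),
        "TDS": (272.5, 263.38, 251.88, 255.71, 296.36, 254.7, 257.44),
        "pH": (8.14, 8.16, 8.16, 8.14, 8.16, 8.18, 8.13),
        "TH": (113.82, 112.14, 112.73, 115.02, 110.56, 109.61, 108.15),
    }
)

#: FAO irrigation / WHO drinking guideline columns of the same table.
FIXTURE_LIMITS: Mapping[str, tuple[float | None, float | None]] = MappingProxyType(
    {
        "Ca": (400, 75), "Mg": (60, 50), "Na": (919, 200), "K": (2, 12),
        "Cl": (1036, 250), "SO4": (960, 250), "HCO3": (610, 120), "CO3": (3, 350),
        "NO3": (None, 50), "Fe": (5, 0.3), "Mn": (0.2, 0.1),
        "EC": (3000, 1500), "TDS": (2000, 500), "pH": (8.5, 8.5), "TH": (None, 500),
    }
)

_FIXTURE_SHA256 = "fea14f07af79c45b25e65e1803f77816f53eee9ef8ab6672ffea1b6bc1ddafa7"

#: Printed campaign-wide parameter ranges (min, max) used as truncation
#: envelopes.  CO3/NO3/Fe/Mn ranges were not printed and are plausible
#: envelopes around the site means.
DEFAULT_RANGES: Mapping[str, tuple[float, float]] = MappingProxyType(
    {
        "pH": (7.6, 8.6), "EC": (360.0, 680.0), "TDS": (199.0, 370.0),
        "Ca": (39.0, 68.0), "Mg": (12.0, 24.0), "Na": (11.0, 25.5),
        "K": (0.1, 4.0), "Cl": (15.0, 40.0), "SO4": (27.0, 51.0),
        "HCO3": (125.0, 255.0), "CO3": (2.0, 16.0), "NO3": (3.0, 12.0),
        "Fe": (0.2, 1.0), "Mn": (0.01, 0.12), "T": (0.5, 28.0), "TH": (85.0, 140.0),
    }
)

#: Assumed within-site coefficients of variation by parameter.
DEFAULT_CV: Mapping[str, float] = MappingProxyType(
    {
        "pH": 0.012, "EC": 0.08, "TDS": 0.08, "TH": 0.05, "T": 0.30,
        "Ca": 0.06, "Mg": 0.08, "Na": 0.10, "K": 0.12, "Cl": 0.10,
        "SO4": 0.08, "HCO3": 0.06, "CO3": 0.15, "NO3": 0.12,
        "Fe": 0.12, "Mn": 0.15,
    }
)

#: Default one-factor loading structure: a shared salinity factor drives the
#: covarying majors; pH, CO3, Fe, Mn, T are left independent.
DEFAULT_LOADINGS: Mapping[str, Mapping[str, float]] = MappingProxyType(
    {
        "salinity": MappingProxyType(
            {
                "Ca": 0.85, "Mg": 0.85, "Na": 0.95, "Cl": 0.95, "SO4": 0.8,
                "HCO3": 0.8, "NO3": 0.7, "K": 0.4, "EC": 0.85, "TDS": 0.7, "TH": 0.85,
            }
        )
    }
)

GENERATED_PARAMS = tuple(_FIXTURE_ROWS)


def fixture_frame():
    """The packaged site-mean table as a parameters × sites DataFrame."""
    import pandas as pd

    return pd.DataFrame(_FIXTURE_ROWS, index=SITE_IDS).T


def _fixture_digest() -> str:
    parts = []
    for param in sorted(_FIXTURE_ROWS):
        parts.append(param + ":" + ",".join(repr(v) for v in _FIXTURE_ROWS[param]))
    return hashlib.sha256("|".join(parts).encode()).hexdigest()


def fixture_site_means() -> list[WaterSample]:
    """The seven packaged site-mean samples (immutable transcription).

    Raises :class:`ConfigError` if the packaged table was tampered with
    (checksum mismatch).
    """
    if _fixture_digest() != _FIXTURE_SHA256:
        raise ConfigError("packaged site-mean fixture failed its checksum")
    out = []
    for j, site in enumerate(SITE_IDS):
        conc = {ion: _FIXTURE_ROWS[ion][j]
                for ion in ("Ca", "Mg", "Na", "K", "Cl", "SO4", "HCO3", "CO3", "NO3", "Fe", "Mn")}
        out.append(
            WaterSample(
                site_id=site, ph=_FIXTURE_ROWS["pH"][j], conc=conc,
                temp=_FIXTURE_ROWS["T"][j], ec=_FIXTURE_ROWS["EC"][j],
                tds=_FIXTURE_ROWS["TDS"][j], th=_FIXTURE_ROWS["TH"][j],
            )
        )
    return out


@dataclass(frozen=True)
class CampaignConfig:
    """Study-design parameters of a synthetic campaign.

    Defaults reproduce the reference campaign design: 7 sites, 85 samples in
    total (12 per site, 13 at the first), site means from the packaged
    fixture, one shared latent factor for the inter-ion correlation, draws
    truncated to the printed ranges and electroneutrality enforced at ±5 %.
    """

    n_sites: int = 7
    site_ids: tuple[str, ...] = SITE_IDS
    samples_per_site: tuple[int, ...] = (13, 12, 12, 12, 12, 12, 12)
    seed: int = 0
    site_means: Mapping[str, Sequence[float]] = field(default_factory=lambda: _FIXTURE_ROWS)
    cv: Mapping[str, float] = field(default_factory=lambda: DEFAULT_CV)
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=lambda: DEFAULT_RANGES)
    loadings: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: DEFAULT_LOADINGS)
    balance_adjust: bool = True
    cbe_tolerance: float = 5.0

    def __post_init__(self):
        if len(self.site_ids) != self.n_sites or len(self.samples_per_site) != self.n_sites:
            raise ConfigError("site_ids and samples_per_site must both have n_sites entries")
        if any(n < 1 for n in self.samples_per_site):
            raise ConfigError("every site needs at least one sample")
        for param, means in self.site_means.items():
            if len(means) != self.n_sites:
                raise ConfigError(f"site_means[{param!r}] must have {self.n_sites} entries")
            lo, hi = self.ranges.get(param, (-np.inf, np.inf))
            for m in means:
                if not lo <= m <= hi:
                    raise ConfigError(
                        f"site mean {param}={m} outside its range [{lo}, {hi}]"
                    )
        for param, c in self.cv.items():
            if c < 0:
                raise ConfigError(f"negative CV for {param}")

    @property
    def n_total(self) -> int:
        return int(sum(self.samples_per_site))


def generate_campaign(config: CampaignConfig | None = None) -> list[WaterSample]:
    """Draw a full synthetic campaign; deterministic under ``config.seed``.

    Per sample, latent factors f ~ N(0,1) are shared across parameters and

        value = mean_site · (1 + CV·(Σ_j l_j f_j + sqrt(1 − Σ l_j²)·ε)),

    with ε an independent standard normal, then clipped to the parameter
    range.  If ``balance_adjust`` and the resulting charge-balance error
    falls outside ±``cbe_tolerance`` %, the HCO3 residual is re-solved so
    the sample is exactly electroneutral given its other ions.
    """
    config = config or CampaignConfig()
    rng = np.random.default_rng(config.seed)
    factor_names = tuple(config.loadings)
    params = tuple(config.site_means)
    load_mat = np.zeros((len(params), len(factor_names)))
    for pi, param in enumerate(params):
        for fi, name in enumerate(factor_names):
            load_mat[pi, fi] = config.loadings[name].get(param, 0.0)
        l2 = float((load_mat[pi] ** 2).sum())
        if l2 > 1.0:
            raise ConfigError(f"loadings for {param} exceed unit variance (Σl² = {l2:.3f})")
    resid = np.sqrt(1.0 - (load_mat**2).sum(axis=1))

    samples: list[WaterSample] = []
    for j, site in enumerate(config.site_ids):
        n = config.samples_per_site[j]
        factors = rng.standard_normal((n, len(factor_names)))
        eps = rng.standard_normal((n, len(params)))
        shocks = factors @ load_mat.T + eps * resid
        # center per parameter so each site's sample mean hits its target
        # (the printed table gives means, not a sampling distribution)
        if n > 1:
            shocks -= shocks.mean(axis=0)
        for i in range(n):
            values: dict[str, float] = {}
            for pi, param in enumerate(params):
                v = config.site_means[param][j] * (
                    1.0 + config.cv.get(param, 0.0) * float(shocks[i, pi]))
                lo, hi = config.ranges.get(param, (0.0, np.inf))
                values[param] = float(np.clip(v, lo, hi))
            month = i % 12 + 1
            sample = WaterSample(
                site_id=site, date=date(2019, month, 15), ph=values["pH"],
                temp=values.get("T"), ec=values.get("EC"), tds=values.get("TDS"),
                th=values.get("TH"),
                conc={k: values[k] for k in
                      ("Ca", "Mg", "Na", "K", "Cl", "SO4", "HCO3", "CO3", "NO3", "Fe", "Mn")
                      if k in values},
            )
            if config.balance_adjust and "HCO3" in sample.conc:
                bal = to_meq(sample)
                if abs(bal.cbe_percent) > config.cbe_tolerance:
                    other_an = bal.sum_anions - bal.meq["HCO3"]
                    target_meq = bal.sum_cations - other_an
                    if target_meq > 0:
                        new_hco3 = target_meq * DEFAULT_EQUIVALENT_WEIGHTS["HCO3"]
                        lo, hi = config.ranges.get("HCO3", (0.0, np.inf))
                        sample = sample.with_conc(HCO3=float(np.clip(new_hco3, lo, hi)))
            samples.append(sample)
    return samples


@dataclass(frozen=True)
class CampaignReport:
    n_samples: int
    violations: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return self.n_samples > 0 and not self.violations


def validate_campaign(samples: Sequence[WaterSample],
                      config: CampaignConfig | None = None,
                      mean_rtol: float = 0.05) -> CampaignReport:
    """Check ranges, charge balance and per-site means against the config."""
    config = config or CampaignConfig()
    if not samples:
        return CampaignReport(n_samples=0, violations=("no samples",))
    violations: list[str] = []
    by_site: dict[str, list[WaterSample]] = {}
    for s in samples:
        by_site.setdefault(s.site_id, []).append(s)
        flat = {"pH": s.ph, "T": s.temp, "EC": s.ec, "TDS": s.tds, "TH": s.th, **s.conc}
        for param, v in flat.items():
            if v is None:
                continue
            lo, hi = config.ranges.get(param, (-np.inf, np.inf))
            if not lo <= v <= hi:
                violations.append(f"{s.site_id}: {param} = {v:.4g} outside [{lo}, {hi}]")
        bal = to_meq(s)
        if abs(bal.cbe_percent) > config.cbe_tolerance:
            violations.append(f"{s.site_id}: CBE {bal.cbe_percent:+.2f}% outside QA band")
    for j, site in enumerate(config.site_ids):
        group = by_site.get(site, [])
        if not group:
            violations.append(f"{site}: no samples")
            continue
        for param, means in config.site_means.items():
            target = means[j]
            if param == "pH":
                obs = float(np.mean([s.ph for s in group]))
            elif param in ("T", "EC", "TDS", "TH"):
                attr = {"T": "temp", "EC": "ec", "TDS": "tds", "TH": "th"}[param]
                vals = [getattr(s, attr) for s in group if getattr(s, attr) is not None]
                if not vals:
                    continue
                obs = float(np.mean(vals))
            else:
                obs = float(np.mean([s.conc.get(param, 0.0) for s in group]))
            if target > 0 and abs(obs - target) / target > mean_rtol:
                violations.append(
                    f"{site}: mean {param} = {obs:.4g} deviates >{mean_rtol:.0%} from {target}"
                )
    return CampaignReport(n_samples=len(samples), violations=tuple(violations))
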