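"""Weighted-arithmetic Drinking Water Quality Index (DWQI).

Fifteen parameters are rated against their WHO drinking-water limits Si,

    Qi = 100 · Ci / Si,      wi = K / Si,      K = 1 / Σ(1/Si),

so that Σ wi = 1 identically and DWQI = Σ wi·Qi.  A sample in which every
parameter sits exactly at its limit scores 100.  pH is rated by the same
Ci/Si form as the concentrations (no ideal-value offset).  Because the
weights are inversely proportional to the limits, the index is dominated by
the parameters with the smallest limits — here the trace metals Fe and Mn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigError, ValidationError
from .samples import WaterSample

#: WHO (2017) guideline limits.  Units: pH dimensionless, EC µS/cm, all
#: others mg/L.  The Mn limit defaults to 0.1 mg/L (the WHO health-based
#: value used consistently by the index weights); 0.05 is a legacy aesthetic
#: threshold selectable by overriding the table.
DEFAULT_STANDARDS: Mapping[str, float] = MappingProxyType(
    {
        "pH": 8.5,
        "EC": 1500.0,
        "TH": 500.0,
        "TDS": 500.0,
        "Ca": 75.0,
        "Mg": 50.0,
        "Na": 200.0,
        "K": 12.0,
        "Cl": 250.0,
        "NO3": 50.0,
        "HCO3": 120.0,
        "CO3": 350.0,
        "SO4": 250.0,
        "Fe": 0.3,
        "Mn": 0.1,
    }
)

DWQI_PARAMETERS = tuple(DEFAULT_STANDARDS)

#: classification bands: (upper edge, label); a score equal to an edge takes
#: the lower band (score = 100 → "good").
DEFAULT_CLASS_BANDS: tuple[tuple[float, str], ...] = (
    (50.0, "excellent"),
    (100.0, "good"),
    (200.0, "poor"),
    (300.0, "very poor"),
    (float("inf"), "unfit"),
)


@dataclass(frozen=True)
class DwqiStandards:
    si: Mapping[str, float] = field(default_factory=lambda: DEFAULT_STANDARDS)

    def __post_init__(self):
        for p, s in self.si.items():
            if s <= 0:
                raise ConfigError(f"standard limit for {p} must be positive, got {s}")
        object.__setattr__(self, "si", MappingProxyType(dict(self.si)))


@dataclass(frozen=True)
class DwqiResult:
    k_const: float
    wi: Mapping[str, float]
    qi: Mapping[str, float]
    contributions: Mapping[str, float]
    score: float
    class_label: str


def dwqi_weights(standards: DwqiStandards | None = None) -> tuple[float, dict[str, float]]:
    """K = 1/Σ(1/Si) and the relative weights wi = K/Si (which sum to 1)."""
    st = (standards or DwqiStandards()).si
    k = 1.0 / sum(1.0 / s for s in st.values())
    return k, {p: k / s for p, s in st.items()}


def quality_rating(ci: float, si: float) -> float:
    """Qi = 100·Ci/Si, the parameter rating in percent of its limit."""
    if si <= 0:
        raise ConfigError(f"standard limit must be positive, got {si}")
    if ci < 0:
        raise ValidationError(f"negative concentration {ci}")
    return 100.0 * ci / si


def _parameter_value(sample: WaterSample, param: str) -> float | None:
    if param == "pH":
        return sample.ph
    if param == "EC":
        return sample.ec
    if param == "TH":
        return sample.th
    if param == "TDS":
        return sample.tds
    return sample.conc.get(param)


def dwqi_score(sample: WaterSample, standards: DwqiStandards | None = None,
               class_bands: Sequence[tuple[float, str]] = DEFAULT_CLASS_BANDS) -> DwqiResult:
    """DWQI = Σ wi·Qi over the 15 parameters, with the per-parameter audit trail."""
    standards = standards or DwqiStandards()
    missing = [p for p in standards.si if _parameter_value(sample, p) is None]
    if missing:
        raise ValidationError(
            f"{sample.site_id}: DWQI needs all parameters; missing {', '.join(missing)}"
        )
    k, wi = dwqi_weights(standards)
    qi = {p: quality_rating(_parameter_value(sample, p), s) for p, s in standards.si.items()}
    contrib = {p: wi[p] * qi[p] for p in standards.si}
    score = sum(contrib.values())
    return DwqiResult(k_const=k, wi=wi, qi=qi, contributions=contrib,
                      score=score, class_label=classify_dwqi(score, class_bands))


def classify_dwqi(score: float,
                  class_bands: Sequence[tuple[float, str]] = DEFAULT_CLASS_BANDS) -> str:
    """Band label for a DWQI score; boundary scores take the lower band."""
    if score < 0:
        raise ValidationError(f"negative DWQI score {score}")
    for edge, label in class_bands:
        if score <= edge:
            return label
    raise ConfigError("class bands do not cover the score axis")


def dwqi_table(samples: Sequence[WaterSample],
               standards: DwqiStandards | None = None) -> pd.DataFrame:
    """Per-sample DWQI table with the full Qi / wi·Qi breakdown."""
    rows = []
    for s in samples:
        r = dwqi_score(s, standards)
        row: dict[str, object] = {"site_id": s.site_id, "dwqi": r.score, "class": r.class_label}
        for p in r.qi:
            row[f"qi_{p}"] = r.qi[p]
            row[f"wq_{p}"] = r.contributions[p]
        rows.append(row)
    return pd.DataFrame(rows)
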