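"""Irrigation suitability indices and the class-interpolated IWQI.

The classical sodicity/salinity indices are computed on the meq/L basis:

    SAR  = Na / sqrt((Ca + Mg)/2)
    Na%  = 100·(Na + K)/(Ca + Mg + Na + K)
    SSP  = 100·Na/(Ca + Mg + Na)
    PS   = Cl + SO4/2
    RSC  = (HCO3 + CO3) − (Ca + Mg)

The IWQI (0–100, higher is better) rates EC, Na, Cl, HCO3 and SAR by linear
interpolation inside tabulated suitability classes,

    Qi = Qmax − (Xij − Xinf)·Qamp/Xamp,

and aggregates with fixed weights:  IWQI = Σ Qi·Wi.  Note some published
SAR formulas carry a ×100 factor; it is dimensionally spurious and off by
default (``sar_times_100=True`` reproduces the literal variant for audit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigError, ValidationError
from .samples import IonBalance, WaterSample

#: published weights of the class-interpolated irrigation index
DEFAULT_IWQI_WEIGHTS: Mapping[str, float] = MappingProxyType(
    {"EC": 0.211, "Na": 0.204, "HCO3": 0.202, "Cl": 0.194, "SAR": 0.189}
)


@dataclass(frozen=True)
class IrrigationIndices:
    sar: float | None
    na_pct: float
    ssp: float
    ps: float
    rsc: float
    class_labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "class_labels", MappingProxyType(dict(self.class_labels)))


@dataclass(frozen=True)
class IwqiClassRow:
    q_min: float
    q_max: float
    x_inf: float      # lower bound of the class on the value axis
    x_amp: float      # class width

    @property
    def q_amp(self) -> float:
        return self.q_max - self.q_min


@dataclass(frozen=True)
class IwqiResult:
    qi: Mapping[str, float]
    weights: Mapping[str, float]
    score: float
    restriction_class: str


# ---------------------------------------------------------------------------
# classical indices
# ---------------------------------------------------------------------------

def irrigation_indices(balance: IonBalance, sar_times_100: bool = False) -> IrrigationIndices:
    """All five classical indices (meq/L basis) with their class labels."""
    m = balance.meq
    camg = m["Ca"] + m["Mg"]
    nak = m["Na"] + m["K"]
    if camg > 0:
        sar: float | None = m["Na"] / math.sqrt(camg / 2.0)
        if sar_times_100:
            sar *= 100.0
    else:
        sar = None
    cat_total = camg + nak
    na_pct = 100.0 * nak / cat_total if cat_total > 0 else 0.0
    ssp_den = camg + m["Na"]
    ssp = 100.0 * m["Na"] / ssp_den if ssp_den > 0 else 0.0
    ps = m["Cl"] + m["SO4"] / 2.0
    rsc = (m["HCO3"] + m["CO3"]) - camg
    idx = IrrigationIndices(sar=sar, na_pct=na_pct, ssp=ssp, ps=ps, rsc=rsc)
    return IrrigationIndices(sar=sar, na_pct=na_pct, ssp=ssp, ps=ps, rsc=rsc,
                             class_labels=classify_irrigation(idx))


def classify_irrigation(indices: IrrigationIndices) -> dict[str, str]:
    """Band labels per index (documented conventional bands).

    PS: <3 excellent-to-good, 3–5 good-to-injurious, >5 injurious.
    RSC: <1.25 acceptable, 1.25–2.5 doubtful, >2.5 inappropriate (the lower
    edge is exclusive: RSC = 1.25 is already doubtful).
    """
    labels: dict[str, str] = {}
    s = indices.sar
    if s is None:
        labels["SAR"] = "undefined"
    elif s < 10:
        labels["SAR"] = "excellent"
    elif s < 18:
        labels["SAR"] = "good"
    elif s < 26:
        labels["SAR"] = "doubtful"
    else:
        labels["SAR"] = "unsuitable"
    n = indices.na_pct
    labels["Na%"] = ("excellent" if n < 20 else "good" if n < 40 else
                     "permissible" if n < 60 else "doubtful" if n < 80 else "unsuitable")
    labels["SSP"] = "good" if indices.ssp < 50 else "bad"
    p = indices.ps
    labels["PS"] = ("excellent-to-good" if p < 3.0 else
                    "good-to-injurious" if p <= 5.0 else "injurious-to-unsatisfactory")
    r = indices.rsc
    labels["RSC"] = "acceptable" if r < 1.25 else ("doubtful" if r <= 2.5 else "inappropriate")
    return labels


# ---------------------------------------------------------------------------
# class-interpolated IWQI
# ---------------------------------------------------------------------------

def _rows(spec: Sequence[tuple[float, float, float, float]]) -> tuple[IwqiClassRow, ...]:
    return tuple(IwqiClassRow(*r) for r in spec)

#: suitability class table: per parameter, rows of (q_min, q_max, x_inf, x_amp)
#: ordered from the best class downward.  EC in µS/cm; Na, Cl, HCO3 in meq/L;
#: SAR dimensionless.  Values below the best class's lower bound, or at/above
#: the worst class's upper bound, fall in the 0–35 class with x_inf = 0 and
#: x_amp = the lowest defined bound.
DEFAULT_IWQI_CLASS_TABLE: Mapping[str, tuple[IwqiClassRow, ...]] = MappingProxyType(
    {
        "EC": _rows([(85, 100, 200, 550), (60, 85, 750, 750), (35, 60, 1500, 1500)]),
        "SAR": _rows([(85, 100, 2, 1), (60, 85, 3, 3), (35, 60, 6, 6)]),
        "HCO3": _rows([(85, 100, 1.0, 0.5), (60, 85, 1.5, 3.0), (35, 60, 4.5, 4.0)]),
        "Na": _rows([(85, 100, 2, 1), (60, 85, 3, 3), (35, 60, 6, 3)]),
        "Cl": _rows([(85, 100, 1, 3), (60, 85, 4, 3), (35, 60, 7, 3)]),
    }
)

#: restriction classes on the aggregate score (upper-inclusive edges).
RESTRICTION_BANDS: tuple[tuple[float, str], ...] = (
    (40.0, "severe"),
    (55.0, "high"),
    (70.0, "moderate"),
    (85.0, "low"),
    (100.0, "none"),
)


def iwqi_rating(parameter: str, value: float,
                table: Mapping[str, tuple[IwqiClassRow, ...]] | None = None) -> float:
    """Class-interpolated rating Qi ∈ [0, 100] for one parameter value."""
    table = table or DEFAULT_IWQI_CLASS_TABLE
    if parameter not in table:
        raise ConfigError(f"no IWQI class table for parameter {parameter!r}")
    if value < 0:
        raise ValidationError(f"negative {parameter} value {value}")
    rows = table[parameter]
    for row in rows:
        if row.x_inf <= value < row.x_inf + row.x_amp:
            q = row.q_max - (value - row.x_inf) * row.q_amp / row.x_amp
            return min(100.0, max(0.0, q))
    # out of every tabulated class: the 0-35 class, x_inf = 0, x_amp = lowest bound
    lowest = min(r.x_inf for r in rows)
    if value < lowest:
        q = 35.0 - (value - 0.0) * 35.0 / lowest
    else:
        q = 0.0
    return min(100.0, max(0.0, q))


def iwqi_score(sample: WaterSample, balance: IonBalance,
               weights: Mapping[str, float] | None = None,
               table: Mapping[str, tuple[IwqiClassRow, ...]] | None = None) -> IwqiResult:
    """IWQI = Σ Qi·Wi over {EC, Na, Cl, HCO3, SAR} with its restriction class."""
    weights = dict(weights or DEFAULT_IWQI_WEIGHTS)
    if abs(sum(weights.values()) - 1.0) > 1e-6:
        raise ConfigError(f"IWQI weights must sum to 1, got {sum(weights.values()):.6f}")
    if sample.ec is None:
        raise ValidationError(f"{sample.site_id}: EC required for the IWQI")
    idx = irrigation_indices(balance)
    if idx.sar is None:
        raise ValidationError(f"{sample.site_id}: SAR undefined (Ca + Mg = 0)")
    values = {"EC": sample.ec, "Na": balance.meq["Na"], "Cl": balance.meq["Cl"],
              "HCO3": balance.meq["HCO3"], "SAR": idx.sar}
    qi = {p: iwqi_rating(p, v, table) for p, v in values.items()}
    score = sum(qi[p] * weights[p] for p in weights)
    for edge, label in RESTRICTION_BANDS:
        if score <= edge:
            cls = label
            break
    return IwqiResult(qi=qi, weights=weights, score=score, restriction_class=cls)


def irrigation_table(samples: Sequence[WaterSample],
                     balances: Sequence[IonBalance]) -> pd.DataFrame:
    """Per-sample irrigation export: classical indices, classes, IWQI breakdown."""
    rows = []
    for s, b in zip(samples, balances):
        idx = irrigation_indices(b)
        row: dict[str, object] = {
            "site_id": s.site_id, "sar": idx.sar, "na_pct": idx.na_pct,
            "ssp": idx.ssp, "ps": idx.ps, "rsc": idx.rsc,
        }
        row.update({f"class_{k}": v for k, v in idx.class_labels.items()})
        if s.ec is not None and idx.sar is not None:
            r = iwqi_score(s, b)
            row["iwqi"] = r.score
            row["iwqi_class"] = r.restriction_class
            row.update({f"iwqi_qi_{p}": q for p, q in r.qi.items()})
        rows.append(row)
    return pd.DataFrame(rows)
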