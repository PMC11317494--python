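"""Hydrochemical facies and source diagnostics.

Implements the classic graphical classifications on a numeric basis: Piper
triangle percentages and facies label, the Chadha rectangular variant, Gibbs
mechanism ratios with a polygon zone test, a panel of diagnostic ionic
ratios, and the Schoeller chloro-alkaline indices

    CAI-I  = [Cl − (Na + K)] / Cl
    CAI-II = [Cl − (Na + K)] / (SO4 + HCO3 + CO3 + NO3)

all on a meq/L basis.  Negative CAI values indicate direct ion exchange
(water Na/K traded for aquifer Ca/Mg); positive values the reverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import UndefinedQuantityError
from .samples import IonBalance, MAJOR_ANIONS, MAJOR_CATIONS, WaterSample

#: Gibbs "boomerang" envelope for the rock-weathering dominance field,
#: as (ratio, TDS mg/L) vertices.  Waters with low TDS and high ratio fall in
#: the precipitation-dominance corner; high TDS and high ratio in the
#: evaporation corner.  The classic figure is reproduced as three TDS bands.
GIBBS_ROCK_TDS = (70.0, 10_000.0)      # TDS band of the rock-weathering field
GIBBS_PRECIP_TDS_MAX = 70.0
GIBBS_EVAP_TDS_MIN = 10_000.0
GIBBS_RATIO_ROCK_MAX = 0.8             # rock-weathering field spans ratios below ~0.8


@dataclass(frozen=True)
class FaciesResult:
    cation_pct: Mapping[str, float]
    anion_pct: Mapping[str, float]
    facies_label: str
    chadha_x: float
    chadha_y: float
    chadha_field: str
    gibbs_na_ratio: float
    gibbs_cl_ratio: float
    gibbs_zone: str


@dataclass(frozen=True)
class CaiResult:
    cai1: float | None
    cai2: float | None
    direction: str  # "ion-exchange" (negative), "reverse" (positive), "neutral"


@dataclass(frozen=True)
class RatioValue:
    value: float | None
    defined: bool
    side_of_unity: str  # "above", "below", "on", "undefined"


@dataclass(frozen=True)
class RatioPanel:
    ca_mg_over_hco3: RatioValue
    ca_mg_over_hco3_so4: RatioValue
    na_over_cl: RatioValue
    ca_over_mg: RatioValue
    delta_camg_nak: float   # (Ca+Mg) − (Na+K), meq/L
    delta_hco3_so4cl: float  # HCO3 − (SO4+Cl), meq/L


_PIPER_CATION_GROUPS = (("Ca", ("Ca",)), ("Mg", ("Mg",)), ("Na+K", ("Na", "K")))
#: NO3 joins the Cl vertex (standard trilinear practice) so the three anion
#: groups tile the full anion sum and the percentages close to 100
_PIPER_ANION_GROUPS = (("HCO3+CO3", ("HCO3", "CO3")), ("SO4", ("SO4",)), ("Cl", ("Cl", "NO3")))
#: ions named in the facies label, in the conventional Piper order
_LABEL_NAMES = {"Ca": "Ca", "Mg": "Mg", "Na+K": "Na", "HCO3+CO3": "HCO3", "SO4": "SO4", "Cl": "Cl"}


def piper_percentages(balance: IonBalance) -> tuple[dict[str, float], dict[str, float]]:
    """Cation and anion triangle percentages on the meq basis."""
    if balance.sum_cations <= 0 or balance.sum_anions <= 0:
        raise UndefinedQuantityError("Piper classification undefined: zero cation or anion sum")
    cat = {name: 100.0 * sum(balance.meq[i] for i in ions) / balance.sum_cations
           for name, ions in _PIPER_CATION_GROUPS}
    an = {name: 100.0 * sum(balance.meq[i] for i in ions) / balance.sum_anions
          for name, ions in _PIPER_ANION_GROUPS}
    return cat, an


def facies_label(cation_pct: Mapping[str, float], anion_pct: Mapping[str, float],
                 threshold: float = 20.0) -> str:
    """Facies name: every triangle member holding ≥ ``threshold`` % of its
    triangle's meq, cations first, each block in descending percentage."""
    parts: list[str] = []
    for pct in (cation_pct, anion_pct):
        members = sorted((g for g in pct if pct[g] >= threshold), key=lambda g: -pct[g])
        parts.extend(_LABEL_NAMES[g] for g in members)
    return "–".join(parts)  # en-dash, e.g. "Ca–Mg–HCO3"


def chadha_classify(balance: IonBalance) -> tuple[float, float, str]:
    """Chadha rectangular coordinates and quadrant.

    x = 100·[(Ca+Mg) − (Na+K)]/Σcations, y = 100·[(HCO3+CO3) − (Cl+SO4)]/Σanions
    (NO3 enters the normalising anion sum only).  Quadrants: (+,+) recharging
    Ca–Mg–HCO3; (+,−) reverse-exchange Ca–Mg–Cl; (−,+) base-exchange
    Na–HCO3; (−,−) saline Na–Cl.
    """
    if balance.sum_cations <= 0 or balance.sum_anions <= 0:
        raise UndefinedQuantityError("Chadha classification undefined: zero ion sum")
    m = balance.meq
    x = 100.0 * ((m["Ca"] + m["Mg"]) - (m["Na"] + m["K"])) / balance.sum_cations
    y = 100.0 * ((m["HCO3"] + m["CO3"]) - (m["Cl"] + m["SO4"])) / balance.sum_anions
    if x == 0 and y == 0:
        field = "indeterminate"
    elif x > 0 and y > 0:
        field = "Ca-Mg-HCO3 recharging water"
    elif x > 0:
        field = "Ca-Mg-Cl reverse ion-exchange water"
    elif y > 0:
        field = "Na-HCO3 base ion-exchange water"
    else:
        field = "Na-Cl saline water"
    return x, y, field


def gibbs_point(sample: WaterSample, balance: IonBalance) -> tuple[float, float, float, str]:
    """Gibbs mechanism diagram point: (TDS, Na/(Na+Ca), Cl/(Cl+HCO3), zone).

    Ratios are on the meq basis.  Zone membership uses the documented TDS
    bands and ratio bound of the classic boomerang envelope.
    """
    if sample.tds is None:
        raise UndefinedQuantityError(f"{sample.site_id}: TDS required for the Gibbs diagram")
    m = balance.meq
    na_den = m["Na"] + m["Ca"]
    cl_den = m["Cl"] + m["HCO3"]
    na_ratio = m["Na"] / na_den if na_den > 0 else 0.0
    cl_ratio = m["Cl"] / cl_den if cl_den > 0 else 0.0
    ratio = max(na_ratio, cl_ratio)
    tds = sample.tds
    if tds >= GIBBS_EVAP_TDS_MIN and ratio > 0.5:
        zone = "evaporation"
    elif tds <= GIBBS_PRECIP_TDS_MAX and ratio > 0.5:
        zone = "precipitation"
    elif GIBBS_ROCK_TDS[0] <= tds <= GIBBS_ROCK_TDS[1] and ratio <= GIBBS_RATIO_ROCK_MAX:
        zone = "rock-weathering"
    else:
        zone = "outside"
    return tds, na_ratio, cl_ratio, zone


def cai_indices(balance: IonBalance, numerator: str = "schoeller") -> CaiResult:
    """Chloro-alkaline indices on the meq basis.

    ``numerator="schoeller"`` (default) uses Cl − (Na + K); the variant
    ``"printed"`` reproduces a Cl − (Na − Ca) form occasionally seen in
    print, kept for audit only.
    """
    m = balance.meq
    if numerator == "schoeller":
        num = m["Cl"] - (m["Na"] + m["K"])
    elif numerator == "printed":
        num = m["Cl"] - (m["Na"] - m["Ca"])
    else:
        raise ValueError(f"unknown CAI numerator variant {numerator!r}")
    cai1 = num / m["Cl"] if m["Cl"] > 0 else None
    den2 = m["SO4"] + m["HCO3"] + m["CO3"] + m["NO3"]
    cai2 = num / den2 if den2 > 0 else None
    probe = cai1 if cai1 is not None else cai2
    if probe is None or probe == 0:
        direction = "neutral"
    elif probe < 0:
        direction = "ion-exchange"
    else:
        direction = "reverse"
    return CaiResult(cai1=cai1, cai2=cai2, direction=direction)


def _ratio(num: float, den: float) -> RatioValue:
    if den == 0:
        return RatioValue(value=None, defined=False, side_of_unity="undefined")
    v = num / den
    side = "on" if math.isclose(v, 1.0, rel_tol=1e-12, abs_tol=1e-12) else ("above" if v > 1 else "below")
    return RatioValue(value=v, defined=True, side_of_unity=side)


def ratio_panel(balance: IonBalance) -> RatioPanel:
    """Diagnostic ionic-ratio panel (meq basis) with side-of-1:1-line flags."""
    m = balance.meq
    camg = m["Ca"] + m["Mg"]
    nak = m["Na"] + m["K"]
    return RatioPanel(
        ca_mg_over_hco3=_ratio(camg, m["HCO3"]),
        ca_mg_over_hco3_so4=_ratio(camg, m["HCO3"] + m["SO4"]),
        na_over_cl=_ratio(m["Na"], m["Cl"]),
        ca_over_mg=_ratio(m["Ca"], m["Mg"]),
        delta_camg_nak=camg - nak,
        delta_hco3_so4cl=m["HCO3"] - (m["SO4"] + m["Cl"]),
    )


def classify(sample: WaterSample, balance: IonBalance) -> FaciesResult:
    """Full facies diagnosis for one sample."""
    cat, an = piper_percentages(balance)
    label = facies_label(cat, an)
    x, y, fld = chadha_classify(balance)
    tds, nar, clr, zone = gibbs_point(sample, balance)
    return FaciesResult(
        cation_pct=cat, anion_pct=an, facies_label=label,
        chadha_x=x, chadha_y=y, chadha_field=fld,
        gibbs_na_ratio=nar, gibbs_cl_ratio=clr, gibbs_zone=zone,
    )


def facies_table(samples: Sequence[WaterSample], balances: Sequence[IonBalance]) -> pd.DataFrame:
    """Per-sample facies/CAI table — the plotting-ready coordinate export."""
    rows = []
    for s, b in zip(samples, balances):
        f = classify(s, b)
        c = cai_indices(b)
        rows.append(
            {
                "site_id": s.site_id,
                "facies": f.facies_label,
                **{f"cat_pct_{k}": v for k, v in f.cation_pct.items()},
                **{f"an_pct_{k}": v for k, v in f.anion_pct.items()},
                "chadha_x": f.chadha_x, "chadha_y": f.chadha_y, "chadha_field": f.chadha_field,
                "gibbs_na_ratio": f.gibbs_na_ratio, "gibbs_cl_ratio": f.gibbs_cl_ratio,
                "gibbs_zone": f.gibbs_zone,
                "cai1": c.cai1, "cai2": c.cai2, "cai_direction": c.direction,
            }
        )
    return pd.DataFrame(rows)
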