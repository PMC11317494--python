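"""Sample data model, unit algebra and charge-balance quality assurance.

A :class:`WaterSample` holds one sample's physicochemical record in the
field-standard units (mg/L for dissolved constituents, µS/cm for EC, °C for
temperature).  Major-ion chemistry is converted to milliequivalents per litre
with :func:`to_meq`, from which the signed charge-balance error

    CBE % = 100 · (Σ cations − Σ anions) / (Σ cations + Σ anions)

acts as the analytical QA gate (conventional acceptance band ±5 %).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from datetime import date as _date
from pathlib import Path
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, UndefinedQuantityError, ValidationError

log = logging.getLogger(__name__)

#: Major ions carried by every sample (mg/L).  Fe and Mn are trace metals:
#: they enter indices and health risk but not the equivalent balance.
MAJOR_CATIONS = ("Ca", "Mg", "Na", "K")
MAJOR_ANIONS = ("Cl", "SO4", "HCO3", "CO3", "NO3")
TRACE_METALS = ("Fe", "Mn")
ION_KEYS = MAJOR_CATIONS + MAJOR_ANIONS + TRACE_METALS

#: Equivalent weights in g/eq (molar mass / charge), IUPAC atomic weights.
DEFAULT_EQUIVALENT_WEIGHTS = MappingProxyType(
    {
        "Ca": 20.04,
        "Mg": 12.153,
        "Na": 22.99,
        "K": 39.098,
        "Cl": 35.453,
        "SO4": 48.03,
        "HCO3": 61.017,
        "CO3": 30.005,
        "NO3": 62.004,
    }
)

#: Molar masses in g/mol for molarity-based quantities (ionic strength).
MOLAR_MASS = MappingProxyType(
    {
        "Ca": 40.078,
        "Mg": 24.305,
        "Na": 22.99,
        "K": 39.098,
        "Cl": 35.453,
        "SO4": 96.06,
        "HCO3": 61.017,
        "CO3": 60.009,
        "NO3": 62.004,
    }
)

#: Formal charge magnitude per ion.
ION_CHARGE = MappingProxyType(
    {
        "Ca": 2,
        "Mg": 2,
        "Na": 1,
        "K": 1,
        "Cl": 1,
        "SO4": 2,
        "HCO3": 1,
        "CO3": 2,
        "NO3": 1,
    }
)


@dataclass(frozen=True)
class EquivalentWeights:
    """Ion → g/eq table; immutable defaults, overridable for sensitivity runs."""

    values: Mapping[str, float] = field(default_factory=lambda: DEFAULT_EQUIVALENT_WEIGHTS)

    def __post_init__(self):
        for ion, ew in self.values.items():
            if ew <= 0:
                raise ValidationError(f"equivalent weight for {ion} must be positive, got {ew}")

    def __getitem__(self, ion: str) -> float:
        try:
            return self.values[ion]
        except KeyError:
            raise SchemaError(f"no equivalent weight registered for ion {ion!r}") from None


@dataclass(frozen=True)
class WaterSample:
    """One sample's full physicochemical record.

    Concentrations are mg/L; missing optional fields are ``None``, never a
    silent zero.  ``th`` is the *measured* total hardness (mg/L as CaCO3) and
    is carried through untouched — see :func:`hardness_from_ca_mg` for the
    computed alternative and why the two can disagree.
    """

    site_id: str
    ph: float
    conc: Mapping[str, float]
    date: _date | None = None
    temp: float | None = None
    ec: float | None = None
    tds: float | None = None
    th: float | None = None
    do: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.ph <= 14.0:
            raise ValidationError(f"{self.site_id}: pH {self.ph} outside [0, 14]")
        for ion, c in self.conc.items():
            if ion not in ION_KEYS:
                raise SchemaError(f"{self.site_id}: unknown ion key {ion!r}")
            if c is not None and c < 0:
                raise ValidationError(f"{self.site_id}: negative concentration {ion} = {c}")
        for name in ("ec", "tds", "th", "do"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{self.site_id}: negative {name} = {v}")
        object.__setattr__(self, "conc", MappingProxyType(dict(self.conc)))

    def ion(self, key: str, default: float | None = None) -> float:
        """Concentration of ``key`` in mg/L; ``default`` if absent."""
        v = self.conc.get(key)
        if v is None:
            if default is None:
                raise SchemaError(f"{self.site_id}: ion {key!r} not measured")
            return default
        return v

    def with_conc(self, **updates: float) -> "WaterSample":
        new = dict(self.conc)
        new.update(updates)
        return replace(self, conc=new)


@dataclass(frozen=True)
class IonBalance:
    """meq/L view of the major-ion chemistry plus charge-balance diagnostics."""

    meq: Mapping[str, float]
    sum_cations: float
    sum_anions: float
    cbe_percent: float

    def __post_init__(self):
        object.__setattr__(self, "meq", MappingProxyType(dict(self.meq)))

    def __getitem__(self, ion: str) -> float:
        return self.meq[ion]


@dataclass(frozen=True)
class QAResult:
    sample: WaterSample
    cbe_percent: float
    pass_flag: bool
    notes: tuple[str, ...] = ()


def to_meq(
    sample: WaterSample,
    ew: EquivalentWeights | None = None,
    missing_as_zero: bool = True,
) -> IonBalance:
    """Convert major-ion concentrations to meq/L and compute the balance.

    meq[i] = conc[i] / equivalent_weight[i].  CO3 (often below titration
    detection) defaults to 0 with a logged warning when absent and
    ``missing_as_zero`` is true; any other absent ion is an error unless
    ``missing_as_zero``.
    """
    ew = ew or EquivalentWeights()
    meq: dict[str, float] = {}
    for ion in MAJOR_CATIONS + MAJOR_ANIONS:
        c = sample.conc.get(ion)
        if c is None:
            if not missing_as_zero:
                raise SchemaError(f"{sample.site_id}: ion {ion!r} missing and missing_as_zero=False")
            if ion == "CO3":
                log.warning("%s: CO3 not measured, defaulting to 0 mg/L", sample.site_id)
            c = 0.0
        meq[ion] = c / ew[ion]
    sum_cat = sum(meq[i] for i in MAJOR_CATIONS)
    sum_an = sum(meq[i] for i in MAJOR_ANIONS)
    if sum_cat + sum_an > 0:
        cbe = 100.0 * (sum_cat - sum_an) / (sum_cat + sum_an)
    else:
        cbe = 0.0
    return IonBalance(meq=meq, sum_cations=sum_cat, sum_anions=sum_an, cbe_percent=cbe)


def charge_balance_error(balance: IonBalance) -> float:
    """Signed CBE % = 100·(Σcat − Σan)/(Σcat + Σan).

    Raises :class:`UndefinedQuantityError` when both sums are zero.
    """
    total = balance.sum_cations + balance.sum_anions
    if total <= 0:
        raise UndefinedQuantityError("charge balance undefined: both ion sums are zero")
    return 100.0 * (balance.sum_cations - balance.sum_anions) / total


def qa_screen(
    samples: Iterable[WaterSample],
    tolerance: float = 5.0,
    ew: EquivalentWeights | None = None,
    action: str = "flag",
) -> list[QAResult]:
    """Charge-balance QA gate: every sample gets a :class:`QAResult`.

    ``action`` is ``"flag"`` (default, all samples returned with pass/fail
    flags) or ``"exclude"`` (failing samples dropped from the returned list).
    """
    if tolerance < 0:
        raise ValidationError(f"tolerance must be >= 0, got {tolerance}")
    if action not in ("flag", "exclude"):
        raise ValidationError(f"action must be 'flag' or 'exclude', got {action!r}")
    out: list[QAResult] = []
    for s in samples:
        bal = to_meq(s, ew)
        cbe = charge_balance_error(bal) if (bal.sum_cations + bal.sum_anions) > 0 else 0.0
        notes: list[str] = []
        ok = abs(cbe) <= tolerance
        if not ok:
            notes.append(f"CBE {cbe:+.2f}% outside +/-{tolerance:g}%")
        res = QAResult(sample=s, cbe_percent=cbe, pass_flag=ok, notes=tuple(notes))
        if action == "exclude" and not ok:
            continue
        out.append(res)
    return out


def hardness_from_ca_mg(ca_mg_l: float, mg_mg_l: float) -> float:
    """Total hardness (mg/L as CaCO3) computed as 2.497·Ca + 4.115·Mg.

    Provided as a utility only.  Measured TH reported alongside the major-ion
    table of the reference campaign is NOT reproduced by this formula (the
    field convention behind those TH numbers is unstated), so indices always
    use the measured value.
    """
    return 2.497 * ca_mg_l + 4.115 * mg_mg_l


# ----------------------------------------------------------------------------
# CSV I/O
# ----------------------------------------------------------------------------

#: Case-insensitive header aliases → canonical field name.
_HEADER_ALIASES = {
    "site": "site_id", "site_id": "site_id", "sample": "site_id", "station": "site_id",
    "date": "date", "month": "date",
    "ph": "ph",
    "t": "temp", "temp": "temp", "temperature": "temp", "t_c": "temp",
    "ec": "ec", "conductivity": "ec", "ec_us_cm": "ec",
    "tds": "tds",
    "th": "th", "hardness": "th", "total_hardness": "th",
    "do": "do", "dissolved_oxygen": "do",
    "ca": "Ca", "ca2+": "Ca", "calcium": "Ca",
    "mg": "Mg", "mg2+": "Mg", "magnesium": "Mg",
    "na": "Na", "na+": "Na", "sodium": "Na",
    "k": "K", "k+": "K", "potassium": "K",
    "cl": "Cl", "cl-": "Cl", "chloride": "Cl",
    "so4": "SO4", "so4^2-": "SO4", "so42-": "SO4", "sulfate": "SO4", "sulphate": "SO4",
    "hco3": "HCO3", "hco3-": "HCO3", "bicarbonate": "HCO3",
    "co3": "CO3", "co3^2-": "CO3", "co32-": "CO3", "carbonate": "CO3",
    "no3": "NO3", "no3-": "NO3", "nitrate": "NO3",
    "fe": "Fe", "fe3+": "Fe", "iron": "Fe",
    "mn": "Mn", "mn2+": "Mn", "manganese": "Mn",
}

_MANDATORY = ("site_id", "ph")
_SCALAR_FIELDS = ("temp", "ec", "tds", "th", "do")


def _canon_header(name: str) -> str | None:
    key = name.strip().lower().replace(" ", "_").replace("²", "2").replace("³", "3")
    key = key.replace("⁻", "-").replace("⁺", "+")
    return _HEADER_ALIASES.get(key)


def read_samples(path: str | Path, aliases: Mapping[str, str] | None = None) -> list[WaterSample]:
    """Read one :class:`WaterSample` per CSV row.

    Header names are matched case-insensitively against the built-in alias
    table (extendable via ``aliases``, mapping raw header → canonical name).
    Errors carry the 1-based data row number.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path)
    extra = {k.strip().lower(): v for k, v in (aliases or {}).items()}
    colmap: dict[str, str] = {}
    for col in df.columns:
        canon = extra.get(col.strip().lower()) or _canon_header(col)
        if canon is not None:
            if canon in colmap.values():
                raise SchemaError(f"duplicate column for field {canon!r} in {path.name}")
            colmap[col] = canon
    canon_cols = set(colmap.values())
    for must in _MANDATORY:
        if must not in canon_cols:
            raise SchemaError(f"missing mandatory column {must!r} in {path.name}")

    samples: list[WaterSample] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 1
        rec: dict[str, object] = {}
        conc: dict[str, float] = {}
        for raw, canon in colmap.items():
            val = row[raw]
            if pd.isna(val):
                continue
            if canon == "site_id":
                rec["site_id"] = str(val)
            elif canon == "date":
                rec["date"] = val if isinstance(val, _date) else pd.to_datetime(str(val)).date()
            else:
                try:
                    num = float(val)
                except (TypeError, ValueError):
                    raise SchemaError(
                        f"{path.name} row {rowno}: non-numeric value {val!r} in column {raw!r}"
                    ) from None
                if canon in ION_KEYS:
                    conc[canon] = num
                else:
                    rec[canon] = num
        try:
            samples.append(WaterSample(conc=conc, **rec))  # type: ignore[arg-type]
        except (ValidationError, SchemaError) as exc:
            raise ValidationError(f"{path.name} row {rowno}: {exc}") from exc
    return samples


def samples_to_frame(samples: Sequence[WaterSample]) -> pd.DataFrame:
    """Flat DataFrame view (one row per sample) in the canonical CSV schema."""
    rows = []
    for s in samples:
        row: dict[str, object] = {"site_id": s.site_id, "date": s.date, "pH": s.ph,
                                  "T": s.temp, "EC": s.ec, "TDS": s.tds, "TH": s.th, "DO": s.do}
        for ion in ION_KEYS:
            row[ion] = s.conc.get(ion, math.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_samples(samples: Sequence[WaterSample], path: str | Path) -> None:
    samples_to_frame(samples).to_csv(path, index=False)


def qa_report_frame(results: Sequence[QAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [r.sample.site_id for r in results],
            "date": [r.sample.date for r in results],
            "cbe_percent": [r.cbe_percent for r in results],
            "pass": [r.pass_flag for r in results],
            "notes": ["; ".join(r.notes) for r in results],
        }
    )


def write_qa_report(results: Sequence[QAResult], csv_path: str | Path, json_path: str | Path | None = None) -> None:
    frame = qa_report_frame(results)
    frame.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = frame.assign(date=frame["date"].astype(str)).to_dict(orient="records")
        Path(json_path).write_text(json.dumps(payload, indent=2))
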