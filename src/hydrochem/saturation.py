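"""Simplified aqueous speciation and mineral saturation indices.

The chain is: molar concentrations → ionic strength → Davies activity
coefficients → free-ion activities → carbonate-system speciation → per-mineral
saturation index SI = log10(IAP) − log10(Ksp) and the CO2 partial pressure
log10 pCO2 = log10({H2CO3*}/K_H).

The model deliberately neglects ion pairing (CaSO4°, CaHCO3+, MgCO3° …),
which a full speciation program includes; for dilute waters (I ≈ 0.01 mol/L)
this shifts SI by at most a few tenths of a unit and never the sign.  pH is
taken as the hydrogen-ion *activity* (what a glass electrode measures).

CO3²⁻ activity defaults to the thermodynamically consistent route
{CO3} = K2·{HCO3}/{H+} because titrated carbonate at pH ≈ 8 is often
over-reported; the measured-CO3 route is available via ``co3_source``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

import pandas as pd

from .errors import ModelRangeError, UndefinedQuantityError
from .samples import ION_CHARGE, IonBalance, MOLAR_MASS, WaterSample

R_KCAL = 1.98720425864083e-3  # gas constant, kcal/(mol·K)
T_REF_K = 298.15


@dataclass(frozen=True)
class ActivityModel:
    """Davies activity model: log10 γ = −A·z²·(√I/(1+√I) − b·I), valid I ≤ 0.5."""

    a_debye: float = 0.5092  # at 25 °C
    davies_b: float = 0.3
    i_max: float = 0.5

    def gamma(self, z: int, ionic_strength: float) -> float:
        if ionic_strength < 0:
            raise ModelRangeError(f"negative ionic strength {ionic_strength}")
        if ionic_strength > self.i_max:
            raise ModelRangeError(
                f"Davies model invalid at I = {ionic_strength:.3g} mol/L (max {self.i_max})"
            )
        s = math.sqrt(ionic_strength)
        log_g = -self.a_debye * z * z * (s / (1.0 + s) - self.davies_b * ionic_strength)
        return 10.0 ** log_g


#: log10 equilibrium constants at 25 °C and standard reaction enthalpies
#: (kcal/mol, phreeqc.dat conventions) for the optional van 't Hoff correction.
#: Minerals are written as dissolution reactions to free ions.
@dataclass(frozen=True)
class EquilibriumConstants:
    log_ksp: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType(
            {
                "calcite": -8.48,
                "aragonite": -8.336,
                "dolomite": -17.09,
                "gypsum": -4.58,
                "anhydrite": -4.36,
                "halite": 1.570,
            }
        )
    )
    delta_h: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType(
            {
                "calcite": -2.297,
                "aragonite": -2.589,
                "dolomite": -9.436,
                "gypsum": -0.109,
                "anhydrite": -1.710,
                "halite": 0.918,
                "K_H": -4.776,   # CO2(g) = CO2(aq)
                "K1": 1.737,     # H2CO3* = H+ + HCO3-
                "K2": 3.561,     # HCO3- = H+ + CO3--
            }
        )
    )
    log_k_h: float = -1.468
    log_k1: float = -6.352
    log_k2: float = -10.329

    def log_k_at(self, name: str, log_k25: float, temp_c: float | None) -> float:
        """van 't Hoff-corrected log10 K at ``temp_c`` (°C); 25 °C value if None."""
        if temp_c is None or name not in self.delta_h:
            return log_k25
        t_k = temp_c + 273.15
        dh = self.delta_h[name]
        return log_k25 - dh / (math.log(10.0) * R_KCAL) * (1.0 / t_k - 1.0 / T_REF_K)


#: mineral → stoichiometry of the dissolution reaction over free-ion species
MINERAL_REACTIONS: Mapping[str, Mapping[str, int]] = MappingProxyType(
    {
        "calcite": {"Ca": 1, "CO3": 1},
        "aragonite": {"Ca": 1, "CO3": 1},
        "dolomite": {"Ca": 1, "Mg": 1, "CO3": 2},
        "gypsum": {"Ca": 1, "SO4": 1},
        "anhydrite": {"Ca": 1, "SO4": 1},
        "halite": {"Na": 1, "Cl": 1},
    }
)

MINERALS = tuple(MINERAL_REACTIONS)


@dataclass(frozen=True)
class SpeciationResult:
    ionic_strength: float
    gamma: Mapping[int, float]
    activities: Mapping[str, float]
    si: Mapping[str, float]
    log_pco2: float | None
    co3_source: str


def ionic_strength(sample: WaterSample, balance: IonBalance | None = None) -> float:
    """I = ½ Σ cᵢ zᵢ² (mol/L) over the nine major ions, from mg/L inputs."""
    total = 0.0
    for ion, z in ION_CHARGE.items():
        c_mg = sample.conc.get(ion, 0.0) or 0.0
        c_mol = c_mg / MOLAR_MASS[ion] / 1000.0
        total += c_mol * z * z
    return 0.5 * total


def speciate(
    sample: WaterSample,
    model: ActivityModel | None = None,
    constants: EquilibriumConstants | None = None,
    co3_source: str = "derived-from-K2",
    temperature_correction: bool = False,
) -> SpeciationResult:
    """Full speciation for one sample.

    ``co3_source`` is ``"derived-from-K2"`` (default) or ``"measured"``.
    ``temperature_correction`` applies the van 't Hoff adjustment to every
    equilibrium constant using the sample temperature; by default the 25 °C
    constants are used regardless of the field temperature.
    """
    if co3_source not in ("derived-from-K2", "measured"):
        raise ValueError(f"unknown co3_source {co3_source!r}")
    model = model or ActivityModel()
    k = constants or EquilibriumConstants()
    temp = sample.temp if temperature_correction else None

    ion_strength = ionic_strength(sample)
    gammas = {z: model.gamma(z, ion_strength) for z in (1, 2)}

    molal = {ion: (sample.conc.get(ion, 0.0) or 0.0) / MOLAR_MASS[ion] / 1000.0
             for ion in ION_CHARGE}
    act: dict[str, float] = {ion: gammas[ION_CHARGE[ion]] * m for ion, m in molal.items()}
    act["H"] = 10.0 ** (-sample.ph)

    log_k1 = k.log_k_at("K1", k.log_k1, temp)
    log_k2 = k.log_k_at("K2", k.log_k2, temp)
    log_kh = k.log_k_at("K_H", k.log_k_h, temp)

    log_pco2: float | None = None
    if act["HCO3"] > 0:
        # {H2CO3*} = {HCO3}{H+}/K1 ;  pCO2 = {H2CO3*}/K_H
        act["H2CO3*"] = act["HCO3"] * act["H"] / 10.0 ** log_k1
        log_pco2 = math.log10(act["H2CO3*"]) - log_kh
        if co3_source == "derived-from-K2":
            act["CO3"] = 10.0 ** log_k2 * act["HCO3"] / act["H"]
    elif co3_source == "derived-from-K2":
        act["CO3"] = 0.0

    si: dict[str, float] = {}
    for mineral, stoich in MINERAL_REACTIONS.items():
        log_iap = 0.0
        defined = True
        for species, nu in stoich.items():
            a = act.get(species, 0.0)
            if a <= 0:
                defined = False
                break
            log_iap += nu * math.log10(a)
        if defined:
            si[mineral] = log_iap - k.log_k_at(mineral, k.log_ksp[mineral], temp)
    return SpeciationResult(
        ionic_strength=ion_strength,
        gamma=gammas,
        activities=act,
        si=si,
        log_pco2=log_pco2,
        co3_source=co3_source,
    )


def carbonate_speciation(sample: WaterSample, **kwargs) -> tuple[float, float, float, float | None]:
    """Carbonate-system activities ({HCO3-}, {CO3--}, {H2CO3*}) and log10 pCO2.

    Raises :class:`UndefinedQuantityError` when bicarbonate is absent, which
    leaves the CO2 partial pressure undefined.
    """
    r = speciate(sample, **kwargs)
    if r.log_pco2 is None:
        raise UndefinedQuantityError(f"{sample.site_id}: pCO2 undefined (HCO3 = 0)")
    return r.activities["HCO3"], r.activities["CO3"], r.activities["H2CO3*"], r.log_pco2


def saturation_index(sample: WaterSample, mineral: str, **kwargs) -> float:
    """SI = log10(IAP/Ksp) for one mineral (see :func:`speciate` for options)."""
    if mineral not in MINERAL_REACTIONS:
        raise UndefinedQuantityError(
            f"unknown mineral {mineral!r}; registered: {', '.join(MINERALS)}"
        )
    result = speciate(sample, **kwargs)
    if mineral not in result.si:
        raise UndefinedQuantityError(
            f"{sample.site_id}: SI({mineral}) undefined — a reactant activity is zero"
        )
    return result.si[mineral]


def speciation_table(samples: Sequence[WaterSample], **kwargs) -> pd.DataFrame:
    """Per-sample speciation export: I, log pCO2, SI per mineral."""
    rows = []
    for s in samples:
        r = speciate(s, **kwargs)
        rows.append(
            {
                "site_id": s.site_id,
                "ionic_strength": r.ionic_strength,
                "log_pco2": r.log_pco2,
                **{f"si_{m}": r.si.get(m) for m in MINERALS},
                "co3_source": r.co3_source,
            }
        )
    return pd.DataFrame(rows)
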