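# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
known limits of the approach.

## Units and ion algebra

Samples carry concentrations in mg/L (pH dimensionless, T in °C, EC in
µS/cm). Milliequivalents use fixed equivalent weights (IUPAC molar mass /
charge): Ca 20.04, Mg 12.153, Na 22.99, K 39.098, Cl 35.453, SO₄ 48.03,
HCO₃ 61.017, CO₃ 30.005, NO₃ 62.004 g/eq. They are overridable for
sensitivity work but should not normally be touched.

The charge-balance error includes NO₃⁻ among the anions, matching the anion
set of the chloro-alkaline indices. The QA gate defaults to ±5 % and flags
rather than excludes; exclusion is a config switch because dropping samples
is an analyst's decision, not a library default.

Total hardness is carried as a **measured** input. The packaged table's TH
values (~110 mg/L) are irreconcilable with CaCO₃-equivalent hardness
computed from its own Ca/Mg (≈200 mg/L via 2.497·Ca + 4.115·Mg); the
convention behind the measured numbers is unstated, so indices always use
the measured column and the computed formula is exposed only as a flagged
utility.

## Facies diagnostics

Piper percentages are computed on meq with NO₃ folded into the Cl vertex
(standard trilinear practice) so each triangle closes to 100 %. The facies
label lists every vertex holding ≥20 % of its triangle, cations first,
descending — the labeling rule is this package's choice; the ≥20 % cut is
the common convention. Chadha's x uses (Ca+Mg)−(Na+K) over Σcations and y
uses (HCO₃+CO₃)−(Cl+SO₄) over Σanions, with NO₃ in the normalising sum only
(configurable). Gibbs ratios are computed on meq (a mg-basis switch exists);
the boomerang envelope is encoded as documented constants — TDS bands
70–10 000 mg/L for rock-weathering, with precipitation below and evaporation
above at ratios > 0.5 — because the classic diagram is drawn, not tabulated.

The chloro-alkaline indices use the Schoeller numerator Cl − (Na + K). A
printed variant with (Na − Ca) circulates in parts of the literature; it is
available behind `numerator="printed"` for audit but inverts the sign on
calcium-rich bicarbonate waters and is not the index Schoeller defined.

## Saturation model

The speciation chain is deliberately minimal: molarities → ionic strength →
Davies coefficients (A = 0.5092 at 25 °C, b = 0.3, enforced validity
I ≤ 0.5 mol/L) → free-ion activities → carbonate system from pH. pH is
treated as hydrogen-ion activity. CO₃²⁻ defaults to the K₂-derived route
({CO₃} = K₂{HCO₃}/{H⁺}) because titrated carbonate at pH ≈ 8.1 is typically
over-reported relative to carbonate-system equilibrium; the measured route
is selectable and the sign conclusions hold under both.

log₁₀ Ksp at 25 °C: calcite −8.48, aragonite −8.336, dolomite −17.09,
gypsum −4.58, anhydrite −4.36, halite +1.570; carbonate constants
log K_H = −1.468, log K₁ = −6.352, log K₂ = −10.329. These are the standard
phreeqc.dat values, which is also where the optional van 't Hoff reaction
enthalpies come from. Constants default to 25 °C regardless of field
temperature; enabling the correction at the campaign's 14–16 °C moves each
SI by at most ≈0.45 log units (dolomite, the largest |ΔH|) and never changes
a sign on the reference waters.

Ion pairing (CaSO₄⁰, CaHCO₃⁺, MgCO₃⁰, …) is neglected. Versus a full
speciation program this biases SI by a few tenths of a unit on dilute water
(I ≈ 0.0075 mol/L here); conclusions are therefore reported at sign level,
and no redox or Fe-phase saturation is attempted.

## Drinking water quality index

The weighted-arithmetic form with `Σwᵢ = 1` by construction. Two
documented resolutions of inconsistencies in the published worked table:
the Mn limit is 0.1 mg/L (the value consistent with the published weights
and ratings; the 0.05 appearing in one cell is treated as a typo and kept
available by config), and pH is rated as plain Cᵢ/Sᵢ·100 with no
ideal-value-7 offset, exactly reproducing the published pH rating.
Temperature and DO are not index parameters. Classification bands are the
standard convention (<50 excellent, 50–100 good, 100–200 poor, 200–300 very
poor, ≥300 unfit), boundary scores taking the lower band.

Because weights scale with 1/Sᵢ, Fe (limit 0.3) and Mn (limit 0.1) carry
~98 % of the weight; the index is effectively a trace-metal index with
major-ion seasoning. That is a property of the method, not a bug.

## Irrigation indices

SAR is implemented without the ×100 factor that some printed formula tables
carry: the factor is dimensionally spurious and incompatible with the
universally used SAR class bands (a flag reproduces the literal variant).
The IWQI follows the class-interpolation equation and published class table
exactly, with the published weights (EC 0.211, Na 0.204, HCO₃ 0.202,
Cl 0.194, SAR 0.189); the AHP derivation of those weights is not
reproducible from available sources, so they are configuration. Values
below the lowest class bound interpolate from zero up to that bound within
the 0–35 band; values at or above the top bound rate 0. A consequence worth
knowing: very dilute water rates poorly on Na and Cl (both below their best
classes), so clean rivers can score "high restriction" — the scale rewards
mid-range composition, and the classical indices (SAR, Na%, SSP, PS, RSC)
are the better guide for such waters.

## Health risk

The USEPA oral-ingestion chain with cohort defaults: adult IR 2.2 L/d,
ED 70 y, BW 70 kg, AT 25 550 d; child IR 1.8 L/d, ED 6 y, BW 15 kg,
AT 2 190 d; EF 350 d/y; RfD Mn 0.024, Fe 0.7, NO₃ 1.6 mg/kg/d. Since
ED·365 = AT, the CDI coefficient per unit concentration is 0.030137 (adult)
and 0.11507 (child), fixing the child:adult HQ ratio at 3.82. (A factor of
~2.1 sometimes quoted for child excess risk is not derivable from these
parameters; this package reports the parameter-exact 3.82.) Dermal and
inhalation routes are out of scope — the ingestion equations are the only
ones parameterised.

Monte Carlo: concentrations get a truncated normal fitted to the supplied
values (lognormal selectable), bounded below at zero; exposure factors use
assumed CVs — IR 20 %, BW 15 %, EF 5 % (EF also capped at 365 d/y) — with
ED, AT and RfD fixed. These spreads are assumptions, fully config-driven.
Each element × cohort stream is seeded from (seed, CRC32 of the name), so
results are independent of call order and bit-reproducible. Default 10 000
iterations.

## Multivariate stage

z-scores use the n−1 denominator. Significance flags come from the
two-tailed t test on r. PCA eigendecomposes the correlation matrix, retains
eigenvalues > 1, and rotates with varimax under Kaiser normalisation
(tolerance 1e−8, ≤1000 sweeps); component signs are fixed by making each
component's largest-magnitude loading positive, and rotated components are
ordered by explained variance. Clustering is Ward linkage on Euclidean
distances between variable z-score profiles (samples-mode available), with
Newick export for the dendrogram.

The reference campaign's published loading and correlation tables were
computed on raw data that is not distributed, so this stage is validated by
construction instead: parameter recovery on synthetic campaigns with
planted factor blocks and variable clusters, plus the site-mean Na–Cl
correlation, which is checkable from the packaged table.

## Synthetic campaign generator

The generator emulates the study design the analysis assumes: 7 sites,
85 samples (12 per site, 13 at S1), monthly dates, site means equal to the
packaged table, draws from a latent-factor model and truncated to the
campaign's printed parameter ranges (pH 7.6–8.6, EC 360–680 µS/cm,
TDS 199–370, Ca 39–68, Mg 12–24, Na 11–25.5, K 0.1–4, Cl 15–40, SO₄ 27–51,
HCO₃ 125–255 mg/L; CO₃, NO₃, Fe, Mn envelopes are assumptions). A single
shared "salinity" factor with loadings 0.7–0.95 on the covarying majors
(Na and Cl highest, matching the strongest observed pair) reproduces the
dense positive inter-ion correlation block; pH, CO₃, Fe and Mn stay mostly
independent. Within-site CVs are assumed at 5–15 % by parameter — the
campaign published means and ranges, not variances.

Two deterministic post-steps: per site and parameter, the latent shocks are
mean-centered so each site's sample mean hits its target exactly (the
printed table states means, not a sampling distribution); and when a draw's
CBE leaves ±5 %, its HCO₃ is re-solved to electroneutrality. Seasonal
trends, spatial autocorrelation, detection-limit censoring and
measurement-error structure are **not** modeled — so passing tests on
synthetic campaigns demonstrates pipeline correctness under the assumed
correlation structure, not robustness to real-data pathologies.

## Numerical choices and degenerate inputs

Ratios with zero denominators are returned as flagged undefined values,
never silent infinities. Zero ion sums make facies and CBE undefined
(errors). Davies refuses I > 0.5 mol/L. The IWQI clamps ratings to
[0, 100]. DWQI class boundaries go to the lower band; the RSC 1.25 boundary
goes up (to "doubtful"), reading "less than 1.25 acceptable" exclusively.
CSV output from the pipeline is serialised at 6 significant digits; JSON
keeps full precision; library returns are never rounded.

## Known limitations

- No ion pairing or redox in the saturation model (see above).
- The IWQI scale punishes dilute waters by design; interpret alongside the
  classical indices.
- Exposure-factor spreads in the Monte Carlo layer are assumptions.
- The generator's one-factor default cannot reproduce fine structure such
  as the weak, sign-mixed Fe correlations seen in real campaigns; plant
  extra factors via `CampaignConfig.loadings` when that matters.
- Problem sizes in the shipped tests and scripts follow the reference
  campaign (7 sites, 85 samples, 10 000 Monte Carlo iterations).
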