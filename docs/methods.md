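# Methods

## Scope and model

`sedrisk` computes point-estimate (deterministic) contamination and
risk measures for heavy metals in river sediments.  The measured input
is a table of per-sample element concentrations (mg/kg dry weight) with
site, zone (upper/lower reach), month and replicate metadata.  All
downstream quantities are deterministic functions of that table and of
four configuration tables: geochemical backgrounds, toxic response
factors, receptor exposure parameters, and dose–response constants.
There is no probabilistic (Monte-Carlo) exposure modelling and no
fish-consumption pathway; both are deliberate non-goals.

By default, site-level indices and doses are computed on **site-mean**
concentrations.  Which statistic feeds the exposure concentration (site
mean, zone mean, per-sample) is a genuine modelling choice; the
grouping is exposed (`per={sample|site|zone}`) with site means as the
default because sites are the study's reporting unit.

## Reference tables

- **Backgrounds.**  Two baselines ship built-in: the Taylor & McLennan
  upper-continental-crust averages and the Turekian & Wedepohl (1961)
  average shale, 13 elements each.  Every contamination factor divides
  by one of these; baselines are selectable per run and user files of
  the same YAML shape are accepted.  Validation rejects non-positive
  values and unknown element symbols.
- **Toxic response factors** (dimensionless): Hakanson-lineage values —
  Hg 40, Cd 30, As 10, Sb 7, Cu/Pb/Ni 5, Cr/V 2, Zn/Mn/Mo 1.  The
  values for Ni, Sb, V, Mn and Mo postdate Hakanson's original list and
  follow common sediment-risk usage; all are configurable.
- **Exposure profiles** (EPA RAGS-style defaults): adult ABW 70 kg, IR
  100 mg/day, IHR 20 m³/day, SA 5700 cm², SAF 0.07 mg/(cm²·day), ED
  24 y; child ABW 15 kg, IR 200 mg/day, IHR 10 m³/day, SA 2800 cm², SAF
  0.2 mg/(cm²·day), ED 6 y; both EF 350 days/y, PEF 1.36×10⁹ m³/kg, CFU
  10⁻⁶ kg/mg, DAF 0.03 for As and 0.001 otherwise.  Averaging times:
  AET_nc = ED×365 (so ED cancels from non-carcinogenic doses) and
  AET_ca = 70×365 days (lifetime).  These conventions are encoded in the
  config, not the code, and every computed dose is a function of the
  config.
- **Dose–response constants** (IRIS/RSL-lineage values as commonly used
  in sediment studies): per-element RfD by route, oral slope factor,
  inhalation unit risk, and gastrointestinal absorption fraction
  (GIABS).  The dermal RfD is derived as RfD_ing × GIABS.  IUR values
  are stored pre-converted to (mg/kg/day)⁻¹ assuming a 70 kg adult
  breathing 20 m³/day (unit risk per µg/m³ × 70/20 × 1000), so the
  inhalation risk is a plain product CDD_inh × IUR.

A symbol note: the mass unit conversion factor (kg/mg) in the dose
equations is called *Cf* in parts of the exposure literature, colliding
with the contamination factor.  This package always names the
conversion factor `CFU`; `Cf` is only ever the contamination factor.

## Element scopes

Twelve elements enter the contamination indices (Cu, Cr, Fe, Mn, Mo,
Ni, Pb, V, Zn, Sb, As, Cd); Hg is carried in the data model and the
generator but excluded from the default index set.  The ecological risk
set defaults to the ten of those with defensible published toxic
response factors — {As, Cd, Cr, Cu, Mn, Ni, Pb, Sb, V, Zn}, i.e. the
twelve minus Fe and Mo; Fe has no meaningful toxicity factor and
serves as the EF reference element instead.  Health risk defaults to
the five priority metals {As, Cd, Cr, Ni, Pb}.  All three sets are
configuration lists, because reasonable studies differ on exactly which
elements carry which index.

## Classification conventions

Published band definitions mix strict and non-strict inequalities and
rarely state closure.  The conventions here, each honoured literally
where a strict form is standard, and each pinned by a boundary unit
test:

| quantity | bands |
|---|---|
| Cf | `< 1` low; `[1,3)` moderate; `[3,6)` high; `>= 6` very high |
| Igeo | class 0 `<= 0`, then unit-width classes `(k-1, k]`, class 6 `> 5` |
| EF | anthropogenic iff `> 1.5` (strict) |
| PLI | contaminated iff `> 1`; secondary critical-site flag `> 1.3` |
| mCd | `< 1.5` nil/very low, then doubling bands (Abrahim & Parker) |
| RI | `<= 95` low; `(95,190]` moderate; `(190,380]` considerable; `> 380` very high |
| HI | `> 1` possible chronic adverse effect (strict); `HI = 1` remains insignificant |
| TCR | `< 1e-6` no significant risk; `[1e-6, 1e-4]` acceptable; `> 1e-4` unacceptable |

A zero sample concentration makes Igeo −∞; it is reported with the
sentinel category "below scale" rather than propagating −∞ into band
arithmetic.

## Site Ranking Index

The SRI formula (`W = Σn/Σi`, `SRI = W/S × 100`) is under-determined in
the literature that uses it: the population over which contaminant
ranks are taken is rarely stated.  Ranking each site's S contaminants
internally is degenerate — ranks 1..S always sum to Σi, forcing
W = 1 and SRI = 100/S for every site.  This package therefore ranks all
(site, contaminant) values **pooled across the site collection**, once
under Cf and once under Igeo (average ranks on ties, averaged between
the two orderings), which discriminates sites as the index intends: a
site whose contaminants occupy the top of the pooled ordering scores
high.  A lone site whose contaminants occupy exactly positions 1..S
still gives W = 1.  The convention is isolated in one function
(`pooled_average_ranks`) so alternates can be swapped, and the
implementation is guarded by a brute-force comparison-counting oracle
in the tests.  Site categories use median ± sample SD of the SRI
collection (low < median−SD; moderate [median−SD, median); high
[median, median+SD]; severe > median+SD); when all sites tie, SD = 0
and every site falls on the closed median band ("high") — a documented
degenerate case.

When Cf and Igeo are computed against the same background, their
orderings coincide (Igeo is a monotone transform of Cf) and the rank
average is redundant; it matters only for user-supplied rankings built
from different baselines.

## Dermal carcinogenic risk

The conventional carcinogenic chain multiplies each lifetime-averaged
dose by a route potency: SF (oral), IUR (inhalation).  For the dermal
route the standard practice is the dermal slope factor SF/GIABS, which
is the default here (`dermal_mode="giabs"`); a plain `CDD × SF` variant
is selectable.  Elements lacking a slope factor or unit risk simply
contribute no carcinogenic term for that route rather than erroring.

## Synthetic survey generator

Only zone-level summary statistics (mean and SD per element, two zones)
are available for the study design the generator emulates, so it is
moment-matched at the zone level: concentrations are lognormal with
location `ln(m²/√(m²+s²))` and scale² `ln(1+s²/m²)`, which has exactly
mean m and SD s.  The lognormal is the natural model for nonnegative,
right-skewed geochemical concentrations (several elements here have
SD ≈ mean, e.g. As and Zn upstream); a zero SD degenerates to a point
mass, and a truncated-normal alternative is selectable (only
approximately moment-matched, since truncation at zero shifts the
moments).  The default survey is 6 sites × 2 months × 1 replicate
(N = 6 per zone), matching the emulated design's group sizes.  An
optional mean-one lognormal site effect (`site_effect_sd`) adds
within-zone heterogeneity; it defaults to 0 so zone-moment tests are
clean.  All draws are made from one `numpy` generator seeded by the
spec, in a fixed (site, element) order, so a fixed seed gives
bit-identical tables.

What the generator does **not** emulate: spatial autocorrelation along
the river, seasonal/hydrological dynamics, inter-element correlation
(each element is drawn independently), and genuine per-site targets
(zone parameters are shared by the three sites of a zone).  Tests that
pass on this synthetic data therefore validate the computational chain
and its statistical conventions, not any claim about the real river.

## Zone comparison

Between-zone differences use a two-sided rank-sum test.  For combined
n ≤ 20 the p-value is exact by full enumeration of all C(n, n1) group
splits; ties are handled through average ranks, and the null U
distribution's symmetry about n1·n2/2 gives the two-sided tail.  (The
enumeration is implemented here because library exact methods decline
tied data; on tie-free inputs it agrees with the library's exact method
to 1e-12, which the tests assert.)  Larger samples use the
tie-corrected normal approximation.  Raw p-values are reported by
default; a Holm-adjusted column is available behind a flag.

## Numerical choices

- PLI is computed as `exp(mean(log Cf))`; a zero Cf raises rather than
  silently producing 0.
- Exported tables and JSON format floats to 6 significant digits so
  rerun bundles are byte-identical.
- Sample SD (n−1) everywhere; a single observation reports SD 0.
- Values below the limit of quantification (cells written `<0.01`) are
  substituted by LOQ/2 by default; `loq`, `zero` and `drop` policies
  are selectable.  Missing values stay missing and are excluded
  per-element from means — never treated as zero.
- The worked end-to-end fixture uses concentrations whose Cf values are
  exactly representable off band edges (e.g. Cd 0.35 → Cf 3.5), so
  hand-computed categories are stable under binary floating point.

## Problem sizes

The default test suite and the acceptance script run the survey at its
natural size (12 samples), the generator checks at 10,000 draws for
moment recovery and ~1,000 per zone for ordering checks, the dose
oracle at 1,000 random parameter draws, and exact rank-sum enumeration
up to combined n = 8 in the oracle comparisons (the implementation
itself enumerates up to n = 20).  Everything completes in well under a
minute on one CPU.

## Known limitations

- Point estimates only; no uncertainty propagation from the exposure or
  dose–response tables.
- The dose–response and toxic-response defaults are literature
  conventions, not jurisdictional values; results scale directly with
  these configs and should be re-run with local values for regulatory
  use.
- The SRI convention above is one defensible reading of an
  under-specified index; cross-study SRI comparisons should verify the
  ranking population matches.
- PCA, clustering, heatmaps and GIS/spatial modelling are out of scope;
  the exported matrices support any external plotting tool.
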