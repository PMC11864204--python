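# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations behind `nibam`.

## Bioavailability model structure

All three taxon models (average invertebrate, algae, fish) share the gBAM
form: the free-ion L(E)C50 equals `10^-(Q50 + S_pH-term)` times a cation
competition factor `1 + Σ K_CatBL·{Cat²⁺}`. The pH term is **cumulative and
piecewise linear**: each model carries an ordered list of contiguous pH
segments `(lower, upper, slope)`, and the exponent adds
`slope × (min(pH, upper) − lower)` for every segment below the water's pH.
This anchoring guarantees continuity of the predicted toxicity across
segment breakpoints (the high-pH slope applies only to the pH excess above
the breakpoint, mirroring the two-step normalization used for chronic Ni
models). A naive application of the high slope to absolute pH would
introduce a jump at the breakpoint and is rejected by construction. For the
single-segment fish model the segment is anchored at the lower
applicability bound; the anchor convention is immaterial because the
dataset-calibrated Q50 absorbs any constant offset.

Parameter sets (`src/nibam/data/models.json`):

| model | log K_CaBL | log K_MgBL | S_pH segments | pH window | hardness (mg CaCO₃/L) |
|---|---|---|---|---|---|
| d_magna | 3.10 | 2.47 | 0 (5.7–8.1) | 5.7–8.1 | 6.2–292 |
| d_pulex | 4.20 | 3.60 | 0 (5.6–8.3) | 5.6–8.3 | 16–161 |
| c_dubia | 3.30 | 3.30 | 0 (6.3–8.1) | 6.3–8.1 | 15–253 |
| avg_invertebrate | 3.80 | 3.32 | 0 (5.6–8.0), 1.00635 (8.0–8.9) | 5.6–8.9 | 6.2–339 |
| algae | — | 3.30 | 0.143 (5.7–8.2), 0.906 (8.2–8.7) | 5.7–8.7 | 6.3–315 |
| fish | 3.60 | 3.60 | 0.324 (5.5–8.8) | 5.5–8.8 | 12–290 |

The average invertebrate constants derive from the three cladoceran models
by averaging on the **linear** K scale (`log10(mean(10^x))`), which gives
3.80 (Ca) and 3.32 (Mg) at two decimals; the high-pH slope 1.00635 is the
arithmetic mean of the two published component slopes (1.095, 0.9177),
conventionally reported as 1.006. The algae model's Mg competition is
applied over its full pH range; Ca/Mg competition is assumed
pH-independent above the breakpoint (an explicit model assumption that
available data cannot test). Taxon assignment: algae → algae model; fish
and amphibians → fish model; all invertebrates **and plants** → average
invertebrate model (cross-species evaluations for plants are ambiguous,
and the invertebrate model was the better performer where a difference was
observable).

Direction 1 (observation → Q50) is the exact algebraic inverse of
Direction 2 (Q50 → prediction); the round trip holds to 1e-12 relative and
is property-tested. Applicability: Direction-1 inputs outside a model's
window are screened out of retained data; Direction-2 target waters outside
the combined window (pH 5.7–8.7, hardness 12–290 mg CaCO₃/L) yield a
warning-tagged result, not a failure, so regulatory users can see exactly
which waters are extrapolations.

## Speciation engine

Humic speciation codes are not reproduced here. Instead `chemistry`
exposes a stateless engine interface with two implementations:

* **ReferenceEngine** — inorganic equilibria of Ni, Ca and Mg with OH⁻,
  CO₃²⁻, HCO₃⁻, SO₄²⁻ and Cl⁻, using a versioned table of
  infinite-dilution log K values (NIST-style critical constants, 25 °C;
  `data/stability_constants.json`) and Davies activity corrections
  (A = 0.509). The carbonate system is partitioned from DIC at fixed pH;
  DIC, when absent, is derived from pH and alkalinity under an open-system
  convention (charged carbonate species set by carbonate alkalinity,
  CO₂(aq) fixed by atmospheric pCO₂, so zero alkalinity leaves only
  atmospheric CO₂). Ca/Mg/SO₄ ligand depletion is solved by fixed-point
  iteration; ionic strength by a damped outer loop. Ni is treated as a
  trace metal for the *ligand pools* (Ni complexation does not deplete
  SO₄/CO₃), while the Ni mass balance itself — including a single-site 1:1
  DOC binding term — is closed in closed form, so Σ(Ni species) equals
  dissolved Ni to machine precision (the 0.1% mass-balance invariant is
  property-tested). DOC binding uses a *documented stand-in*
  parameterization (conditional log K 4.5 against free Ni²⁺ activity,
  6e-6 mol sites per mg active organic matter, 65% active fraction): it
  reproduces the qualitative role of DOC (free fraction strictly
  decreasing in DOC; ~70% bound at DOC 20 mg/L in moderately hard water)
  but is **not** a humic-ion binding model, and results carry the engine id
  `reference_davies_v1` as provenance. DOC = 0 bypasses organic binding.
* **ExternalActivityEngine** — adapter for externally computed free-ion
  activity tables (e.g. output of a humic speciation code), passing through
  the pipeline identically to internally computed results.

The inverse map (free Ni²⁺ activity → dissolved Ni) is bracketed Brent
root-finding on the strictly monotone forward map (rtol 1e-13; round trip
verified to 1e-6 over the full chemistry window). Temperature is accepted
on `WaterSample` but constants are held at 25 °C (no van 't Hoff
correction by default — the source models are silent on temperature).
Counter-ions of the dosed Ni salt are not tracked.

## Data screening

Records are annotated (never destroyed) by four ordered rules: total-basis
values accepted only in artificial media (there total = dissolved);
taxon-specific acute duration windows (vertebrates 48–96 h with 96 h
nominal — the published window contains an evident typo; amphipods
48–168 h; insects/annelids/ostracods ≤ 96 h; cladocerans 48 h; molluscs
96 h, glochidia 48 h; anostraca 24 h; algae 72 h; plants 96–168 h);
minimum chemistry (pH, DOC, and Ca or hardness reported); and the assigned
model's applicability window. Human reliability judgements are a
pre-screened boolean input, not inferred. Chemistry completion fills Ca/Mg
from hardness at a 3:1 molar ratio, DIC from pH + alkalinity, and sets
DOC = 0 for artificial media without added organic matter, recording the
provenance of every filled field. Screening is idempotent and each
rejected record carries exactly one machine-readable reason code. When a
mollusc record lacks a life-stage column the adult/juvenile 96-h window is
used.

## Performance metrics

Observed and predicted L(E)C50s are compared on the log10 scale. r² is
`1 − SSR/SST`, clamped to 0 when the model underperforms the dataset-mean
null model, and reported as missing when the observed vector is constant
(SST = 0). FA is the fraction of predictions within 2-fold,
boundary-inclusive (with a 1e-9 guard so an exactly-2-fold prediction
counts regardless of rounding). The residual score per toxicity-modifying
factor is `RS_f = 1 − |Pearson r(residuals, f)|`, averaged arithmetically
into Tot RS over the factors present (pH and DOC raw, Ca and Mg as free-ion
activities); this is a transparent stand-in preserving the published
semantics (1 = unbiased, bounded [0, 1]) — published Tot RS values are
therefore not comparison targets, only the MPS aggregation
(`mean(r², FA, Tot RS)`, reported to 2 decimals) is. Residual spreads
below 1e-10 log units are treated as unbiased (RS = 1): correlating
machine-precision residuals with anything would be noise. Per-dataset Q50
calibration is the arithmetic mean of Direction-1 Q50s over records with
Ca and Mg each below 3 mmol/L.

## SSD and HC5

Species aggregation happens at the Q50 level: per species, records are
grouped by (endpoint, duration), each group gets an arithmetic-mean Q50,
and the group with the **highest** mean Q50 (most sensitive endpoint, and
for duration multiplicity the most sensitive duration) is carried into the
SSD; life stages are pooled. Normalization to a target water applies
Direction 2 with each species' model and translates back to dissolved Ni,
evaluating the competition activities self-consistently at the predicted
Ni level (the same convention Direction 1 uses, so normalizing a species
to the water of its only record returns that record's value exactly).

Six families are fitted by maximum likelihood to the log10 normalized
values: normal, logistic and Gumbel (location–scale on ℝ), and gamma,
log-normal and Weibull with location fixed at zero — these require
strictly positive log10 values; normalized values ≤ 1 µg/L mark such
families *inapplicable* for that water rather than silently shifting the
data (shifts change quantiles). Normal and log-normal fits use their
closed-form MLEs (identical to the iterative fits). The Anderson–Darling
statistic is computed from the fitted CDF by the standard order-statistic
formula; selection uses the statistic alone, with ties broken by a fixed
preference order (normal, log-normal, logistic, gamma, Weibull, Gumbel)
for determinism. p-values are reported only for the normal/log-normal
families (Stephens' estimated-parameters approximation); other families'
p-values would need family-specific tables and are omitted.

HC5 is `10^(5th percentile)` of the selected fit. The published bootstrap
prescription ("parametric bootstrap … with replacement") is internally
contradictory, so both flavors exist: the **default is nonparametric**
(resample the n species values with replacement, refit the selected family
each time — the family is held fixed across resamples), with a parametric
mode (`parametric=True`: draw size-n samples from the full-data fit)
behind a flag; B = 1000 by default, all randomness from one seed. The
reported HC5-50 is the bootstrap median, per the convention of the
regulatory tables this mirrors; the full-data best-fit HC5 is also
emitted. More than 20% resample fit failures flag the result unreliable.

**Known limitation — CI coverage.** Percentile bootstrap intervals for a
tail quantile at SSD-typical sample sizes undercover: for a normal 5th
percentile at n = 40 the measured coverage of the 90% interval is ≈ 0.83
(nonparametric) and ≈ 0.84 (parametric) rather than 0.90. This is a
property of the interval construction itself, kept because it is the
prescribed construction; treat HC5-5 as an optimistic lower bound.

## Synthetic data generator

`synthetic.generate` emulates the structure of a compiled acute Ni
database: species cycle through a taxon mix covering all three model
groups; per-record test chemistry is sampled inside the combined window
(pH uniform 5.7–8.7, hardness log-uniform 12–290 mg CaCO₃/L, DOC 0 for the
artificial-medium half of records, else uniform 0–20 mg/L); minor ions
follow a reconstituted-water-style recipe (fixed Na/K/Cl backgrounds, SO₄
and alkalinity co-varying with hardness; `data/synthetic_media.json`).
True Q50s are drawn from Normal(5.0, 0.7) — the sd chosen once so the
implied unnormalized L(E)C50 spread matches the ~2.3-log10-unit 5th–95th
percentile range typical of real multi-species acute Ni data. Replicate
noise is multiplicative log-normal with sd log10(2)/1.645 ≈ 0.183 (a
2-fold error at the 95th percentile, the conventional repeatability of
acute tests). Each record's dissolved L(E)C50 is computed exactly through
the forward gBAM + speciation chain before noise, and the truth table
stores each species' Q50 and noise-free dissolved L(E)C50 in a fixed
reference water (pH 7.5, DOC 2 mg/L, hardness 100 mg CaCO₃/L).

What passing synthetic tests do and do not show: they verify the
*machinery* — exact noise-free recovery, unbiased noisy recovery,
normalization round trips, SSD/bootstrap determinism — under idealized
conditions (perfectly known chemistry, log-normal noise, correctly
specified speciation). They cannot validate the bioavailability models or
the DOC-binding stand-in against real organisms or real humic matter;
those claims rest on the published validation datasets, not on this
generator. Test problem sizes (40 species × 3 records; 200 replicate
experiments for coverage; 1000-draw round-trip suites) were chosen so the
Monte-Carlo error of each check is small relative to its acceptance band.
The replicate-coverage simulation runs on the log-sensitivity scale: for a
fixed target water the map from Q50 to log10 dissolved L(E)C50 is
monotone and near-affine (exactly affine at trace Ni without DOC
saturation), and the normal-family bootstrap is equivariant under affine
maps, so coverage on that scale equals coverage on the dissolved scale.

## The seven freshwater scenarios

`synthetic.make_ecoregion_waters` ships the standard European scenario set
(Lake Monate, Rhine, Otter, Teme, Swedish Lake, Ebro, Dutch Ditches) with
their tabulated pH/DOC/hardness, completed by the minor-ion recipe. With
the reference engine these reproduce the expected *ordering* of
site-specific HC5s (soft-water Swedish Lake most sensitive, hard high-DOC
Ditches least); absolute HC5 values additionally depend on the underlying
toxicity database and on the speciation engine, so published threshold
values are not reproduction targets for the reference engine.
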