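# Methods

This note documents the models, unit conventions, numerical choices and
known limitations of `foramphos`, stage by stage.

## Biovolume from 2D measurements

Specimens are measured on stereomicroscope images, so only two or three
outer axes are available per individual. Each species is mapped to the
closest simple solid and its closed-form volume:

| shape              | axes (full lengths, µm) | volume (µm³) |
|--------------------|-------------------------|--------------|
| sphere             | d                       | πd³/6        |
| prolate spheroid   | length, width           | π·l·w²/6     |
| oblate spheroid    | diameter, height        | π·d²·h/6     |
| triaxial ellipsoid | length, width, height   | π·a·b·c/6    |
| elliptic cone      | length, width, height   | π·a·b·h/12   |
| elliptic cylinder  | length, width, height   | π·a·b·h/4    |
| half-ellipsoid     | length, width, height   | π·a·b·c/12   |

All axes are full lengths as measured (diameters, not semi-axes); the
formulas divide internally. For the half-ellipsoid the third axis is
the full diameter of the notional complete ellipsoid, so the dome's
physical height is half of it. Volumes convert to litres at
1 µm³ = 10⁻¹⁵ l and the test suite checks every formula against
numerical integration of elliptical cross-sections to 0.5%.

Two height-inference rules cover shapes whose vertical axis is not
visible in apical view: a fixed species-mean height (133 µm for
*Bolivina spissa*) and a shortest-diameter:height ratio (0.424 for
*Cibicidoides wuellerstorfi*, height = shortest diameter / 0.424). The
species→shape table ships with editable defaults for the measured
species; the two height rules above are calibrated values, the
remaining shape assignments are morphological judgement calls and
should be overridden when better morphometry exists. Unknown species
raise rather than guess.

The cytoplasm (cell) volume is `cytoplasm_fraction × test_volume` with
default 0.75: the internal test volume is taken as 75% of the outer
test volume and assumed completely filled with cytoplasm. Reported
per-species "mean cell volume" therefore already includes this factor.

## Extract quantification

Per-individual content: `content = c·V·10⁶/n` pmol ind⁻¹ from the
autoanalyser concentration `c` (µmol l⁻¹), extract volume `V` (l,
default 3 ml) and pooled count `n` (1–75 depending on body size).
Intracellular concentration: `C = content·10⁻⁹/V_cell` mM.

Design choices:

* Species means are **means of per-sample values** (mean of ratios).
  The pooled-ratio alternative (total content / total volume) differs
  whenever sample sizes vary, and does not reproduce the multi-sample
  reference rows; single-sample rows are plain ratios either way.
* Standard deviations use the n−1 denominator and are omitted for
  single samples.
* Procedural-blank correction is available (`max(c − mean(blanks), 0)`)
  but **off by default**: in the source protocol the 13 procedural
  blanks served the nitrate channel. Enable it explicitly when blanks
  were run for phosphate.
* Values below the 0.004 µmol l⁻¹ detection limit are flagged, never
  censored or zeroed — censoring would bias low-content species.
* Display rounding mirrors the reference table (integer pmol, 0.1 mM);
  unrounded values are carried alongside.

## Assemblage stocks and budgets

Station stock: `Σ_n A_n · content_n · 10⁻⁹` mmol m⁻² over living
abundances in ind m⁻², times `10⁻³ ×` molar mass for g m⁻². The molar
mass defaults to 95 g mol⁻¹ (phosphate as measured; configurable).
Abundance dialects (ind per 10 cm³, ind cm⁻², ind cm⁻³) convert
explicitly to ind m⁻² with a logged factor and a layer-depth argument
(default 1 cm).

Content lookup: exact species match first (excluded entries skipped);
otherwise the mean over non-excluded congeners — genus is the first
whitespace token of the binomial; otherwise the species is excluded and
its abundance tallied into an `excluded_share` per station, so the
unaccounted stock can be bounded. The shipped library flags
*Ammonia veneta* excluded: it is the only species measured from
laboratory culture rather than environmental samples. Duplicate
entries for a species (e.g. the same species measured in two regions)
average.

Regional summary: weighted mean `Σwx/Σw` (equal weights by default —
the area-of-influence weights behind published weighted-mean maps are
not part of the main-text record) with s.e.
`sqrt(Σw(x−x̄)²/(Σw·(n−1)))`, reducing to sd/√n for equal weights; a
single station yields s.e. = NaN. Budgets:
`total [t] = mean_stock · area · 10⁻⁶` and
`buffer_days = total/runoff · 365`. The bloom extrapolation converts a
volumetric density over a surface layer:
`ind m⁻² = density[ind cm⁻³] · depth[cm] · 10⁴`, then content × molar
mass × area.

## EDS ratio maps

Cryo-SEM–EDS count maps of frozen-hydrated cell cross-sections violate
the flat-surface/homogeneous-depth assumptions of standard ZAF
quantification, and raw minor-element maps are dominated by the
position-dependent bremsstrahlung continuum. Assuming the background
spectral *shape* is position-independent, the per-pixel
intensity-to-noise ratio

    R(m,n) = I_i(m,n) / (CPS(m,n) − Σ_i I_i(m,n))

uses the out-of-peak continuum (total counts minus all
characteristic-peak counts) as a proxy for the background under the
element's own peak, so R = S_i/B_i + 1 wherever that proxy holds: R ≈ 1
is pure background, R > 1 signal. Numerical choices:

* The denominator sum spans **all** mapped elements by default; a
  `denominator="exclude_target"` flag implements the alternative
  reading that removes only the other elements' peaks. Both are exact
  on phantoms built for the corresponding bookkeeping.
* Pixels with denominator < ε (default ε = 1 count) or with
  CPS < Σ_i I_i (bookkeeping violations) are masked, never clipped;
  every downstream operation carries the mask.
* Median filter: (2r+1)² window (default r = 1, the "one-pixel"
  filter), clipped at image borders, masked pixels excluded from the
  window; verified against a brute-force per-pixel oracle.
* 16-colour LUT: linear bins over the valid range (or a caller-fixed
  range for cross-map comparability), class = ⌊16·(v−lo)/(hi−lo)⌋
  clipped to [0, 15]; the underlying values are never modified; masked
  pixels render transparent. The palette is a fixed 16-entry
  blue→red→white ramp; any fixed palette is equivalent.
* Registration: closed-form least-squares similarity fit (Umeyama) —
  scale, rotation, translation, no shear/warp — from ≥2 control-point
  pairs, via `skimage.transform.SimilarityTransform`, with the residual
  RMS reported. Coincident points are a degenerate-geometry error.
* Image convention: row 0 is the top, x = columns; transforms are in
  pixel units.

Region contrast is estimated from count totals rather than per-pixel
ratios: `k̂ = R̂_in/R̂_out − 1` with `R̂ = ΣI_i/Σ(CPS − ΣI)` over each
region's valid pixels. Because the expected R is constant within a
region under the fixed-background-shape assumption, the totals-based
quotient has negligible small-count bias (the per-pixel mean of ratios
carries an E[1/denominator] bias of order 1/counts), and `k̂` recovers
the injected signal-to-background contrast exactly on noiseless
phantoms and within Poisson error on sampled ones.

## Synthetic data: what it emulates, and what it does not

* **Specimens**: lognormal axis lengths per species (field size
  distributions are right-skewed); truth volumes computed with the same
  closed forms, so recovery is exact by construction — this validates
  plumbing and unit bookkeeping, not the realism of shape assignment.
* **Extractions**: multiplicative Gaussian error (default checks use
  5%) on the noiseless inversion of the content relation — a reasonable
  model of segmented-flow autoanalyser error at these signal levels; it
  does not model carry-over, drift or matrix effects.
* **Assemblages**: by default 135 stations (the station count of the
  densest real survey emulated) × 8 species — 5 measured, 2 unmeasured
  congeners (imputable), 1 unknown genus (excluded) — with iid
  lognormal abundances, µ = ln(2×10⁴) ind m⁻², σ = 1 (median 2×10⁴
  ind m⁻², spanning roughly two orders of magnitude across stations, as
  is typical of shelf assemblage surveys). Contents span the measured
  range. The generator returns the exact per-station stocks, the
  analytic regional mean (lognormal mean e^{µ+σ²/2} × summed contents)
  and the exact sampling s.e. of the regional mean from the lognormal
  variance. Real assemblages have spatial autocorrelation and
  species co-occurrence structure; the generator does not, so passing
  recovery tests demonstrate correct estimation under independent
  sampling, not robustness to survey design.
* **EDS phantoms**: a smooth positive background field (broad Gaussian
  bump, ~2× centre-to-edge) whose per-channel split is fixed — the
  fixed-background-shape assumption made explicit — with disc
  enrichments of stated contrast and optional Poisson sampling; CPS is
  assembled as Σ I_i + out-of-peak continuum, exactly the bookkeeping
  the ratio map inverts. Detector artefacts (peak overlap, pile-up,
  absorption) are not modelled.

Seeding: one master seed, split into named per-generator streams with
`numpy.random.SeedSequence`, so tables regenerate independently and
identically.

## Statistical recovery checks

The coverage-style checks ("estimate within 2 s.e. of truth in ≥95% of
seeded replicates") centre the band on the true parameter and use the
generator's **exact** sampling standard error, which is available
because truth is synthetic. This isolates recovery of the mean from
s.e.-estimation noise: with small per-replicate sample sizes the
sample-s.e. variant is a t-interval with materially lower coverage
(≈91% at n = 8), and for skewed lognormal stocks the estimated s.e.
co-varies with the mean, costing a further ~1% of coverage at n = 135
stations. Both coverage rates are reported by `scripts/acceptance.py`.
The replicate problem sizes (200 assemblage regions, 1,000 extraction
sets, 50 phantoms) keep the full suite in the tens of seconds on one
core while leaving binomial noise on the rates near one percentage
point.

## Known limitations

* Default species→shape assignments beyond the two calibrated height
  rules are placeholders to be overridden with project morphometry.
* Regional means use equal station weights unless weights are given; no
  geostatistical interpolation or kriging is attempted.
* Genus imputation assumes the first name token is the genus and that
  congeners share content scale; synonymies need a user-supplied
  mapping before lookup.
* The ratio map is a background *suppression*, not a quantification:
  R values are not concentrations and are comparable across maps only
  with a fixed LUT range and similar beam conditions.
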