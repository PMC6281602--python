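# Methods

This note records the models implemented in `dielflux`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator can and cannot stand in for.

## Rhythm detection

### Statistic

For a series sampled on a common grid modulo the period (24 h), all
observations sharing a clock phase — replicates and repeated days alike —
form one rank group ("independent" treatment). A candidate rhythm is a peak
phase p and a rise length r (in grid steps); its umbrella ordering runs from
the trough group up to the peak in r steps and back down over the remaining
T − r steps. The score is the peak-known Mack–Wolfe statistic

    A = Σ_{i<j in rise} U(g_i, g_j) + Σ_{i<j in fall} U(g_j, g_i),

where U(a, b) counts pairs x∈a, y∈b with x < y (ties count ½). The full
candidate set is every phase × every rise length 1..T−1 (30 candidates for
T = 6).

### Null distributions

- *Exact regime.* When the number of distinct assignments of the pooled
  observations to the time groups (a multinomial coefficient) is at most
  60,000, the null is computed by full enumeration, ties included. The cap
  is an arrangement-count bound rather than a per-group-size bound because
  the enumeration cost is governed by the former: six groups of three
  replicates already generate ~1.4 × 10⁸ arrangements, far beyond exact
  reach, while the designs where exactness matters (few timepoints, few
  cycles, two-group reductions) fall comfortably under the cap.
- *Normal regime.* Otherwise A is standardised with the closed-form
  Mack–Wolfe null mean and variance (verified in the test suite against the
  enumeration distribution), with the variance deflated by the Kendall tie
  factor (N³ − N − Σ(t³ − t))/(N³ − N); an all-tied series returns p = 1.

### Candidate correction

The 30 candidate orderings are strongly correlated, and a Bonferroni bound
over them is measurably conservative: under the flat null at the default
campaign design the rejection rate at nominal α = 0.05 is ≈ 0.028. The
default correction is therefore a min-p (Westfall–Young) calibration: the
corrected p-value is the null probability that the smallest per-candidate
p-value is at least as small as observed. In the exact regime this
probability comes from the same full enumeration (deterministic and exact);
in the normal regime from 999 label permutations drawn from a fixed internal
stream, so results are reproducible for identical input. Measured size at
α = 0.05 is ≈ 0.05 and the smallest resolvable p is 1/1000. With a single
candidate both corrections reduce to the marginal p-value, so a two-group
single-rise design is exactly the one-sided Mann–Whitney U test.
`correction="bonferroni"` retains the classical conservative bound.

### Dusk-vs-dawn t-test

Pooled-variance two-sample t on per-day dawn and dusk means (replicates
averaged per timepoint first); a campaign with five sampled days per group
gives df = 8. Welch is available. Zero-variance degeneracies are handled
explicitly: identical groups → (t = 0, p = 1); distinct constant groups →
(t = ±∞, p = 0).

## Quantification

Concentration = (area / RF) × (IS added / IS recovered) / volume. The
internal-standard correction is a single sample-level factor because one
DNP-PE spike is added per extraction. TAG response factors come from a
linear least-squares model in ECN (= acyl carbons − 2 × double bonds); the
linear form is the simplest monotone choice consistent with a single-class
calibrant series, and predictions are clamped to the calibrated ECN range
± 4 with a warning. Betaine lipids without their own standard (DGTA, DGCC)
are quantified through the DGTS standard.

TAG carbon mass fraction uses the glyceryl tri-ester formula
C_(N+3) H_(2(N+3)−4−2·D) O₆ (N acyl carbons, D double bonds) with atomic
masses 12.011/1.008/15.999; the dominant marine species (48–52 carbons,
0–3 unsaturations) give fractions of 0.757–0.764, and the flux stage's
default mix-free factor is 0.76.

## Flux accounting

Daily net TAG production is max − min of the replicate-averaged
concentration within each 24-h window running dawn-to-dawn (06:00–06:00),
aligning the window with the production phase. Replicates are averaged per
timepoint *before* the min/max because replicate spread would otherwise
bias the range upward; a no-averaging option is retained for diagnostics.
The two-point dawn/dusk variant floors negative differences at zero and
flags them rather than dropping them, preserving sample counts in
summaries. Campaign summaries are arithmetic means with (n − 1)-denominator
SDs; rounding happens only at presentation.

The published per-day production table ships in `dielflux.datasets` as
input data. Re-deriving its percentage columns from the printed rates
reproduces the printed values to within the propagation of the inputs' own
rounding (printed at 2–3 significant figures); the two nanophytoplankton-share
dispersion statistics printed as 10 and 11 come out at ≈ 11.6–11.8 from the
printed inputs under both the (n − 1) and n SD conventions, indicating they
were computed from unrounded source data that is not available; tests carry
a 2-point allowance there and assert everything else at printed precision.

## Production models

P(z) = 12000 × PAR(z) × [chl a](z) × a* × Φc with a* = 0.026 m² (mg chl a)⁻¹
(summer HPLC-based regional value, exposed as a parameter) and Φc a
mandatory-override quantum yield defaulting to 0.03 mol C (mol quanta)⁻¹
(mid-range; values above the theoretical 0.125 maximum are flagged). When no
measured light profile exists, PAR₀·e^(−kd·z) serves as a clearly labelled
stand-in.

PSD bins convert to carbon by splitting each bin's total volume into cells
of the bin-centre volume (geometric-mean diameter, spheres) and applying the
non-diatom protist allometry C = 0.216 · V^0.939 pg C (the published
log-form coefficients: log₁₀C = −0.665 + 0.939·log₁₀V). Size-class
production is the max − min of the 2–20 µm carbon between dawn and dusk per
day; the daily amplitude is reported per day — the same convention as the
TAG day-difference — and the amplitude divided by the photoperiod is
additionally exposed as an hourly rate.

## Budgets

Night-time consumption is partitioned between producer respiration and
mortality as competing first-order sinks, scaled so total night consumption
equals daytime net production (the stock returns to its dawn baseline,
consistent with stable dawn concentrations). Only the ratio of the two
rates matters: fractions are r/(r+m) and m/(r+m). A 70/30 split corresponds
to r:m = 7:3; the package does not assert a particular split, it exposes the
rates.

Caloric enrichment applies caloric equivalents 9.4/5.65/4.1 kcal g⁻¹
(lipid/protein/carbohydrate) to a dawn composition (defaults: 15% lipid,
45% protein, 25% carbohydrate of dry mass) plus the day's added TAG mass;
with the default composition and a 2.3-fold lipid rise the dusk gain is
≈ 37%. Depth integration is trapezoidal, truncated at the first
non-positive rate (clamped to zero at that endpoint) since deeper points are
outside the production layer. Global extrapolation multiplies by the gyre
area (default 40% of Earth's 5.10 × 10¹⁴ m² surface) and 365 d, with the
10⁻¹⁸ mg→Pg factor pinned by test. With the default synthetic spring-like
profile the depth-integrated rate is ~14–28 mg C m⁻² d⁻¹ and the global
flux ~1–2 Pg C yr⁻¹; basin-scale estimates are parameter-dominated (area,
profile shape) and should be read as order-of-magnitude.

## Synthetic campaigns

The generator emulates: triplicate sampling every 4 h over 8 days starting
at dawn (06:00); a storage lipid cycling 2.3-fold with an 18:00 peak; a
near-flat membrane-lipid biomass proxy (1.27-fold); an antiphase
respiratory quinone (pre-dawn peak, 04:00, 3.3-fold); dark-bottle rates
averaging 4 ± 1% of light rates; 24-h ¹⁴C activity below 12-h activity by
the injected night respiration; and a 2–20 µm biovolume triangle cycle with
a dawn minimum and dusk maximum.

Design choices:

- *Waveform* — cosine in log-concentration with the trough 12 h after the
  peak, so the noiseless peak:trough ratio equals the configured fold
  exactly and ratio-based statistics see a symmetric signal on the scale
  they operate on.
- *Noise* — multiplicative lognormal, unit mean, independent across
  replicates and timepoints; the default CV of 0.10 is a stand-in (field
  within-triplicate CVs are not published).
- *Depth* — the time-series generator expresses the configured fold at its
  shallowest (reference) sampling depth, because a time-series station
  samples where the signal it characterises lives; the depth-profile
  generator uses the absolute form 1 + (F − 1)·e^(−z/λ) from the surface
  with λ defaulting to one third of the photic depth, which keeps the
  residual amplitude below 5% of the surface excess at the photic-zone base.
- *Seeding* — one integer seed expands into independent per-table
  substreams by stable hashing of the table name, so adding a table to a
  workflow never perturbs the others.

What passing tests on synthetic data do *not* show: the generator has no
day-to-day environmental variability (every day repeats the same clean
waveform), no trends, no autocorrelated noise, and no covariance between
lipid classes. Consequently the synthetic near-flat membrane-lipid class is
reliably *detected* as rhythmic at the default noise level, whereas the
corresponding field signal was not significant — field day-scale variance is
much larger than replicate noise. Calibration results (type-I error, power)
apply to the stated design and noise model, not to arbitrary field data.

## Numerical conventions

Exact-regime p-values compare statistics with a 10⁻⁹ absolute guard to
absorb float noise in tie handling. The permutation stream is fixed
(deterministic) and independent of the data. Fold changes use the 06:00
reference by convention; missing reference hours raise with the available
hours listed. All floors (negative rates, dark over-correction) warn rather
than fail, and percentage denominators ≤ 0 produce NaN with a warning.
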