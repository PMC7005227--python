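# Methods

## Dose quantities and conversions

All quantities are stored in the units in which survey tables print them —
ESAK, KfiA and organ doses in mGy, KAP in Gy·cm², effective dose in mSv —
and these units are encoded in the CSV headers (`esak_mGy`, `kap_Gycm2`,
`e_mSv`, …). Conversion to Sv happens only inside the risk formulas
(a factor 10⁻³, with equivalent dose numerically equal to absorbed dose for
X-rays). We deliberately do not canonicalise to SI internally: a single
table-unit convention removes a whole class of I/O conversion bugs and
keeps file contents directly comparable to published tables.

Conversions implemented: `ESAK = KfiA × BSF` (backscatter factor, scalar
configuration value, default 1.49; its dependence on kV, filtration and
field size is out of scope), `KfiA = KAP / area` (with the Gy→mGy factor),
and inverse-square rescaling `KfiA × (d_from/d_to)²` to move a free-in-air
kerma between reference planes. Absent dose fields are represented as
explicitly absent (`None` / empty CSV cell), never as zero.

Effective dose uses the hermaphrodite-phantom convention for the gonads:
the gonad equivalent dose entering E is the *mean* of the testes and
ovaries doses, so the gonad term is `(w_g/2)(H_testes + H_ovaries)` —
exactly `0.04 (H_testes + H_ovaries)` under the ICRP 103 gonad weighting
factor 0.08. This convention is an assumption of the package; it is what
makes the 0.04 factor in the risk model exact. The registry ships the
three historical gonad weights 0.25 (ICRP 26), 0.20 (ICRP 60) and
0.08 (ICRP 103).

### Printed-table comparisons

Published dose and risk tables are printed at one or two significant
digits while the underlying computations used unrounded intermediates
(visible, e.g., where a printed ESAK of 0.78 mGy corresponds to
0.52 × 1.49 = 0.7748). Comparisons against printed values therefore
half-up round the computed value to the printed number of digits and allow
±1 unit in the last printed digit. A handful of published risk-table cells
are not recoverable from the rounded dose inputs even at that tolerance;
the test suite lists them explicitly rather than forcing agreement.

## Risk model

Per radiograph,

    R_sex = r_cancer · (E − 0.04(H_testes + H_ovaries)) + r_heritable · H_gonad(sex)

with `r_cancer = 5.5 × 10⁻² Sv⁻¹` (detriment-adjusted nominal cancer risk,
whole population) and `r_heritable = 5.40 × 10⁻³ Sv⁻¹` (heritable disease,
reproductive population). A gonad shield with protection factor GS
(defaults: 0.95 testes, 0.5 ovaries) removes the fraction GS of the gonad
dose and hence multiplies only the heritable term by (1 − GS); the risk
reduction is `GS · r_heritable · H_gonad`, computed directly so that
unshielded = shielded + reduction holds to floating-point exactness.
Sex is modelled as binary only because the heritable term is organ-specific;
the hermaphrodite averaging lives entirely inside effective dose.

Risks are stored as raw probabilities and formatted per 10⁶ (half-up) only
at reporting time. Two degradation/trade-off helpers accompany the model:
a population-average protection factor
`p·GS_correct + (1−p)·GS_misplaced` for imperfect shield placement
(surveys report only ~34 % of shields correctly positioned, and effective
testes factors of ~0.77 instead of 0.95 in adolescents), and a break-even
incident rate `10⁶ × reduction / harm_per_incident`. The
detriment-equivalent harm per shielding-related incident has no canonical
value; it is a required user input (the analysis driver prints the rate
for 1.0 and 0.1 as illustrations). A risk below 1 × 10⁻⁶ is conventionally
considered inconsequential; the package does not gate any output on that
threshold.

## Collective-dose scenarios

Collective dose is `Σ_c pop_c · (freq_c/1000) · E_c` in man-Sv, reported
in kman-Sv at one decimal (half-up). Scenarios either override the
per-exam effective dose uniformly (0.52 mSv at the most common European
DRL of KAP 3.0 Gy·cm², 0.26 mSv at the Dutch target DRL of 1.5 Gy·cm²,
0.095 mSv at the optimised hospital level) or harmonise the frequency to a
reference country (a Netherlands-like 39.8 per 1000). Uniform-dose
scenarios are computed from per-country frequencies when a table is
supplied, but the aggregate shortcut — total population × mean frequency ×
uniform dose — is also supported and is exact by linearity; the acceptance
checks use it because no per-country source table is published. The
baseline scenario keeps all national values; percentages are relative to
it. The per-country scenario results (baseline and frequency-harmonised)
depend on unpublished national dose data and are therefore exercised on
synthetic tables via linearity and conservation properties, not on exact
published values. The assumption that the AP projection dominates
published "pelvis" effective doses is inherited from the source surveys
and not modelled further.

## Trend analysis

The historical decline of ESAK is fitted as
`ESAK(y) = a₀ exp(−k (y − y₀))` by unweighted ordinary least squares of
`ln ESAK` on `y − y₀` (reference year y₀ = 1896, the first data year).
Weighted or segmented variants are out of scope. The fit reports the
residual log-sd `√(SSR/(n−2))` and the standard error of k; the decline
factor between two years is `exp(k·Δy)` and is reported as the
*fitted-line* factor (endpoint averages would give a different, noisier
number). Quantiles use linear interpolation between order statistics
(numpy's default, the "type 7" rule) — stated explicitly because survey
percentile ratios are quoted without a rule. Relative errors of
multi-parameter dose reconstructions combine in quadrature, `√(Σσᵢ²)`,
treating parameters as independent multiplicative (log-space) errors;
seven 20 % errors give 53 %, inside the 40–60 % uncertainty band typical
of such reconstructions.

## Synthetic data

The generators emulate the *statistical shape* of the survey inputs, not
their actual national values.

* **Country tables** (default 35 countries, 573 × 10⁶ inhabitants):
  populations log-normal (log-sd 1.2, spanning roughly the 0.3–80 million
  range of European states) rescaled to the exact configured total;
  national frequencies log-normal (log-sd 0.6) rescaled multiplicatively
  so the population-weighted mean equals the target (54.3 per 1000)
  *exactly*, sparing a pinned reference country (39.8 per 1000) when
  configured; per-exam effective doses log-normal with median 0.75 mSv and
  log-sd 0.5, matching the right-skewed, order-of-magnitude spread of
  published survey bar charts and a Europe-wide mean of ~0.8 mSv implied by
  published collective-dose totals. Log-normal marginals were chosen
  because the surveyed quantities are strictly positive and right-skewed.
* **Dose histories** (default 182 points over 1896–2018): years uniform,
  doses on the exponential curve (a₀ = 400 mGy, k = ln 400/122 so the
  construction declines by exactly ×400 over the span) with log-normal
  noise of sd 1.0 — more than an order of magnitude of scatter at any
  time, as historical compilations show.
* **Exam records**: independent truncated-normal draws (truncated at zero)
  around per-room means of kVp, mA, exposure time, tube load, KAP, FID and
  KfiA; ESAK is always *derived* as KfiA × 1.49, never drawn. The zero
  truncation shifts sample means slightly above the configured means for
  high-variance fields (e.g. KAP 0.48 ± 0.29 → expected mean ≈ 0.51); the
  tests account for this. Correlations between technique factors (mAs vs
  KAP, FID vs KfiA) are *not* modelled — a documented simplification, so
  passing tests demonstrate calibration and reproducibility of marginals,
  not realism of joint technique distributions.

All generators are bit-reproducible given (seed, config). Because the
synthetic tables match the real surveys only in aggregate (totals, means,
spread shapes), tests on them validate the *estimators and arithmetic*,
not the historical record itself.

## Problem sizes and numerics

The default analysis sizes — 35 countries, 182 history points, 200
replicate histories for the bias check, 10⁵ Monte-Carlo draws for the
quadrature check, 200 exam records per room — mirror the survey sizes the
package emulates and run in seconds. Degenerate inputs are rejected with
field-named validation errors (negative doses, backscatter factor < 1,
fewer than three trend points or a single distinct year, empty country
tables, a reference country that alone meets the frequency target).
Half-up rounding (not banker's) is used wherever values are formatted for
comparison with printed tables.

## Known limitations

* Organ and effective doses are taken as user-supplied conversion results;
  no Monte-Carlo phantom transport or beam-quality modelling is included.
* Risk coefficients are age-independent adult values; paediatric risk is
  out of scope.
* The backscatter factor is a scalar; field-size and beam-quality
  dependence is ignored.
* Negative side-effects of shielding enter only through the break-even
  rate and the population-average protection factor; specific adverse
  events are not modelled probabilistically.
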