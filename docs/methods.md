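# Methods

This note documents the statistical procedures implemented in irtools,
their assumptions, the default parameters and why, and the design
decisions taken where the underlying study protocol leaves the choice
open.

## Bioassay analysis

WHO tube tests expose groups of 20–25 adult females per tube for one hour
and score mortality at 24 h. Pooled mortality for a condition
(population × insecticide × synergist) is 100·Σdead/Σexposed across
tubes; the per-tube SD is reported alongside because assay figures
conventionally show it as error bars. Tubes outside 15–30 mosquitoes
raise a warning but are not rejected, so synthetic stress tests can use
unusual sizes. Fewer than 100 specimens in total sets a `low_n` flag
(WHO asks for a minimum of 100).

Abbott's correction, 100·(obs − ctrl)/(100 − ctrl), is applied only when
control mortality lies in [5%, 20%]; below 5% WHO practice uses the raw
mortality, above 20% the run is invalid and an error is raised rather
than a corrected number returned. Classification uses the WHO bands:
mortality < 90% ⇒ resistant, 90–98% ⇒ suspected resistance, ≥ 98% ⇒
susceptible. The 90% boundary is strict (exactly 90.0% is *not*
resistant). A `paper_mode` collapses the two upper bands to
`not_resistant`, reproducing the simple below-90 rule used when only
resistant/not-resistant is reported.

Synergist restoration is tested by pooling dead/alive counts across
tubes into a single 2×2 table (with vs without synergist) and applying
the exact test below. Pooling discards tube identity; this matches how
single mortality rates per condition are conventionally reported, and a
replicate-level alternative is out of scope. The direction (mortality
increased/decreased) is reported separately from the two-sided P.

Enzyme activities are compared field-vs-reference per enzyme family with
the Mann-Whitney test; direction (elevated/reduced) comes from the
median difference.

## Exact contingency tests

The r×c Fisher exact test is implemented by full enumeration of all
tables with the observed margins under the multivariate hypergeometric
null. The two-sided P is the probability-ordering (Freeman–Halton)
convention: the sum of probabilities of every table whose point
probability does not exceed the observed one, with a relative tie
tolerance of 1e-7 (the convention of standard implementations). For 2×2
tables this reduces exactly to the classic two-sided Fisher test, and a
vectorised single-free-cell path is used. Larger tables are enumerated
over the (r−1)(c−1) free cells; beyond a grand total of 500 for tables
larger than 2×2 the function refuses with an "enumeration limit" error
instead of silently approximating. The 2×3 genotype tables analysed here
(totals ≤ ~170) enumerate in well under a millisecond.

Whether the original analyses were exact or asymptotic, one- or
two-sided, is not stated anywhere they are used; two-sided exact tests
are assumed throughout and the choice is recorded in each result's
`method` field.

## Differential-expression caller

Input is K probe×replicate matrices of normalised log2(field/reference)
ratios with per-array detection flags (`detected`/`marginal`/`absent`);
normalisation and feature extraction are upstream of this package.

1. **Detectability filter.** A probe is retained only if no array in any
   contrast flags it `absent` (marginal is acceptable). Everything else
   is `filtered`.
2. **Per-contrast statistics.** The per-probe mean log2-ratio m gives
   the signed fold change FC = 2^m (m ≥ 0) or −2^(−m) (m < 0), so
   |FC| ≥ 1 and underexpression is negative. The one-sample t-test of
   the replicate log2-ratios against 0 tests the null of an expression
   ratio of 1. Zero-variance probes take the limiting convention
   (P = 1 if the common value is 0, else P = 0, flagged degenerate).
3. **Replication call.** `significant` requires P < α and |FC| >
   fc_threshold with one common sign in *every* contrast (defaults
   α = 0.05, fc_threshold = 2, K = 3). `potential` requires at least
   K−1 contrasts passing both criteria in one direction, **every**
   passing contrast showing |FC| > rescue_fc (default 20), and no
   passing contrast of opposite sign. The rescue bound is enforced on
   the passing contrasts, not the average: the motivating example is a
   gene whose two passing contrasts show FC 41 and 53 while the third
   (FC 10) misses the P threshold at 0.060.
4. **Representation.** Mean FC (arithmetic on the signed-FC scale by
   default; a geometric option exists) and Fisher's-method combined P
   (X² = −2Σln pᵢ on 2K df) are computed for reporting only — they never
   enter the call, so the averaging convention cannot change results.

P-values are not multiplicity-adjusted; the replication criterion itself
is the error control, and `expected_false_positives(n, α, k) = n·αᵏ`
quantifies it (≈454 for one contrast, ≈1.1 for 3-of-3 at n = 9083,
independence across contrasts assumed, the FC criterion ignored).

The caller is monotone in evidence: decreasing any P or increasing any
|FC| (same sign) never demotes a probe in the ordering
not_significant < potential < significant. This is property-tested.

## qRT-PCR quantification

Efficiency per primer pair is the least-squares fit of Ct against log10
relative input over a 5-fold dilution series (≥ 3 points),
E = 10^(−1/slope); estimates outside (1, 2.2] are flagged as
out-of-range rather than clamped. The Pfaffl ratio per biological
replicate is E_t^ΔCt_t / E_ref^ΔCt_ref with ΔCt = mean Ct(control) −
Ct(sample); with two reference genes (L8 and S7 here) the denominator is
the geometric mean of the per-gene normalisation terms — the established
convention when the combination rule is not otherwise specified.
Technical replicates are averaged within biological replicate first. The
point estimate is the mean of replicate ratios and the 95% CI a
t-interval across the (typically four) biological replicates; the CI
method behind published tables of this kind is rarely stated, and the
t-interval is the simplest defensible choice. With all efficiencies
equal to 2 the ratio reduces exactly to 2^(−ΔΔCt) (property-tested).

## kdr genotype analytics

Mutant-allele frequency in a stratum of N individuals is
(n_het + 2·n_mut_hom)/2N; fixation (frequency 1) is reported with a flag
and never tested, since a fixed locus carries no variance — association
testing at such a locus raises an error. Population comparisons and
genotype–phenotype association both default to the genotype-based 2×3
exact test (populations or phenotype classes × three genotypes), with
unobserved genotype columns dropped. This construction was validated
against an independent enumeration oracle and reproduces the published
exact-test P-values on the printed genotype counts (0.263 for the
between-population comparison; 0.491, 0.317, 0.220 for three of the four
association tests). An allele-based 2×2 variant (2N alleles per class)
is available by option; it gives systematically smaller P on the same
data and is not the default.

## Synthetic-data generators

Defaults reproduce the study conditions: 9083 probes × 3 contrasts × 4
replicate hybridizations; tubes of 25 with 4 replicates; 40 individuals
per group in enzyme assays; 4 biological replicates and 5-point 5-fold
dilution series in qPCR; ~90 genotyped individuals per population at
V1016I-like frequencies (0.17/0.23).

- **Expression**: null probes have mean-0 Gaussian log2-ratios; spiked
  probes mean ±de_log2fc, symmetric up/down because the caller operates
  on log ratios. The replicate SD default (0.5) and dropout rate are
  generator choices, not reconstructions — the underlying raw arrays
  give no noise estimates. Flags take all three states; dropout assigns
  `absent` (default `marginal` rate 0.05 so the marginal-is-retained
  rule is exercised).
- **Bioassay**: per-tube deaths ~ Binomial(tube_size, p) per condition;
  control tubes use the control mortality.
- **Genotypes**: Hardy–Weinberg draws at allele frequency q; resistance
  phenotype from a logistic model additive on the log-odds scale with a
  per-allele odds multiplier (1 = null), the simplest model that covers
  both the null and associated regimes.
- **qPCR**: Ct = intercept − log_E(relative input) + Gaussian noise;
  field samples shift by −log_E(true ratio); reference genes are pinned
  to ratio 1.
- **Enzyme activity**: log-normal per-individual activities; the field
  group's location shifts by log(shift multiplier).

One global integer seed drives everything through per-component
SeedSequence substreams, so any generator can be re-run independently
yet bit-identically. What the generators deliberately do **not**
emulate: probe sequences, dye bias, spatial array artifacts, array
normalisation, inter-probe correlation, overdispersed tube mortality, or
Hardy–Weinberg departures. Passing calibration/power tests on this
synthetic data therefore validates the *statistical machinery* under the
stated models, not the upstream measurement process of real arrays or
assays.

## Problem sizes used in validation

Null calibration of the replication criterion uses 50 simulated null
datasets at the full study geometry (9083 × 3 × 4) and checks the mean
3-of-3 P-pass count against n·α³ within its 99% Monte-Carlo band.
Sensitivity for spiked log2FC = 2 probes (replicate SD 0.25) pools 200
seeded datasets of 400 probes (10% spiked) — 8,000 spiked probes total —
rather than 200 full-size arrays, which leaves the per-probe sampling
distribution unchanged while keeping the suite quick. Type-I calibration
of the rank test runs 1,000 null 40-vs-40 comparisons; exact-test oracle
equivalence sweeps every 2×2 table with total ≤ 40 (~136k tables) and
random 2×3 tables with total ≤ 30 against an exact rational-arithmetic
enumeration oracle.

## Numerical conventions

- Probability-ordering ties in exact tests use a 1e-7 relative
  tolerance.
- The Mann-Whitney test is exact for n₁+n₂ ≤ 20 without ties, otherwise
  the normal approximation with tie and continuity correction (the
  study's n = 40 per group always takes the approximation); the choice
  is recorded per result.
- Fisher's method rejects p ≤ 0 and p > 1 rather than truncating.
- Written tables carry 6 significant figures (round-trip safe);
  human-facing report JSON rounds frequencies to 2 decimals and
  P-values/ratios to 3 significant figures, matching the precision such
  tables are conventionally printed at.
- Missing cells in input tables are validation errors, never imputed.

## Known limitations

- The published bioassay mortalities, enzyme activities and qRT-PCR Cts
  are not printed as raw data, so those stages are validated by
  properties and synthetic recovery, not by numeric reproduction of the
  published figures/tables.
- The r×c exact test is enumeration-only by design; very large sparse
  tables need a network-algorithm implementation this package does not
  provide.
- The expected-false-positive formula assumes independent contrasts;
  shared reference strains induce positive correlation that makes it an
  approximation (conservative for the replication criterion's benefit
  claim).
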