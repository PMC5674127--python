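# Methods

This note documents the models implemented in `thermotx`, their
assumptions, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Study design assumed throughout

Isothermal batch cultures at four temperatures (30, 40, 65, 77 °C; 65 °C
optimal), each sampled at its own specific growth rate (0.006, 0.087,
0.274, 0.107 h⁻¹), with two RNA-seq libraries per temperature of roughly
3 million mapped non-rRNA reads. Because each temperature was grown at
exactly one rate, the rate covariate is a deterministic function of the
temperature factor: this aliasing is the central statistical difficulty
the cascade addresses, and it is preserved faithfully in the simulator.

The scaling constant for the effect-size ratio defaults to 0.115 h⁻¹,
the design's stated average growth rate. Note the arithmetic mean of the
four rates above is 0.1185; because the averaging population behind
0.115 is not recoverable, the constant is exposed as configuration
(`CascadeConfig.rate_scale`) rather than recomputed.

## Count model and differential expression

Counts are modelled negative-binomial with mean μ and common dispersion
φ, variance μ + φμ². The common-φ choice matches the assumption of the
two-group exact test; per-gene (tagwise) dispersion is out of scope.

*Dispersion estimation* pools within-group scatter across genes:
E[SS_g] = df_g (μ_g + φμ_g²), solved for φ with a two-pass correction
for the plug-in bias of the sample mean, clipped at zero (sub-Poisson
data report φ = 0). On simulated data the estimator recovers φ = 0.2
within ~10 % at 2000 genes and reports < 0.002 on Poisson data.

*Exact test.* Libraries in a comparison are scaled to their geometric
mean library size, scaled counts are summed per condition
(rounding half-to-even, fixed), and the two-sided conditional p-value
enumerates all splits k of the gene total s, summing the probabilities
not exceeding the observed one. Group sums are NB(n_g λ, size n_g/φ)
with λ = s/(n₁+n₂); at φ = 0 this reduces to the conditional binomial.
The implementation matches an exhaustive enumeration oracle to 10⁻¹⁰
and edgeR's `exactTestBySmallP` to ~10⁻¹⁴ (tests).

*Responsiveness criteria* (all three required, per comparison against
65 °C): BH-adjusted q < 0.05 (strict), fold change ≥ 2 on mean RPKM
(inclusive), and > 20 reads (strict) in at least one of the two
conditions. "Reads per condition" sums raw counts within the condition;
a per-sample toggle is provided (`min_reads_per="sample"`) since the
wording is ambiguous. A zero reference mean with a nonzero test mean
counts as infinite fold change (passes the fold criterion); an optional
RPKM pseudocount is off by default.

FDR is applied within each pairwise comparison separately, matching
per-comparison reporting of responsive counts.

## Growth-rate/temperature cascade

1. **Correlation filter.** Pearson r of log₂(RPKM+1) against growth rate
   over all samples. |r| ≤ 0.7 (strict pass above 0.7) → label
   `not_correlated`; the temperature-responsive interpretation stands.
   The log transform is a design choice (the analysis scale was not
   recoverable); raw RPKM is a toggle.
2. **ANCOVA.** `expression = growth_rate + temperature` with treatment
   coding, reference 65 °C. With rates constant within temperature the
   design is rank-deficient by one; dummy columns are dropped starting
   from the highest temperature until full rank and reported as aliased.
   This reproduces deterministically what standard linear-model software
   does silently.
3. **Likelihood-ratio test** of `expression = growth_rate` against the
   full model. The reported statistic is n·ln(RSS_reduced/RSS_full).
   Its p-value uses the exact finite-sample null of that statistic under
   Gaussian errors — the equivalent F(df₁, n−p) tail, a monotone
   transform of the same likelihood ratio — because the asymptotic χ²
   reference is badly anti-conservative at n = 8 (empirical size ≈ 0.2
   at nominal 0.05; with the exact null the type-I rate is calibrated,
   verified by simulation in the tests). BH correction is applied over
   the genes that reach this stage.
4. **Effect-size ratio** ρ = |β_T,best / (β_rate · 0.115)| with
   β_T,best the estimable temperature coefficient with the smallest
   per-coefficient p (ties to the largest |β|). Growth rate dominates
   iff ρ < 1, strictly; β_rate = 0 yields `undetermined`. Exact
   boundary equality (ρ = 1 up to round-off) is resolved as *not*
   dominant to honour the strict inequality.

Interpretation note: a gene whose planted pattern is non-collinear with
rate (e.g. induction only at 77 °C) rarely passes the correlation filter
— by construction no such pattern can correlate strongly with rate — so
the cascade attributes it to temperature via `not_correlated` rather
than `temperature_dominant`. Recovery tests therefore count both labels
as temperature attribution.

## COG enrichment

For each category: observed = responsive genes carrying the category
(multi-category genes count everywhere, unassigned genes count as NC);
expected = genome-wide category count × (responsive genes / genome
genes); `diff_percent` = 100·(obs − exp)/exp. A second reading of the
axis — difference in percentage-point shares of category incidences —
is emitted as `diff_points`. No significance test is attached to the
primary output; a seeded permutation p-value is available as an extra.

## LGT detection

Hits are filtered per query (E < 10⁻⁵ strict, coverage ≥ 0.70
inclusive, then the 500 best bit scores, ties broken by subject id).
Each retained hit contributes bitscore / (best self-group bitscore) —
the query's own self-match is excluded from the sums but serves as the
normalizer when present; absent any self hit the normalizer is 1.0,
flagged. Contributions are summed into Self (own genus), Close (two
presets: sister genus, or the whole order) and Distal (everything else),
with membership by label matching against the recorded lineage path —
no live taxonomy lookups.

The cutoff for a score distribution: Gaussian KDE (Silverman bandwidth,
512-point grid from 0 to the maximum), find the density peak nearest
zero and the first local minimum after it, and take the median of the
data points between the two landmarks (midpoint of the landmarks when
fewer than 5 points lie between, flagged). A unimodal distribution is an
explicit error — with few genes (≲300 at 30 % transfer) the bandwidth
can smooth away the zero peak, and the failure is surfaced rather than
guessed around. Transfer requires Close < cutoff and Distal > cutoff,
both strict. Recentness: K when no retained non-self-group hit lies in
the home phylum (the genome's own matches are necessarily in-phylum and
are exempt), else K + M when the order-level and sister-genus Close
scores differ by < 1 (strict); K takes precedence.

## Growth curves and cardinal temperatures

Log-phase rate: over all contiguous windows of ≥ `min_window` points,
the OLS slope of ln OD vs time is computed and the steepest window wins
(ties: longer, then earlier). This is the "easy linear" estimator of
Hall et al. (2014); on a noiseless exponential segment it returns the
full segment and the exact rate. An R²·length window score was
considered and rejected: on three-phase curves the full-curve window
nearly always maximizes it (R² stays high while length grows), biasing
the slope low. Window length trades variance against bias: with ~5 %
multiplicative noise, windows of ≳15 points keep the worst-case slope
inflation from window selection under a few percent.

Cardinal temperatures: least squares on
√r = b(T − T_min)(1 − exp(c(T − T_max))), four parameters, bounds
keeping T_min below and T_max above the observed range, five jittered
starts (seeded) from (b from the low-temperature slope of √r, c = 0.1,
T_min = min T − 5, T_max = max T + 2). Noiseless 8-temperature data are
recovered to 10⁻³; under 5 % rate noise the median cardinal-temperature
error is ≈ 0.3 °C. Predicted rates are clipped to 0 outside
(T_min, T_max) when simulating. Note that fitting only the four design
rates is an exact interpolation (4 points, 4 parameters), so the printed
growth-permissive range from such a fit is a containment statement
(T_min < 30, T_max > 77), not a precision estimate.

## Genome comparison

Coding density is the interval union of annotated gene spans (both
strands, overlaps once; RNA genes included by default, CDS-only toggle)
over the genome length; the headline statistic is the
noncoding : coding ratio. ANI cuts genome A into consecutive 1020-nt
fragments (grid anchored at position 1, trailing partial dropped),
aligns each to genome B, and averages the identities of fragments with
≥ 70 % alignable fraction and ≥ 30 % identity; both directions and
their mean are reported. The built-in aligner seeds on exact 15-mers
(both orientations) with ungapped diagonal scoring — sufficient for the
substitution-dominated ≥ 80 % identity regime of congeneric
comparisons, and cross-checked against edlib alignment identities in
the tests; any callable `fragment -> (identity, fraction)` can replace
it to reuse external alignments. Indel-rich or more divergent pairs are
outside the built-in aligner's design envelope.

## Synthetic data: what it emulates and what it does not

The expression simulator plants four gene classes (null,
temperature-responsive with a ±`effect_log2` offset at one non-reference
temperature, rate-linear with log₂ expression slope per unit growth
rate centred on the mean rate, and mixed), NB counts at the configured
dispersion (default 0.05), lognormal library sizes (median 3×10⁶,
σ = 0.15) and uniform gene lengths (300–3000 nt). Default class mix
70/15/10/5 % and rate slope 8 log₂-units·h (a ~2 log₂ sweep across the
design's rate range) were chosen once as a realistic planted-effect
regime. It does not model batch effects between sequencing platforms,
rRNA carry-over, read-level error, or per-gene dispersion variation —
so passing recovery tests demonstrate correctness of the statistics
under the stated model, not robustness to those artefacts.

Growth curves are lag/exponential/stationary with multiplicative
lognormal noise; acclimation lags after temperature shifts are not
modelled. Homology-hit tables plant 30 % transfers by default, split
~60/40 between recent (no in-phylum homologs) and sister-shared, with a
per-gene conservation factor spreading vertical Close scores into a
continuum so that the zero peak is a genuine mixture component, as in
real screens. Genome pairs are substitution-only (no indels or
rearrangements), which is exactly the regime the built-in ANI aligner
targets.

## Numerical conventions

Half-to-even rounding after library scaling; probability comparisons in
the exact test use a 1 + 10⁻¹² relative tolerance to keep ties stable
in floating point; the LRT declares RSS zero below 10⁻¹² of the
response scale; cutoff estimation fails loudly rather than guessing on
unimodal inputs; all simulators take a single integer seed and are pure
functions of it (numpy PCG64).

## Problem sizes

Default analyses run at 2000 simulated genes, 1000 genes for LGT
screens, 100-seed replications for null-calibration and
cardinal-temperature recovery, and ~100 kb genomes for ANI — sizes at
which every recovery statistic in the test suite is stable to the
asserted tolerances.
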