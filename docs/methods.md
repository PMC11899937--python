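# Methods

## Score model

The LDL-C SNP score is a fixed-weight polygenic score over seven genotyped
variants. Five variants contribute additively on allele dosage: the score
contribution of SNP *i* is `dᵢ·wᵢ`, with `dᵢ` the count (0/1/2) of the
declared risk allele in the unphased genotype and `wᵢ` the per-copy weight
shipped in the panel (`rs629301` 0.15, `rs1367117` 0.1, `rs11220462` 0.05,
`rs6511720` 0.18, `rs1800562` 0.057). The remaining two variants, rs429358
and rs7412, are the *APOE* ε-haplotype system and contribute a single
diplotype-level weight (ε2ε2 −0.9 … ε4ε4 +0.2, ε3ε3 = 0); they are never
weighted individually. Scores are raw weighted sums — no centering or
standardisation — reported to 3 decimals in text output while full floating
precision is kept internally. Exhaustive enumeration of all 3⁵ × 6
dosage/diplotype combinations gives the attainable range [−0.9, 1.274].

Two conventions deserve emphasis:

- **Risk allele = reference allele** at rs6511720 and rs1800562.
  The weighted allele is the common (major) G allele;
  the minor alleles (T and A) are LDL-lowering. A typical homozygote
  therefore contributes 2×weight, and the all-zero score requires the rare
  protective homozygotes at both loci.
- **APOE double heterozygote.** The unphased genotype rs429358 T/C with
  rs7412 C/T admits two phasings: ε2/ε4 and ε1/ε3. Because ε1 (C–T in cis)
  is vanishingly rare, the default policy resolves it to ε2ε4 — the
  conventional call in the APOE literature. A strict policy returns
  UNRESOLVED instead, and genotypes *only* consistent with ε1-bearing
  phasings (e.g. rs429358 C/C with rs7412 T/T) are hard errors rather than
  silently mis-labelled calls.

Missing data: a sample missing any of the seven loci (or with an unresolved
diplotype) receives a missing score by default, with a structured reason;
an opt-in partial mode sums the available loci and flags the result
incomplete. Allele validation is strict — calls are matched to the panel's
declared allele set by rsID and mismatches are errors; no strand flipping
is attempted (none of the panel SNPs requires A/T / C/G disambiguation in
the declared sets).

## Synthetic cohorts

The simulator emulates the study design the analysis stage expects: a
STEMI patient group (default n=93) and a high-LDL comparison group
(default n=61).

- **Genotypes.** Each dosage locus is drawn as Binomial(2, p) at the
  group's configured variant-allele frequency — i.e. exactly
  Hardy–Weinberg proportions — independently across loci (no LD). The two
  *APOE* sites are the exception: per-individual haplotype pairs are drawn
  i.i.d. from ε-allele frequencies derived from the two marginal
  variant-allele frequencies under a no-ε1 constraint (f(ε4) =
  f(rs429358-C), f(ε2) = f(rs7412-T), f(ε3) the remainder), so the two
  sites are in complete LD through the haplotype structure, as they are in
  real data.
- **Frequency interpretation.** Default frequencies are the two study
  groups' reported per-group variant frequencies, interpreted as *allele*
  frequencies. Because the source tabulation does not state whether its
  percentages are allele or carrier frequencies (some values suggest
  carrier), a `freq_kind="carrier"` switch converts a carrier frequency c
  to the HWE-equivalent allele frequency 1 − √(1 − c).
- **LDL-C** (mmol/L) is log-normal — chosen for positivity and right skew;
  the generating distribution is not identified by a median and range alone
  — with exp(μ) matched to the group median, σ set so the configured
  min–max spans the central 99% of the untruncated law, and rejection
  truncation to the configured range (patients: median 3.88, range
  2.87–6.63; comparison: 5.67, 3.19–9.7).
- **Covariates.** Sex, ever-smoking, statin use and hypertension are
  Bernoulli at the groups' reported prevalences (smoking is a single
  binary ever-smoker flag: 59.1% patients, 27.9% comparison); age is
  uniform on each group's min–max and unused downstream by default.
- **Disease model (optional).** When configured, case status is assigned
  by logit P(case) = β₀ + β_PRS·S + β_smoke·smoking to candidates drawn
  from the comparison-group frequencies, and the two group quotas are
  filled from cases and controls (capped at 10⁶ draws). This is the
  minimal generative structure under which the downstream logistic
  regression is well-specified; it is an assumption of the simulator, not
  a claim about the real cohorts.

All randomness flows from one `numpy.random.default_rng(seed)`; draws
happen in a fixed order, so identical configs reproduce identical tables.
What the simulator does **not** emulate: linkage disequilibrium between the
dosage loci, genotyping error, covariate correlations (e.g. age–smoking),
or any LDL-C dependence on genotype within a group. Tests that pass on
these cohorts therefore validate the pipeline's arithmetic and its
statistical calibration under the stated model — not the biological effect
sizes of any real population.

## Statistics

- **Kruskal–Wallis** (tie-corrected, χ² reference with k−1 df) for
  quantitative group comparisons; for two groups the p-value coincides with
  the two-sided tie-corrected Mann–Whitney normal approximation. If every
  pooled value is tied, H = 0 and p = 1 by convention. Delegated to
  `scipy.stats.kruskal` behind the module surface.
- **Pearson χ²** with expecteds from the margins and **no Yates continuity
  correction** — the convention that reproduces the reference sex and
  hypertension statistics (0.252 and 8.368) from their printed counts.
  Zero margins are errors.
- **Fisher's exact test**, two-sided by the point-probability rule: p is
  the total probability of margin-fixed tables whose point probability
  does not exceed the observed one (relative tolerance 1+1e-7 against
  floating-point ties). 2×2 uses the hypergeometric distribution
  (`scipy.stats.fisher_exact`); 2×K is enumerated directly over the
  margin-fixed polytope and refuses tables beyond ~2×10⁶ candidates,
  pointing to χ² instead.
- **Logistic regression** by IRLS (Newton scoring) with step-halving, so
  the log-likelihood trace is non-decreasing. Convergence when max|score|
  < 1e-8 or the relative log-likelihood change < 1e-10; iteration budget
  100. Complete separation is detected (perfect classification of the
  outcome at the 1e-5 probability level — a finite MLE implies overlap)
  and raised as a diagnostic rather than emitting divergent estimates.
  Odds ratios are exp(β) with Wald 95% CIs exp(β ± 1.96·SE); Wald rather
  than profile-likelihood intervals match the symmetric-on-log-scale
  intervals conventional in this literature.
- **Backward selection** drops, at each refit, the term with the largest
  Wald p ≥ α until all survivors are significant; the intercept is never a
  candidate; the full drop trace is recorded; eliminating every term
  returns the intercept-only model rather than an error. The default
  threshold is α = 0.05. (The source description of the selection
  threshold reads "p < 0.5", which we take to be a typo for 0.05; 0.5
  remains reachable through the `--alpha` flag.)
- **LDL-C dichotomisation** at 4.9 mmol/L (strictly greater), the
  FH-suggestive threshold; missing stays missing; non-positive
  concentrations are validation errors. The LDL-threshold model is fitted
  within the comparison group by default (the patient group's admission
  LDL-C is distorted by the acute event and treatment), with an override.
- The case-status model's candidate terms default to PRS, smoking, sex,
  age, hypertension and statin use, exposed as configuration rather than
  hard-coded, since the covariate set entering a multivariate model is a
  study-level choice.

Percentages in reports are always computed from the supplied denominators,
never back-filled from printed values.

## Pipeline and formats

`prs-ldl run` orchestrates simulate (or load) → score → analyze and writes
a bundle: scores TSV, analysis JSON, text report, run log (panel version,
seed, stage counts), and the serialized config. Genotype input is VCFv4.2
(GT only, matched by the ID column, phase ignored, duplicate rsID records
fatal) or a wide TSV (`sample_id` + one `X/Y` column per rsID). Emitted
VCFs carry GRCh38 coordinates from panel metadata; those coordinates are
informational — every match in the package is rsID-based. Weight files are
a two-section TSV (variants + APOE diplotype weights), versioned, and
round-trip losslessly.

## Problem sizes in the test suite

The statistical calibration tests use sizes chosen to make their Monte
Carlo error small relative to the asserted bands: frequency/HWE recovery
at n = 20 000 (3 standard-error bands), rank-test type-I error over 1000
replicate 93+61 cohorts (band 5% ± 1.5%), Wald-CI coverage of
β_PRS = log 12.044 and β_smoking = log 24.962 over 500 replicates at
n = 5000 (≥ 90% coverage), and exhaustive Fisher-vs-enumeration agreement
over all 2×2 tables with N ≤ 40.

## Known limitations

- The five dosage loci are simulated without LD, so the simulated score
  variance slightly differs from a real cohort's whenever the panel loci
  co-segregate.
- The published cohort-specific results (group medians 0.824/0.674 as
  medians, ORs 12.044/24.962/20.391) depend on individual-level data that
  were never deposited; this package reproduces the scoring arithmetic and
  the statistical machinery exactly, and treats those cohort-level numbers
  only as simulation targets for calibration tests.
- The 2×K Fisher enumeration is exponential in K; it is intended for the
  small tables that arise in cohort-characteristics reporting.
- Backward selection inherits the usual caveats of stepwise procedures
  (post-selection inference is not adjusted).
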