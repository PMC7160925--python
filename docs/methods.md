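# Methods

## Trophic position from amino-acid δ15N

A consumer's trophic position (TP) is estimated from the δ15N difference
between glutamic acid/glutamine (Glx, trophic) and phenylalanine (Phe,
source) measured in the same tissue. All isotope values are ‰ vs
atmospheric N2 (δ15N) or V-PDB (δ13C); Glx is the combined glutamic
acid + glutamine pool as measured after acid hydrolysis.

Three estimator variants are provided.

**classic** — TP = (Glx − Phe − β)/TDF + 1 with β = 3.4‰ (the Glx−Phe
offset in marine primary producers) and TDF = 7.6‰ (the per-step
enrichment observed in low-trophic-level marine steps). Appropriate for
invertebrates and fish; it underestimates TP in birds, whose tissues
discriminate less.

**multi_tdf** (default) — TP = 2 + (Glx − Phe − TDF_tissue − β)/TDF_Glx-Phe,
anchoring the consumer one step above the producer (the "2") and
splitting discrimination into a meta-analytic per-step TDF_Glx-Phe =
6.2‰ and a final tissue-specific step: 3.5‰ for feathers, 4.0‰ for red
blood cells. Egg membranes use the feather constant: the published
egg-membrane group TP (3.2) back-computes exactly under 3.5‰ and not
under 4.0‰.

**multi_aa** — the multi_tdf form applied per trophic amino acid
(Glx, Ala, Leu, Ile, Pro, Asp) with per-AA (β, TDF) constants,
unweighted-averaged over the amino acids present. Only Glx ships with
default constants (3.4, 6.2): reliable tissue-specific β/TDF values for
the other trophic amino acids are not established, and shipping invented
defaults would masquerade as ground truth. Users supply their own via
`TDFConfig.per_aa_params` or the YAML config.

All variants are affine in the amino-acid values, so the TP of a group's
mean profile equals the mean of its per-individual TPs — the property
that lets printed group-mean Glx/Phe values reproduce printed group TP
means. TP values below 1 are returned with a `below_producer` flag, not
clamped or rejected: measurement noise can legitimately produce them.

A documented irreproducibility: the published breeding-season Gentoo
penguin blood row prints TP 3.7, but the blood equation on its own
printed means (Glx 27.7, Phe 7.5) gives ≈ 4.06. By the affine property
this cannot be a means-vs-individuals artifact; the package reports the
computed value and treats the printed one as an exception. The "induced
feathers (all)" row of the prion table back-computes to 3.77 against a
printed 3.9 — consistent with one-decimal rounding of the printed means,
and within the group's sampling error.

## Paired-tissue TDF calibration

When two tissues grow over the same window (chick feathers and chick red
blood cells, both integrating ~2–4 weeks), they record the same diet, so
the correct tissue-B TDF is the one that equalises the two TP estimates.
`calibrate_tissue_tdf` evaluates a user-supplied candidate grid and
returns the candidate minimising the mean absolute TP difference across
pairs, ties broken toward the smaller candidate; it also reports the
full candidate→loss table and the closed-form solution
TDF_B = TDF_A + mean[(Glx−Phe)_B − (Glx−Phe)_A], which is the exact zero
of the loss for these affine equations. On the published chick group
means (feather gap 15.7‰, blood gap 16.7‰) the zero-loss blood TDF is
4.5‰, not the adopted 4.0‰ — the loss under which 4.0 was chosen is not
recoverable, so the package reports the discrepancy rather than hiding
it. Grid resolution limits precision: with per-pair TP noise of SD 0.1
and a 0.5‰-spaced grid, neighbouring candidates differ by only 0.08 TP,
and simulation puts the probability of selecting the true candidate from
20 pairs near 0.88 — calibration from small paired samples should use
the closed form or a fine grid.

## Habitat classification

Bulk feather δ13C separates polar from temperate water masses. The rule
is a single threshold, default −21‰, polar strictly below. A sample at
exactly the threshold is temperate — the literal reading of "polar for
δ13C < −21‰" — with a `boundary_polar` flag to flip the convention.
Records without δ13C are returned explicitly unclassified, never
dropped, so polar + temperate + unclassified always equals n.

## Summary-statistic comparison layer

Published tables report only per-group n, mean and SD, so all group
comparisons run from summaries:

- Welch t: t = (m₁ − m₂)/√(s₁²/n₁ + s₂²/n₂), Welch–Satterthwaite df.
- One-way ANOVA: between-group SS from means and ns around the weighted
  grand mean; within-group MS pools the group variances with n−1
  weights; F on (k−1, N−k) df. Algebraically identical to the raw-data
  ANOVA when summaries are unrounded.
- Tukey–Kramer: q = |mᵢ − mⱼ|/√((MSW/2)(1/nᵢ + 1/nⱼ)) referred to the
  studentized-range distribution; the Kramer form handles unequal n.
  Homogeneous subgroups are lettered by the insert-and-absorb compact
  letter display: start with one column holding all groups, split every
  column containing both members of each significant pair, absorb subset
  columns. Groups share a letter iff no significant difference separates
  them.
- Default sidedness is two-sided; published paired and two-sample P
  values match two-sided probabilities, and a `sidedness` argument
  exposes the one-sided alternatives.

Raw-data diagnostics wrap scipy: Levene's test uses the median-centred
Brown–Forsythe variant (the robust default of the ecosystem the analysis
was originally run in); Shapiro–Wilk accepts 3 ≤ n ≤ 5000.

Repeatability of duplicate CSIA measurements is the one-way intraclass
correlation: with samples as groups and the two measurements as
replicates, ICC = (MS_between − MS_within)/(MS_between + MS_within),
reported in percent. It can be slightly negative when within-pair noise
dominates; it is not truncated.

Printed t and F magnitudes in published tables were computed from
unrounded raw data and cannot be recovered from one-decimal summaries;
the package therefore validates its tests against raw-data oracles
(exact equality when summaries are exact) and degrees-of-freedom
structure, not against printed magnitudes.

## Synthetic data

The generator emulates the per-sample data behind published group
tables: (Glx, Phe) drawn from a bivariate normal with the printed
marginals and a configurable correlation, bulk δ13C/δ15N as independent
normals, optional further amino acids as independent normals, and
optional duplicate measurements adding independent N(0, σₑ) error per
replicate. Three packaged spec sets carry the printed means, SDs and
group sizes (4–11 per group) of a Falkland Islands seabird community
dataset: breeding-season red blood cells of four species, moult feathers
of five species, and Thin-billed prion tissues across the annual cycle.

Assumptions and what the generator does not emulate:

- The Glx–Phe within-individual correlation is unpublished; the default
  is 0, and correlation-sensitive properties are exercised by setting it
  explicitly. Marginal group means and SDs are matched in expectation,
  not per draw.
- Normal marginals throughout; no heavy tails, no shared baseline shifts
  between groups, no temporal autocorrelation, no diet mixing. Passing
  recovery tests therefore demonstrates correctness of the estimators
  and statistics under the stated model, not robustness to real-data
  pathologies.
- Overlapping published groups (the "all" induced-feather row and its
  polar/temperate subsets) are generated as independent groups, not as a
  partition of shared individuals.

Seeds are mandatory arguments (numpy `default_rng`), never global state;
identical seeds give identical records.

## Numerical choices

- Table comparisons round half away from zero to one decimal, matching
  the printed tables' convention.
- Group SDs use the n−1 denominator; a group of one reports its SD
  absent, and empty groups are omitted.
- Replicate measurements are averaged per sample before group
  statistics.
- Calibration ties break toward the smaller candidate; the candidate
  grid is evaluated exhaustively (no continuous optimiser), with the
  closed form reported alongside.
- CSV values are written with `repr` (shortest round-tripping decimal),
  so write→read is exact; missing stays missing ("" or "NA"), never 0.
- The typographic minus "−" and en-dash "–" are accepted as negative
  signs on read.

## Problem sizes

Simulation-backed tests use 200 seeds for group-mean recovery (pooled
SE well under the 3·SD/√n acceptance band), 500 replicates for
repeatability and paired-test calibrations, 1000 for the Levene type-I
check, and 200 for calibration recovery — sizes at which Monte Carlo
error is negligible relative to every asserted tolerance.

## Known limitations

- Per-AA constants beyond Glx must come from the user; the multi-AA
  estimator is only as good as those inputs.
- The summary-driven Tukey assumes the pooled-variance model; with
  strongly heterogeneous variances (flagged by Levene) the letters
  should be read cautiously, as in the original tables.
- No Bayesian error propagation: TP uncertainty is reported as group
  SDs, not posterior intervals.
- Historical comparisons are plain per-variable Welch tests; collection
  year is not modelled as a covariate.
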