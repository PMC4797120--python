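# Methods

## The survey model

The package analyses culturable-endophyte surveys with a balanced
factorial layout: season (winter, summer, rainy) × site (1–6) × tissue
(leaf, stem, petiole), 54 cells in all, each cell sampled in triplicate
with a fixed number of tissue segments per replicate. Each incubated
segment either yields a culture of a given fungal species or it does
not, so the natural per-species, per-cell observable is the
colonization frequency CF = 100 · colonized/incubated (percent), and
the natural per-replicate observable for variance analysis is the
isolate count.

The default segment design is 45 segments per replicate, 3 replicates
per cell (135 segments per cell). This is the grain implied by the
transcribed CF tables themselves: their smallest nonzero entry is
0.74 ≈ 1/135, and entries step in multiples of 1/135 (the published
segment total, 2430, matches one season of this design rather than the
full survey; the design is therefore an explicit `SegmentDesign`
parameter rather than a constant). Converting percent CF back to
integer counts is `count = round(cf · 135/100)`; entries whose printed
CF is more than 0.01 percentage points from `count · 100/135` are
flagged, because the printed tables truncate rather than round (1.4
prints for 2/135 = 1.481).

## Diversity indices

All indices operate on an isolate-count vector for one grouping
(season, site or tissue marginal, summed over the other two factors):

- richness Np = number of species with count > 0;
- Gleason G = (Np − 1)/ln S and relative Gleason GR = (Np − 1)/S, with
  S the isolate total — the variants fixed here are the only simple
  forms consistent with several printed rows at once;
- Simpson dominance D = Σ p_i² and complement 1 − D;
- Shannon–Wiener H′ = −Σ p_i ln p_i in natural-log units (nats), chosen
  because the companion evenness values printed for the summer and
  petiole rows reproduce only under E = H′/ln Np in nats;
- Pielou evenness E = H′/ln Np, undefined for Np < 2; a single-species
  grouping is reported as E = 1 with `evenness_defined = False` (a
  one-species community is trivially even) rather than raising.

Internal computation is at full precision; display rounding is
half-away-from-zero at 3 dp (indices) and 2 dp (evenness).

### Agreement with printed values

A recomputed value is scored as matching a printed one when it lies
within one unit in the last printed digit (|Δ| < 10⁻ⁿ at n dp). The
published tables demonstrably mix display conventions — 21/ln 320 =
3.64057 is printed 3.640 (truncation) while 23/ln 272 = 4.10289 is
printed 4.103 (rounding) — so one-ulp agreement is the tightest rule
that accepts both conventions, and it is what the reproduction report
and acceptance tests assert. Several printed rows are not reproducible
under any convention (e.g. rainy G = 4.029 against 23/ln 635 = 3.564;
rainy E = 0.88 against 2.870/ln 24 = 0.903); these are reported as
mismatches with notes, never fitted. The printed Shannon/Simpson
columns would need exact isolate-level abundances, whose reconstruction
from truncated percent CF is ambiguous, so they are recomputed only
from synthetic data.

## Jaccard similarity

Inter-site similarity uses presence/absence only: a species is present
at a site if any CF > 0 there in any season or tissue, and J_c =
100·|A∩B|/|A∪B|, rounded to integer percent. Two empty communities get
J_c = 100 (reflexivity; avoids 0/0). The matrix recomputed from the
transcribed CF tables (off-diagonals 74–83 %) differs substantially
from the published site-similarity matrix (51–76 %), which cannot be
derived from the published CF tables by any presence threshold we
tried; the reproduction report lists the per-pair deviations and treats
the published matrix as reference only.

## Three-way ANOVA

For the balanced fixed-effects factorial the classical cell-mean
decomposition is exact and Type I/II/III sums of squares coincide, so
the implementation subtracts marginal means directly (per-observation
effect columns built by inclusion–exclusion; SS is the sum of squared
effects). F = MS_effect/MS_error with df_error = abc(r − 1) = 108 for
the study design, and the upper F tail is evaluated through the
regularized incomplete beta function I_x(d2/2, d1/2), x = d2/(d2 +
d1·F). Unbalanced data are rejected with the first deficient cell
named — the decomposition is only exact for equal cell sizes and the
survey design is balanced — and r = 1 is rejected because it leaves no
within-cell error term. A constant response is legal: every SS is 0, F
reports 0 and p reports 1. The response is a caller-supplied column
(the survey's is the isolate count per replicate sample); no transform
is applied by default, with `--transform sqrt|log1p` available on the
CLI. No multiplicity correction is applied across the seven sources.
Significance stars in display output follow the survey's legend
(*** p < 0.001, ** p < 0.015).

## Synthetic data generator

`CommunityModel` draws segment-level colonization with the study's
factorial structure. Species base probabilities follow a geometric
ranked-abundance series p_i ∝ k^i (default k = 0.8), the simplest
ranked-abundance model producing a few core dominant species plus a
rare tail; a log-series alternative was considered and rejected as
adding a parameter without changing what the tests can show. The series
is scaled so the species mean equals `base_rate` (default 0.011, set so
the default survey yields ≈ 1.9·10³ isolates — the observed scale of
the study). Season/site/tissue effects are multiplicative on the
colonization probability, because the factorial ANOVA acts on counts
whose cell means these multipliers control directly; optional pairwise
interaction multipliers are supported. Probabilities are clamped to
[0, 1] and clamp events counted in the output. The RNG is numpy's
PCG64 `default_rng`, recorded in the output metadata; the same seed
reproduces a survey bit for bit, and `recovery_experiment` uses seed +
simulation-index so repeated draws are independent but reproducible.

What the generator does *not* emulate: spatial or phylogenetic
structure, between-replicate overdispersion beyond binomial sampling,
epiphyte contamination, or species interactions. Passing recovery tests
therefore show that the estimators behave correctly under independent
binomial colonization with multiplicative effects — not that real
surveys satisfy those assumptions.

## Problem sizes and numerical choices

The oracle-agreement suites use 1000 random abundance vectors/set pairs
(brute-force summation and bitmask oracles) and 200 random balanced
designs cross-checked against an independent least-squares factorial
fit at 10⁻⁸ relative agreement; null calibration uses 1000 i.i.d.
normal datasets on the full 3×6×3, r = 3 design with a 99 % binomial
confidence band around α = 0.05; the power experiment uses 200
simulated surveys with a 3× leaf multiplier. These sizes give stable
Monte-Carlo verdicts while keeping the default suite in the tens of
seconds. Tie-breaks and degenerate inputs: dashes in input tables are
exact zeros (meaning "not isolated", not missing); an all-zero
abundance vector is a domain error everywhere; F on a zero error mean
square is reported as the degenerate (0, p = 1) rather than infinity.

## Known limitations

- The published summary tables contain internal inconsistencies
  (documented above and in the reproduction report); the package
  reproduces the self-consistent subset and reports the rest.
- Replicate-level field data were never published, so the ANOVA's SS
  column for the real survey cannot be recomputed — only its df
  structure and the F-ratios implied by the printed mean squares.
- Isolate-count ANOVA assumes approximate normality within cells;
  counts with small means violate this, and the simulator's calibration
  check quantifies how benign the violation is at the study's scale
  rather than removing it.
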