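# Methods

This note documents the statistical procedures `modadvice` implements,
the choices made where the procedure left room for interpretation, and
what the synthetic-data tests do and do not establish.

## Questionnaire scoring

SRSQ (9 items, 1–3), PANAS (20 items, 1–5, ten per subscale in the
standard alternating assignment), and MHC-SF (14 items, 0–5) are scored
as plain keyed sums. Decisions where the instruments' public descriptions
underdetermine the implementation:

- **SRSQ keying.** The published material gives only the total's
  direction (higher = more sleep reduction) and the clinical cutoff
  (>17.3). The default keying applies no reversal, which is consistent
  with the 9–27 total range and the reported cohort mean of 15.76; a
  keying vector is configurable for reverse-scored variants.
- **Strict inequalities.** All cutoffs are strict: Sleep requires
  total > 17.3 (so integer totals ≥ 18), suboptimal affect requires
  PA < 30 or NA > 30, and "more than 6" functioning items means ≥ 7.
- **PANAS combination rule.** Whether suboptimal affect requires one or
  both subscale conditions is not documented; the default is the
  permissive OR, switchable to AND (`panas_rule`).
- **Missing items** are rejected, not imputed. `allow_prorated_totals`
  enables within-instrument mean imputation for exploratory use only.
- **Wellness legacy rule.** The deployed procedure advised Wellness by a
  rule that deviated from the flourishing criterion; the exact wrong rule
  was never stated. The engine implements the correct criterion by
  default; `legacy_wellness` forces the questionnaire step to always
  advise Wellness (the closest reproducible reading of "advised more
  often than was correct"), and `exclude_wellness` drops Wellness from
  the congruency analyses, as the published evaluation did.

All thresholds live in one `RunConfig` object because threshold choice is
itself an open question in this kind of decision procedure; the defaults
are the deployed values.

## Network estimation

Per participant, completed beeps (rows with every mapped item answered —
listwise deletion; no imputation, detrending, or within-day centering)
are pooled into a Pearson correlation matrix R over the retained nodes,
and partial correlations are read off the standardized inverse:
ρ̂ᵢⱼ = −Pᵢⱼ/√(PᵢᵢPⱼⱼ), P = R⁻¹. Filters, applied in order:

1. **Compliance:** ≥ 50 of 84 beeps (`min_beeps`), read as an inclusive
   bound on the count of fully answered beeps.
2. **Variance pruning:** nodes with sample SD < 10 slider units
   (`sd_min`, n−1 denominator) are removed — near-constant items carry no
   contemporaneous signal. The yes/no social-company item is coded 0/100
   so the rule operates on the common scale (0/1 coding would force its
   removal at any mixing rate).
3. **Estimability:** ≥ 3 retained nodes and n > k+2 observations;
   correlation matrices with condition number > 1e8 are declared
   infeasible, reporting the most collinear pair.
4. **Edge threshold:** |ρ̂| ≥ 0.3 (`edge_min`), absolute value, inclusive.
   The absolute-value reading follows from the procedure's own use of a
   negative anxious–positive-affect association in its feedback script;
   `signed_edges` restores the signed reading.

Every infeasibility is data (a `SymptomNetwork` with `feasible=False` and
a reason), never an exception: participants without a network simply
receive no network-based advice.

Two-sided p-values for each partial correlation come from the t transform
with df = n − k (k retained nodes); they are metadata only — the operative
edge filter is the magnitude threshold, which is the only numerically
specified rule.

## Advice and ranking

Trigger map (hub nodes *anxious*, *sad*): experiential avoidance,
behavioral avoidance, social company → Exposure; social company, activity
investment → Behavioral Activation; positive affect, anger, loneliness →
Enhancing Positive Affect; stressed → Wellness; fatigue → Sleep. An edge
between the two hubs advises nothing.

The 9 candidate combinations are generated by constrained enumeration
(triples containing Behavioral Activation or Exposure), indexed
canonically: BA-without-Exposure sets, Exposure-without-BA sets, then the
three BA+Exposure sets, which are flagged time-consuming. The qualitative
ranking rule — interview- and questionnaire-based combinations above
network-based ones — is formalized as the lexicographic key
(covered_primary, covered_network), the minimal model consistent with the
documented worked example (a fully questionnaire-covered triple first,
the two EPA-covering triples second). Tier 1 holds all key-maximal
candidates; tier 2 holds the next-best key when more than three modules
were advised overall. An exhaustive check of all 4×8×32 source states
against a brute-force scorer confirms the ranking.

Choices recorded through shared decision-making may deviate freely
(guidance, not a rule); a choice without either core module is accepted
with a warning flag, and every module is annotated
advised-and-chosen / advised-not-chosen / chosen-not-advised.

## Congruency evaluation

Frequency tables report counts with percentages rounded half-up to two
decimals. 2×2 tables cross participants by module membership in two
axes; module/axis pairings without meaning (e.g. Behavioral Activation on
the questionnaire axis) are rejected. The chi-square statistic uses
Yates' continuity correction, Σ(max(|O−E|−0.5, 0))²/E with df = 1
(flooring the correction avoids inflating near-perfect fits); the test is
withheld whenever any observed cell is below `min_cell` (default 2, which
reproduces the two documented skipped tests with cells of 0 and 1) or a
margin is zero. Expected counts below 5 do not skip the test but raise a
caution flag. No effect sizes, exact tests, or multiplicity corrections
are computed.

## Synthetic cohort

The generator emulates all three input streams with a known ground truth;
its defaults are the study conditions: 74 participants, prior-disorder
mix 20/74 depressive-only, 7/74 anxiety-only, 47/74 both (the exact
printed fractions; the rounded percentages do not sum to one),
questionnaire totals targeting means/SDs 15.76/3.34 (SRSQ), 33.32/5.19
(PA), 18.54/6.00 (NA), 47.96/10.61 (MHC-SF), 84 beeps, and an 85%
beep-completion rate (~71 completed beeps; no completion rate is
published, so a value comfortably above the 50-beep requirement was fixed
once as realistic for a guided study).

- **Items** come from a discretized latent-Gaussian scheme: a shared
  per-participant latent plus per-item noise (noise SD capped at 35% of
  the item range), rounded and clipped to the coded range, with the
  latent mean calibrated by root-finding so the *discretized* total mean
  hits the target despite floor/ceiling bias. This is a test harness, not
  a model of the instruments' psychometrics.
- **EMA streams** are i.i.d. draws from the multivariate Gaussian whose
  unit-diagonal precision matrix realizes the specified
  partial-correlation matrix (positive-definiteness checked by Cholesky),
  scaled to mean 50 / SD 15 per node on the 0–100 sliders (clipping mass
  < 1%, so attenuation is negligible; the unclipped pathway is available
  for oracle tests). Social company is dichotomized at its median and
  recoded 0/100. Missingness is beep-level MCAR. The default ground-truth
  network is a sparse, diagonally dominant structure linking anxiety and
  sadness to stress, positive affect, fatigue, and avoidance. No diurnal
  cycles, autocorrelation, or reactivity are modeled: recovery tests
  establish estimator correctness under the model's own assumptions, not
  robustness to real diary dynamics.
- **Choice models**: adherent (top-ranked combination),
  positivity-biased (swaps Sleep/Exposure for Enhancing Positive
  Affect/Wellness with configurable probability — reproducing the
  observed preference for positively framed modules), and uniform random.

All randomness derives from one spec seed through named generator
streams, so identical specs serialize identically.

## Problem sizes and numerical tolerances

Monte-Carlo calibrations use 500 replicates at the design size (84 beeps,
11 nodes); the oracle-equivalence check uses 200 random instances
(agreement to 1e−8; observed ~1e−16); entrywise parameter recovery to
0.02 uses 40,000 observations, the size at which the maximum over 55
entries of the sampling error (SD ≈ 1/√n) sits below that bound; the
end-to-end sweep runs 100 seeds at 4 participants each. Symmetry of the
partial-correlation matrix is enforced to 1e−10 by averaging with its
transpose.

## Known limitations

- **Empty-network specificity at the design size.** With the deployed
  thresholds (|ρ̂| ≥ 0.3 over 11 nodes at 84 beeps), the null sampling SD
  of a partial correlation is ≈ 1/√73 = 0.117, so an edge-free ground
  truth still yields ≈ 0.49 expected false edges per network and an
  empty estimated network only ≈ 62% of the time. Per-pair specificity
  is ≈ 99.1%, and a true partial correlation of 0.6 is recovered (with
  the correct module advised) in >99% of replicates — but "no true edges
  ⇒ no estimated edges" is not a property these thresholds can deliver,
  which is worth bearing in mind when reading individual networks.
- The exact mapping from the 14 diary items to the 11 nodes is not
  public; the default maps the ten node-named sliders and the yes/no item
  directly and ignores four filler items, and is user-overridable.
- The engine models the decision procedure, not the intervention:
  module content, delivery, and outcomes are out of scope.
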