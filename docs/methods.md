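# Methods

This note documents the models and procedures `aquamicrobe` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The analysis problem

Full-length 16S amplicons sequenced on a nanopore device carry realized
per-base error rates above 10% even when the basecaller predicts a median
Phred of ~15 (≈3%). At that error level a read maps ambiguously to many
near-identical database references, so direct best-hit counting both
scatters counts across spurious references and mis-ranks taxa. The package
resolves this with an expectation-maximization estimator over per-read
alignment weights, validates it against a ground-truth table from a
second platform, and feeds the resulting genus count tables into the
ecology and association statistics of a six-tank aquaponics experiment
(two inoculation arms × three compartments × three sampling days).

## Read QC

Reads are trimmed 10 bp at the 5' end (low-quality start), truncated to
1.5 kbp (the expected 16S length; truncation, not removal — a read longer
than the cap is kept in truncated form), and discarded when expected errors
EE = Σᵢ 10^(−Qᵢ/10) exceed 200 or the read carries more than two N calls.
Both thresholds are strict (`>` fails), so boundary reads pass. EE is
computed on the post-trim qualities, and the trim precedes the length cap;
the reverse order would change which bases survive. Both rules are pure
per-read predicates, so filtering is order-independent; the report tallies
a read under the first failing rule (EE, then N).

## EM quantification

**Compatibility weights.** Each retained alignment contributes a weight
proportional to its identity (`n_matches / block_len` from the PAF
mandatory columns); when a PAF `AS:i` alignment-score tag is present it is
used instead, and a `uniform_weights` flag treats all reported alignments
equally. Per read, duplicate (read, reference) pairs keep their best score,
the top 100 alignments are retained, and weights are normalized to sum to
one.

**EM.** θ is initialized uniform over references with at least one positive
weight. Each iteration computes responsibilities γᵢᵣ = θᵣwᵢᵣ/Σθᵣ'wᵢᵣ' and
updates θᵣ = Σᵢγᵢᵣ/n. Iteration stops when max|Δθ| < 1e-6 (configurable) or
at 1000 iterations, in which case the estimate is returned with
`converged=False` and a warning — near-identical within-genus references
make the ref-level fixed point approach slowly, while genus-level sums
stabilize quickly, so the cap is a pragmatic cost bound rather than a
quality gate. The log-likelihood Σᵢ log Σᵣ θᵣwᵢᵣ is recorded every
iteration and asserted non-decreasing on every run; Σθ = 1 is maintained
to 1e-12.

**Cutoff and collapse.** Expected counts θᵣ·n are rounded half-up (counts
are read units) and references below 300 are dropped as spurious; the
comparison is inclusive (exactly 300 is retained) and the cutoff is a plain
parameter. Surviving counts are *not* renormalized — they feed downstream
in read-count units. Counts are summed onto a taxonomic rank (default
genus); references unassigned at that rank pool into an explicit
`unclassified` bin. The naive baseline assigns each read wholly to its
best-scoring reference, breaking exact ties to the lexicographically
smallest reference id for reproducibility.

## Validation

Concordance against a ground-truth table is computed per rank on the taxa
observed (> 0) on both platforms: ordinary least squares on log10
abundances plus Spearman ρ. Zeros never enter the regression (no
pseudocounts), matching a comparison restricted to taxa detected by both
technologies; with fewer than 3 shared taxa the regression fields are NaN.
Spurious taxa are defined per rank as estimate-only; the removed fraction
at a cutoff counts spurious taxa strictly below it, and is defined as 1
(flagged vacuous) when no spurious taxa exist. Raw counts are compared by
default (each platform keeps its own scale); a `relative` flag switches to
proportions.

## Diversity

Counts are rarefied without replacement (exact multivariate hypergeometric
sampling) to a common depth — 9000 reads at full scale; the alternative
3000-read depth seen in practice is just a parameter change. Shannon
diversity is reported in nats. Beta diversity uses Bray-Curtis on rarefied
counts (Jaccard and Euclidean available); ordination is classical PCoA on
the Gower-centered squared-distance matrix with negative eigenvalues
reported but excluded from coordinates and variance proportions.

PERMANOVA is the sequential (Type I) multi-term decomposition: terms enter
in the given order (compartment, inoculum, compartment:inoculum), each
term's SS is the increment of tr(HG) over the previous model, pseudo-F uses
the full-model residual, and p-values come from free permutation of sample
labels with the +1 correction, p = (1 + #{F* ≥ F}) / (1 + n_perm), so p is
never zero. Term R² values plus the residual sum to one by construction
and order matters for correlated factors — both are asserted in tests. No
within-stratum (tank-restricted) permutation scheme is applied.

## Nitrogen cycling

Analyte series are reduced to per-tank trapezoidal AUCs over observed days
(mg·day/L); missing days are simply absent nodes, with no interpolation.
The nitrate AUC model `nitrate ~ inoculum + dead_fish` is ordinary least
squares with sequential ANOVA sums of squares in formula order; a constant
covariate is reported with R² = 0 and a flag instead of failing. Chemistry
screens reduce each tank's series to its time mean (AUC selectable) and
compare arms per analyte with Welch's t-test (Satterthwaite df), with no
multiplicity correction — they are reported as individual tests.

## Association testing

Size factors follow the "poscounts" definition: the per-taxon reference is
the n-th root of the product of its positive counts (zeros skipped in the
product, counted in the root), each sample's factor is the median of
count/reference over its positive taxa, and factors are centered to
geometric mean 1. Taxa enter testing when their mean count exceeds 10
(strict) and they appear in at least two samples.

Each taxon is tested by a negative-binomial GLM likelihood-ratio test with
log link and log size-factor offset: full model = intercept (+ confounders)
+ covariate, reduced model drops the covariate. The dispersion is the
per-taxon maximum-likelihood estimate under the full model — computed by a
bounded 1-D search over log10 α of the Cox-Reid adjusted profile likelihood
(−½ log det X'WX), the standard small-sample bias correction; without it
the dispersion estimate is biased low at a handful of samples per group and
the test runs anticonservative. The estimate is held fixed for the reduced
fit and the statistic 2(ℓ_full − ℓ_reduced) is referred to χ²₁. No
empirical-Bayes sharing of dispersions across taxa is performed — a
deliberate divergence from DESeq2's shrinkage machinery, with calibration
verified by null simulation in the test suite instead. Non-converged fits
are reported with NaN p-values and excluded from FDR adjustment.

BH adjustment is the literal step-up with cumulative minima, applied within
each (compartment × response) family. Significant taxa are only *reported*
when they exceed 300 counts (strictly) in at least two samples. Tests run
per compartment, never pooled, on treated samples only (the shared
pre-treatment sample carries no covariate value). Mann-Whitney U uses the
exact distribution for combined n ≤ 20 without ties and the tie-corrected
normal approximation above; Spearman ρ is the Pearson correlation of
mid-ranks, with an exact enumeration p for n ≤ 8 and the t-approximation
above.

## The synthetic study generator

The generator emulates the experiment the statistics were built for, so the
whole pipeline is testable without any download.

- **Reference database**: 5 genera × 3 references, 1490 bp each, descending
  from one root: genus ancestors at half the between-genus divergence
  (default 0.20) from the root, members at half the within-genus divergence
  (default 0.02) from their ancestor. Realized divergence ordering is
  checked on every instance. Substitution-only mutation keeps all sequences
  alignable by position; length variation is not modeled. The default genus
  roster names the designated pathogen-like genus "Pseudomonas", the
  diazotroph-like genus "Rahnella", and a denitrifier-like "Rhodanobacter"
  that dominates the commercial inoculum.
- **Communities**: genus-level mean profiles per (tank, compartment, day)
  with Dirichlet noise (concentration 200). EIT rhizospheres ramp the
  pathogen-like genus to 50–80% by day 61 while CIT roots stay below 20%
  and gain the diazotroph (~30%); biofilters in both arms carry the
  pathogen at 5–30%. Background genera follow a geometric tilt (0.6ⁱ) —
  real communities are uneven, and exactly-tied truth proportions would
  make rank-recovery checks degenerate. Day 0 is pre-treatment: one shared
  rockwool root sample (tank id 0, inoculum "initial" — plants enter the
  tanks weeks after inoculation, so per-tank day-0 root samples do not
  exist), and biofilter day-0 profiles equal to their inoculum (commercial:
  denitrifier-dominated; established: pathogen already present). One
  designed missing feces sample mirrors the unbalanced real design.
- **Reads**: sources drawn multinomially from the profile (uniform within
  genus), per-base deletion/substitution/insertion noise at 3/6/3% (12%
  total — the realized nanopore regime), and predicted qualities from a
  two-component mixture (70% of reads around Q17, 30% around Q7, sd 3)
  whose overall median is ~15 and whose low tail gives the EE filter a
  realistic ~30% to remove. N bases are injected at 5×10⁻⁴/base. Truth
  tags (read → source reference) are emitted alongside.
- **Alignment scoring**: per read, the fraction of its 9-mers present in
  each reference, computed by table lookup; the top ≤100 references with
  score ≥ 0.10 become alignment records whose identity equals the score.
  The 0.10 floor corresponds to ~77% identity at k=9 — about the weakest
  hit a long-read aligner reports; a lower floor admits flat cross-genus
  noise alignments that let EM smear abundance toward dominant taxa. True
  banded alignment over all read × reference pairs is beyond desk scale;
  real PAF input remains the production path.
- **Chemistry**: Gaussian-bump ammonia (peak day 10) → nitrite (day 22) →
  nitrate (day 32) cascades with multiplicative log-normal noise, drawn
  independently of the spike flag so spiked and unspiked runs at one seed
  differ only by the added spike mass; the designated death tank gets a
  transient nitrate spike at day 35. pH is a flat control analyte.
- **Phenotypes**: 13 plants per tank measured every 3 days from day 28;
  growth increments scale by 1 − e_path·(pathogen root fraction) +
  e_diaz·(diazotroph fraction) with defaults 0.9/0.8, noise-clipped at
  zero so heights are non-decreasing. Leaves are Poisson increments and
  root length tracks height.
- **Fish deaths**: one per arm by default (tanks 3 and 6; tank 3 drives
  the nitrate spike), making mortality orthogonal to inoculum — matching
  a study outcome in which mortality was independent of the root
  microbiota. Unbalanced mortality patterns can be configured.

What passing tests on this generator do **not** show about real data: no
chimeras (removal is out of scope), no quality-error correlation (realized
errors are independent of predicted Q), no strain-level structure, no
richness growth over time (the genus roster is fixed at 5, so alpha
diversity saturates rather than climbing as real colonizing communities
do), and a far smaller reference database than a production 16S resource.

## Problem sizes

Tests and the acceptance script run the study at desk scale: library sizes
are the full-scale range (9.8K–125K reads) shrunk by a factor of 8, with
the minimum compressed less than the maximum (≈2.1–3.6K reads/sample) so
the rarefaction depth, scaled by the same factor (1125 reads), remains
feasible in every sample after the ~30% QC loss. Count cutoffs scale with
the same factor (300 → 37.5) to preserve their relationship to library
size; cross-table spurious-mapping checks use unscaled tables and the
unscaled 300-count cutoff. The end-to-end recovery test quantifies the
root compartment (the compartment its assertions concern) over 10 seeded
replicates; null calibration of the NB-LRT uses 18 samples × 1500 null
taxa, PERMANOVA null uniformity uses 200 replicates at n=12 with 199
permutations.

## Numerical choices and degenerate inputs

- EM: ties in naive counting break lexicographically; empty compatibility
  matrices are errors; references with no alignments keep θ = 0.
- Rarefaction deeper than a library names the offending sample in the
  error.
- PCoA eigenvalues below 1e-10 of the maximum count as null axes;
  all-coincident points give zero-dimensional coordinates.
- Welch's test refuses two zero-variance groups; Spearman refuses constant
  vectors; Mann-Whitney falls back to the tie-corrected approximation when
  ties preclude the exact distribution.
- The NB dispersion search runs over α ∈ [1e-10, 100] and snaps to the
  Poisson boundary when the profile is flat there, so Poisson-generated
  data reproduce the Poisson GLM LRT.
- Pipeline stage seeds derive from the global seed via fixed
  `SeedSequence` spawn keys indexed by stage slot, so adding a stage never
  perturbs earlier stages' randomness; all derived seeds stay below 2³¹.

## Known limitations

- The NB-LRT remains mildly anticonservative at n=18 even with the
  Cox-Reid adjustment (dispersion uncertainty is not propagated into the
  χ²₁ reference); the null calibration test quantifies this directly.
- The EM estimator inherits whatever sharpness the alignment weights have:
  with flat weights (e.g., a permissive score floor) ambiguous mass drifts
  toward dominant taxa. Identity-based weights from a real aligner are
  sharper than the k-mer stand-in's scores.
- Sequential PERMANOVA R² values are order-dependent by design; the
  reported decomposition fixes the order compartment, inoculum,
  interaction.
- The pipeline treats each sample's quantification independently; no
  cross-sample information sharing is attempted anywhere before the
  association stage.
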