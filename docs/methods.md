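# Methods

## Scope and data model

`acmgml` classifies rare germline BRCA1/BRCA2 variants (GRCh37,
transcripts NM_007294 / NM_000059) into P/LP, VUS and B/LB. It does not
run annotators: VEP/MMSplice/RepeatMasker outputs, population frequencies
and the ClinVar extract are consumed as tables. The unit of work is the
`AnnotatedVariant`, keyed by a normalized `VariantKey`. Copy-number
variants and genes other than BRCA1/2 are out of scope.

Coordinate and allele conventions:

- Variant keys are 1-based (VCF convention); interval arithmetic is
  0-based half-open (BED convention); conversion happens only at the
  boundary between the two.
- Alleles are normalized to a minimal representation by trimming shared
  prefix/suffix bases (the `-` indel dialect is mapped to an empty allele
  first). Full left-alignment would require reference sequence context,
  which the package deliberately does not depend on; prefix/suffix
  trimming is sufficient to make key equality well-defined for the
  same-site comparisons the evidence rules perform (PS1's "different
  nucleotide change, same amino-acid change").
- A normalized pure insertion has an empty reference span; for repeat
  overlap it is assigned the single base at its insertion point, so
  insertions inside repeat tracts can still receive BP3.
- Absent and zero are distinct states for allele frequencies: `None`
  means "not in the extract" and is what PM2 keys on; 0.0 is an observed
  frequency (also accepted by PM2, since a zero-count entry is still
  absence from controls).

## Evidence engine

Seventeen ACMG-AMP criteria are coded as binary flags; the remaining
eleven need per-case evidence (segregation, de novo status, functional
assays) that no annotation table carries. The classical ACMG rule
combiner is intentionally not implemented — the two-tier classifier
replaces it. All thresholds sit in `EngineConfig`:

| parameter | default | role |
|---|---|---|
| `ba1_af_threshold` | 0.05 | BA1: stand-alone benign above 5% pooled AF (strict >) |
| `bs1_af_threshold` | 0.01 | BS1: above the 1% rare-variant ceiling for a dominant disorder |
| `ps4_or_threshold` | 2.0 | PS4: minimum case–control odds ratio |
| `ps4_p_threshold` | 0.05 | PS4: two-sided Fisher exact significance level |
| `gerp_threshold` | 2.0 | PP3/BP7: GERP++_RS conservation cutoff |
| `splice_score_threshold` | 0.6 | PP3/BP7: dbscSNV ada/rf cutoff |
| `mmsplice_threshold` | 0.85 | PS1/PM5 gate: exclude predicted splice-mediated effects |
| `clinvar_min_stars` | 2 | reference admission: review status ≥ 2 stars |
| `brca2_terminal_codon_boundary` | 3326 | PVS1 exception: clinically tolerated BRCA2 truncation region |
| `bp4_mode` | `paper_complement` | see below |

Design choices where the rule text left room:

- **BRCA2 terminal-exon exception.** "The last amino acids of the last
  exon" has no published numeric cutoff; codon 3326 (the boundary of the
  established clinically tolerated truncation region) is the default and
  is configurable. When exon or codon fields are absent the exception is
  not evaluable and PVS1 follows the main loss-of-function rule, with a
  warning.
- **PP3/BP4 complementarity.** The rule as stated makes BP4 the exact
  complement of PP3 whenever at least one in-silico score exists, which
  contradicts the "multiple concordant benign lines" reading. The default
  `paper_complement` mode implements the complement literally;
  `benign_concordance` requires every present score to be benign for BP4.
  Both modes yield (0,0) when no score is present.
- **BP7 missing scores.** Missing ada/rf is treated as "no splice
  impact": dbscSNV only covers splice-region positions, so absence is
  informative. Missing GERP++ blocks BP7: absence of a conservation score
  says nothing about conservation.
- **PS1/PM5 splice gate.** An absent MMSplice score leaves the gate open
  (logged): the gate exists to exclude splice-confounded changes, and
  absence of evidence is treated permissively, consistent with the other
  criteria's fallbacks. PS1 compares normalized genomic keys; PM5 is
  suppressed when PS1 fires.
- **Stop-loss** variants satisfy both the loss-of-function list (PVS1)
  and the protein-length rule (PM4), and the engine assigns both, as both
  rules literally include them.
- **PS4 statistics.** Two-sided Fisher's exact test under the
  point-probability convention (sum of all hypergeometric outcomes no
  more probable than the observed one, relative tie tolerance 1e-7),
  computed from `scipy.stats.hypergeom` with margin-group batching. A
  zero row margin (an empty cohort) is an error; a zero column margin
  leaves a single admissible table and p = 1. Odds ratios use the
  Haldane–Anscombe +0.5 correction when any cell is zero — routine for
  rare variants absent from controls — and the result is flagged as
  corrected.
- **Structural invariants.** PM1 = PP2 = BP1 = 0 always; PP3·BP4 = 0,
  PP5·BP6 = 0, PM4·BP3 = 0, PM2·BA1 = PM2·BS1 = 0, BA1 ⇒ BS1. These are
  asserted on every assembled vector and fuzz-tested.

## Two-tier serial classification

Tier 1 separates VUS from the pooled P/LP ∪ B/LB ("other"); tier 2
separates P/LP from B/LB. Each tier is split, cross-validated and tested
**on its own dataset** (tier 1 on all variants, tier 2 on the non-VUS
subset): at the design cohort's class counts (173/130/194) this yields
the test supports 100 and 74. The cascade (`predict_serial`) is how new
variants are classified, not how per-tier metrics are computed.

Protocol: stratified 80/20 split (test takes `ceil(0.2·n)` rows,
scikit-learn's convention, which reproduces both printed supports);
3-fold stratified CV re-shuffled independently 20 times on the training
split (the split itself is fixed; only folds re-shuffle). Eight
algorithms with pinned hyperparameters: LR (newton-cg), LDA (svd), KNN
(k=5), CART (gini), BernoulliNB (`fit_prior=False`, i.e. uniform class
priors), linear-kernel SVM, RF (200 trees, 11 features per split), MLP
(one 11-unit hidden layer, LBFGS, 400 iterations). Unspecified settings
are frozen explicitly in `default_specs()` and echoed into run reports so
nothing drifts with library defaults.

Metrics are one-vs-rest per class (precision, recall, specificity, F1)
plus support-weighted averages; weighted recall equals accuracy by
construction. Support-weighting of *specificity* is ambiguous in parts of
the literature (a published weighted specificity of 0.96 for the tier-1
worked example is reproducible neither under support- nor
negatives-weighting, which give 0.97 and 0.92); the report therefore
carries both conventions and no test forces a match. Display rounding is
half-up to 2 decimals; comparisons against published table values are
made on rounded display values. AUROC is computed from the Mann–Whitney
U statistic with ties at 0.5, with curve points exported via
scikit-learn.

Feature analysis: Spearman rank correlation (average ranks on ties)
across the 17 criteria flags pairs at |ρ| ≥ 0.85; constant columns have
undefined correlation and are never flagged. Feature importance is the
mean absolute Shapley attribution of the tier model's positive-class
score over training rows, against a background sample. For ≤ 12
non-constant binary features the attribution is **exact**: the model is
evaluated once on every attainable pattern and the coalition sums reduce
to bitmask arithmetic over cached predictions; otherwise a seeded
permutation-sampling estimator is used. Features at or below mean |φ| =
0.01 are flagged as candidate-droppable; constant features attribute
exactly 0 by the null-player axiom.

## Synthetic data generator

The generator emulates the *tabular interface* of a real cohort, not its
biology. Each variant draws a latent class from the 173:130:194 mixture,
then an evidence pattern from a hand-curated library whose additive score
(+8 very strong, +4 strong, +2 moderate, +1 supporting; −8 stand-alone,
−4 strong, −1 supporting benign) falls in that class's band (P/LP above
+6, B/LB below −4, VUS between). Annotation fields are then sampled
*backward* from the pattern — inside the triggering region for intended
criteria, outside it for all others — and the engine is run on every
generated variant to verify the intended vector, so generator/engine
agreement is enforced, not assumed. Label noise flips the final label to
a uniformly drawn different class with probability ε, emulating
inter-interpreter disagreement. Output is byte-identical under a fixed
seed.

What it does **not** emulate: real nucleotide context or haplotypes,
gnomAD population structure, correlated annotation errors, or evidence
patterns outside the library. Passing tests on synthetic data therefore
demonstrate that the pipeline recovers labels that are a (possibly
noisy) function of the criterion vector — they do not measure accuracy
on real cohorts, whose labels encode evidence the 17 automated criteria
cannot see.

A note on the noise experiments: the generator's three-class flip changes
the *effective* noise rate of the tier-2 subproblem (flips to VUS remove
rows from the subset; VUS rows flipped into P/LP or B/LB enter it with
uninformative labels). The "best tier-2 accuracy ≈ 1−ε" check therefore
applies binary flips directly to the tier-2 labels, where 1−ε is a true
ceiling.

## Problem sizes and determinism

The validation suite runs the Fisher-vs-enumeration sweep over all 2×2
tables with N ≤ 60 (628,055 tables), fuzzes 10,000 random variants
against the vector invariants, and uses n = 2,000 synthetic cohorts for
the end-to-end noise experiments — sizes chosen so the whole suite
completes in a few minutes on one CPU while keeping binomial tolerance
bands (3 sd) tight enough to be meaningful. All randomness flows from
explicit seeds; reports and generated file sets are byte-identical across
reruns with the same seed.

## Known limitations

- PM1, PP2, BP1 are constant by design for BRCA1/2; a multi-gene
  extension would need real domain/missense-constraint logic.
- PS1/PM5 compare at the level of normalized genomic keys and annotated
  codons; without transcript-aware CDS mapping, complex substitutions at
  codon boundaries may be missed.
- The PP3/BP4 complement mode can assign BP4 on a single dissenting
  score; the alternative mode is provided but the contradiction is
  inherent to the rule text.
- The ClinVar-scale evaluation harness accepts any labeled criteria
  table, but no real ClinVar download ships with the package.
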