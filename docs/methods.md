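# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions and the open design choices behind `tregsec`.

## Differential expression

Array data are taken as log2 intensities; RNA-seq counts are normalized to
counts-per-million per sample and transformed log₂(CPM + 0.5) (the 0.5
pseudocount avoids log of zero while keeping low counts ordered).  Each
gene then gets a Welch two-sample *t*-test (unequal variances,
Welch–Satterthwaite degrees of freedom) with log2 fold change defined as
mean(case) − mean(control) on the log scale.

The DEG rule is deliberately the field's plain threshold rule rather than
a moderated-variance model: a gene is up when log₂FC > `fc_threshold`
(default 1) and *p* < `p_threshold` (default 0.05), down symmetrically,
ns otherwise.  Boundaries are strict by default ("more than two-fold"); an
`inclusive_fc` switch changes the fold-change comparison to ≥ for users
matching legends that print "|log₂FC| ≥ 1".  The raw p-value is
thresholded; a Benjamini–Hochberg q-value is attached to every table for
information only.  Moderated (empirical-Bayes) tests and count-model GLMs
are intentionally out of scope: the downstream quantities are set-algebra
counts and percentages, which are robust to the exact test as long as the
operating point is calibrated (see the recovery bounds below).

Genes with zero variance in both arms get *p* = 1 and a `zero_variance`
flag rather than a NaN — they can never be called, but they stay in the
denominator of every percentage.

**Housekeeping QC.**  ACTB, GAPDH, PGK1, PPIA, B2M, YWHAZ, SDHA, HMBS and
TBP are checked against a fold-change band, default (−1.3, 1.3) log2
units — wide enough to admit the fold-change range housekeeping genes
display across heterogeneous public Treg datasets while still catching
gross normalization failures.  Genes absent from a platform are reported
missing, not failing.  The band is a QC convention, not a rule derived
from any one dataset, and is configurable.

## Percentages and rounding

All table percentages are `round_half_away_from_zero(100·k/n, 2)`,
computed in exact decimal arithmetic.  This convention (rather than
banker's rounding) is pinned by tests because published count/percentage
tables of this kind are reproduced cell-exactly by it (e.g. 356/1584 →
22.47, 86/2608 → 3.30).  A zero denominator yields a missing value, never
0.

The `/DEG%` denominator is always the contrast's **total** DEG count
(up + down over all measured genes), not the catalog-restricted count —
the choice that makes the reproduced table cells arithmetically
self-consistent.  Catalog genes unmeasured on a platform are simply
absent from intersections; no coverage correction is applied.

## Gene catalogs and symbol matching

Symbols are matched after uppercasing and whitespace removal; mouse/human
pairs (Il6/IL6) intentionally collide, and no orthology mapping is
performed — intersections are plain symbol-set intersections.  The four
secretome catalogs must be pairwise disjoint (enforced at suite
construction); panels may overlap secretomes freely, since only the
secretome routes are defined as mutually exclusive.  Catalog content is
data: the package ships a GMT loader and a synthetic generator that
produces catalogs of the canonical full-scale sizes (2641 / 961 / 1223 /
6560 secretome genes, union 11,385; panels of 191 / 102 / 165; 9
housekeeping genes), not curated lists.

## Pathway activation calls

The enrichment p-value is the hypergeometric upper tail P(X ≥ k) for the
overlap k between the DEG set and the signature, in a universe of the
genes measured in that dataset (the standard enrichment background; using
the whole genome would anti-conservatively inflate enrichment).  The
activation score over signature members that are DEGs and carry a nonzero
expected direction is

  z = (c − d) / √(c + d)

with c sign-consistent and d sign-inconsistent members — the score of a
sign test under a symmetric null, so |z| ≥ 2 approximates a two-sided 5%
sign criterion.  Members with unknown direction (0) count toward k but
not z; when no directional member is a DEG, z is missing and the pathway
cannot be called.  Calls: activated iff p < 0.05 ∧ z ≥ 2; inhibited iff
p < 0.05 ∧ z ≤ −2; p is strict, z inclusive, both configurable.

This layer reproduces the *calling and accounting algorithm* only.
Signatures are user- or simulator-supplied; no proprietary pathway
knowledge base or its pathway names are included or reproducible here.

Group accounting: within a condition group a pathway called in ≥ 2
datasets with a consistent sign is *shared*, in exactly one *specific*,
and with opposite calls *dual*; the three labels partition the pathways
called at least once.  The ≥ 2 threshold is configurable.

## Regulator collaboration

Polarity convention: a gene DOWN after deleting or blocking a regulator is
a regulator-induced candidate; UP is regulator-suppressed.  Blockade
datasets (anti-CTLA-4, anti-PD-1) share the knockout convention.  Crossing
with the Treg DEG direction yields induced / suppressed / noncollab_up /
noncollab_down — always a disjoint cover of the Treg DEG set (a tested
invariant).  Two genuinely open choices are made explicitly:

* Same-direction overlaps (Treg-up ∧ perturbation-up) are
  non-collaboration — the regulator evidently does not *drive* the gene in
  the direction the Treg shows.
* Genes unmeasured in the perturbation dataset are non-collaboration by
  default, since DEG-table inputs cannot distinguish "not DEG" from "not
  measured"; a strict mode excludes them from the denominator instead.

Non-collaboration fractions are reported both over all Treg DEGs and
restricted per direction, because published headline fractions are
ambiguous between the two denominators.

## ROS regulatome

The partition is defined over genes DEG in **both** knockout contrasts
(the reading required for a three-class partition to total the
intersection): ROS-promoted = NOX2-KO-up ∩ NRF2-KO-down, ROS-suppressed =
the reverse, uncertain = same-sign in both.  Genes DEG in only one
contrast are excluded.  Swapping the inputs swaps promoted and suppressed
and fixes uncertain, and the three classes always conserve the
intersection size — both tested on random instances.  Gene-level (not
probe-level) intersection is assumed.

## Group statistics

Dispersion is the standard error of the mean, sd(n−1)/√n (missing for
single-dataset groups).  The default two-group test is Welch's *t*; with
fewer than 4 values on either side an exact Mann–Whitney U is used (exact
enumeration for min(n) ≤ 8 without ties, normal approximation with tie
correction otherwise).  With more than two testable groups the focal
group (default: tumor tissue) is tested against the pooled rest, matching
the one-group-vs-others comparisons this analysis style reports.  Groups
with < 2 datasets are summarized but excluded from testing, and the
exclusion is recorded.  No multiple-testing correction is applied across
the handful of group comparisons; BH q-values accompany per-gene and
per-pathway tables.  The Welch test's type-I error at nominal 0.05 is
verified by simulation to lie in [0.035, 0.075] (2000 Gaussian nulls,
n = 5 per arm).

## Synthetic-data model

The generator emulates the *structure* of public Treg profiling datasets,
with all truth planted by exact count (`round(frac·n)`), never by
Bernoulli draws, so recovery can be asserted exactly.

* **Array platform**: per-gene baselines ~ U(6, 12) log2 units; Gaussian
  noise, default sd 0.4 (typical residual spread of log-intensity
  replicates); planted mean shifts on case samples.
* **RNA-seq platform**: negative-binomial counts, default dispersion 0.1;
  relative abundances spanning ~2³–2⁹; library sizes log-normal around
  10⁶ with sigma 0.2, so CPM normalization is actually exercised.
* **Replicates**: 4 vs 4 by default — a deliberate convention typical of
  desk-scale public datasets, whose true per-dataset replicate counts are
  heterogeneous.
* **Effects**: planted |log₂FC| drawn uniform on [0.6, 1.4]× the mean
  effect size (default mean 2.0 → range [1.2, 2.8]), keeping every
  planted effect above the calling threshold while varying magnitude.
* **DEG fractions**: 5% up, 5% down by default; demo fixtures skew the
  tumor-tissue group toward downregulation (4% up / 8% down), mirroring
  the suppressed-transcriptome phenotype of tumor-infiltrating Tregs.
* **Catalog planting**: each catalog receives `round(rate·|catalog ∩
  measured|)` DEG members (default rate 0.06); the random fill prefers
  non-catalog genes so per-catalog counts stay exact when the DEG quotas
  leave room.
* **Regulator overlaps**: planted (induced, suppressed) fractions default
  to FOXP3 (0.85, 0.85), PD-1 (0.60, 0.50), CTLA-4 (0.15, 0.10) — the
  master transcription factor dominates, PD-1 contributes substantially,
  CTLA-4 blockade touches little.  Same-direction decoys (5% of planted
  DEGs) and perturbation-only DEGs (2% of genes) are added so the
  classifier must actively reject them.
* **Dual KO**: class sizes are arguments realized exactly; defaults in
  fixtures are (1384, 936, 10), plus blocks of single-contrast DEGs that
  the partition must exclude.
* **Randomness**: each stage draws from its own `SeedSequence`-spawned
  stream with documented keys, so adding a stage never perturbs another's
  draws; identical configs are bit-identical.

What the simulation does **not** model: batch effects, probe-level
structure, correlated genes, single-cell sparsity, or realistic pathway
co-membership.  Passing tests therefore demonstrate correctness of the
*algorithms* (calling, set algebra, accounting, statistics) and
calibration under idealized noise, not robustness to the full messiness
of public expression data.

### Frozen operating point

At the reference conditions (10,000 genes, 5% planted up, mean effect
2.0, noise sd 0.4, 4 vs 4, array), the DEG caller's Monte-Carlo operating
point over 20 seeds is sensitivity ≥ 0.9 and FDR ≤ 0.1 (measured ≈ 0.97
and ≈ 0.003); these bounds are frozen as regression tests and recomputed
at run time by `scripts/acceptance.py`.

## Pipeline determinism

`run_pipeline` executes load → DEG → decomposition → enrichment →
collaboration → ROS → panel screens → group statistics, writing TSV/JSON
per stage plus a manifest (config SHA-256, seed, per-stage row counts).
All float output uses a fixed format and all JSON is key-sorted, so
re-running an identical config is byte-identical — tested by hashing
every output file across repeated runs.

## Problem sizes

Default scales were chosen to keep any full run at interactive desk
scale: simulations use 10,000 genes (2,000 in the scaled-down unit-test
workspace), the Monte-Carlo operating point uses 20 seeds, the
calibration check uses 2,000 null simulations, and the demo pipeline
completes in a few seconds.

## Known limitations

* The threshold-DEG rule with raw p is intentionally unadjusted;
  interpret the counts as the analysis style defines them, not as
  FDR-controlled discoveries.
* Symbol-level matching without orthology mapping can both merge and miss
  genes when human catalogs meet mouse datasets.
* The activation z is a sign-agreement score on user-supplied signatures;
  it is not numerically comparable to scores produced by proprietary
  pathway engines, and pathway *names* from any such engine are out of
  scope.
* Group tests on two-dataset groups fall back to an exact Mann–Whitney
  whose smallest attainable two-sided p is above 0.05; significance
  claims need ≥ 4 datasets per side or a pooled comparison.
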