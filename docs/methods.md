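# Methods

## Background error model

Targeted UMI-consensus sequencing of cell-free DNA retains a small residual
error rate that varies by orders of magnitude across substitution classes.
`phylotrace` estimates this *within each library* rather than from a panel of
normals: deep alternate observations (DAO) and deep depth (DDP) are tallied
over the assay's non-variant positions per trinucleotide-context alternate,
after collapsing the 192 strand-specific classes to 96 reverse-complement
identical classes (the stored key is the lexicographically smaller of
`context>alt` and its reverse complement). Positions whose per-alternate VAF
exceeds 1% are excluded from estimation — at that frequency the signal is
more plausibly a germline variant or clonal haematopoiesis than PCR or
sequencing error (`vaf_exclusion`, default 0.01). This exclusion is applied
per position-alternate, reading the rule literally; applying it per position
across alternates would differ only at pathological positions.

Each class gets ER = DAO/DDP with an exact Poisson (Garwood) 95% interval on
the count with DDP as exposure: lower = χ²(α/2, 2k)/2, upper
= χ²(1−α/2, 2k+2)/2, divided by DDP. The method is not prescribed by the
framework being implemented; the exact Poisson interval was chosen to match
the Poisson testing machinery downstream, and it is validated in the tests
against a brute-force inversion of the Poisson tail sums.

Tracked variants are excluded from calling when their class's upper bound
exceeds `er_upper_limit` (default 1e-4, i.e. 0.01%), when annotated
off-target (a pass-through boolean — the information is an upstream aligner
concern and cannot be recomputed from count tables), when a two-sided
binomial test of the alternate-read strand split against the depth strand
split gives p < 0.01 with ≥5 alternate reads (read-strand and
sequencing-strand variants of the same statistic; thresholds are declared
defaults, exposed in `RunConfig`, since no canonical values exist), or when
the VAF outlier filter fires. The outlier filter partitions the passing
VAFs with k = 2 medoids; the high cluster is removed only when it holds ≤3
variants and the Wilson 95% intervals of the boundary members do not
overlap. Wilson intervals are a declared choice; the rule only asks for
"non-overlapping confidence intervals".

**1-D PAM.** All k-medoid steps operate on one-dimensional data, where the
optimal L1 partition is contiguous on the sorted values. They are therefore
computed by exact dynamic programming over contiguous segments (medoid = a
member point minimising within-segment absolute deviation; ties prefer the
earlier split) instead of heuristic medoid swapping. The tests compare the
DP against exhaustive enumeration of all contiguous partitions.

Qualified class rates are clustered into four **D-groups** and each group is
summarised by its DDP-weighted mean rate, Σ ER·DDP / Σ DDP. Grouping trades
class resolution for estimation stability: single classes can have few
background events, a pooled group has enough exposure for a precise rate.
Fewer groups are used (with a warning) when fewer than four distinct
qualified rates exist.

## MRD calling

The sample-level statistic is the total DAO over filter-passing tracked
variants; the null expectation is λ = Σ DDP·(D-group weighted rate). The
one-tailed exact Poisson test is the upper tail *including* the observed
value, p = P(X ≥ obs | λ), so obs = 0 always gives p = 1; p < α (default
0.01) calls the sample ctDNA positive. λ enters the test unrounded; the
floor appears only where the printed estimators use it (below). Variant-level
calls use the variant's own class rate, not the group average — the group
average stabilises the panel-wide λ, while single-variant inference should
not borrow error from unrelated classes.

Derived quantities, with k* = the smallest integer with P(X ≥ k* | λ) < α:

- **Clonal ctDNA level** = max(0, (Σ DAO − ⌊Σ DDP·ER⌋) / Σ DDP) over clonal,
  non-hard-filtered variants; undefined when no clonal variant has depth.
- **MDAF** (minimal detectable allele fraction) = k*/Σ DDP over the tracked
  mutations considered; an optional seeded subsample studies panel-size
  effects (mirroring subsets of 1–150 mutations).
- **MDCL** (minimal detectable clonal level) = (k*_panel − ⌊λ_panel⌋)/Σ DDP
  over clonal variants, conservatively crediting all required reads to
  clonal positions.
- **Shedding classifier**: OLS of log10 clonal level on log10 tumour volume
  (cm³) and a binary histology covariate, fitted on ctDNA-positive cases
  (≥3 per histology group required). A ctDNA-negative case is a *probable
  technical negative* when the lower bound of the 95% prediction interval
  for a new observation falls below the library's MDCL, else a *probable
  biological low-shedder*; a bound exactly at MDCL counts as detectable.
  The stricter new-observation interval is used rather than the
  mean-prediction band, since each patient is a single new draw.

## Subclonal deconvolution

The forward model for a mutation with multiplicity m at a locus with total
tumour/normal copy number CNt/CNn in a sample of ctDNA tumour purity P is
VAF = P·m·CCF/(P·CNt + (1−P)·CNn). Both inversions used below are verified
in the tests against numerical root-finding of the forward equation.

1. **Denoising.** Per clone, variants are k-means-clustered (1-D, on
   expected error reads ER·DDP, deterministic quantile initialisation) into
   g = min(4, max(1, ⌊total expected error reads⌋)) groups, so each group
   carries roughly at least one expected mutant read; a clone with under two
   expected error reads keeps one group. Denoised VAF = (DAO − group mean
   expected error)/DDP. Denoised VAFs may be negative; the raw value is kept
   for diagnostics and clamped to zero only where it enters the purity/CCF
   formulas, avoiding negative purities.
2. **Purity.** For each clonal mutation, P_i = VAF·CNn/(m − VAF·(CNt−CNn))
   (the forward model solved at CCF = 1); the sample purity is the
   unweighted mean of P_i clamped to [0, 1]. Weighting by depth is a
   plausible alternative; unweighted is used absent a stated rule.
3. **CCFs.** CCF_i = VAF·(P·CNt + (1−P)·CNn)/(P·m), capped at 1 per
   mutation (estimates above 1 are noise); a clone's CCF is the mean over
   its mutations.
4. **Quality.** A clone's normalised SD is the coefficient of variation
   (sample SD / mean) of its per-mutation CCFs — "normalised SD" is not
   otherwise defined, and CV is the reading adopted. Clones above the
   threshold (default 0.56) are flagged poor quality and excluded from
   downstream classification; single-mutation and zero-mean clones are not
   flaggable. `calibrate_ccf_sd_threshold` re-derives the threshold from a
   dataset's own clonal clusters in >5%-purity samples as the empirical
   upper 95% quantile of their CVs, falling back to the default below five
   qualifying values.
5. **Clone presence** and 6. **tumour presence**: one-sided Poisson test of
   Σ DAO against Σ DDP·ER over the clone's (or panel's) variants, excluding
   hard- and mid-filtered variants; α = 0.01 to match the MRD threshold.
7. **Minimal detectable CCF** per clone: k* on the clone's summed background
   λ, spread over the clone's total depth (equivalently, k*/n reads per
   mutation at the clone's mean depth), converted through the step-3
   equation with clone-average m and CNt at the sample purity.
8. **Representative minimal detectable CCF**: the same computation for a
   hypothetical subclone of `representative_n_mut` (default 4) mutations
   carrying the sample-average subclonal error and depth — one comparable
   sensitivity figure per sample.
9. **Minimal detectable purity**: panel-wide k*/Σ DDP converted through the
   step-2 (clonal) inversion with panel-average annotation.
10. **Clonal sweeps.** A subclone that swept to fixation is indistinguishable
    from the clonal cluster, so the test is framed with a sweep as the null:
    a Wilcoxon rank-sum test compares the subclone's per-mutation CCFs with
    the clonal cluster's, one-sided (subclone below clonal) since the
    alternative of interest is being below 100% CCF (a two-sided option is
    exposed). A sweep is called when p > 0.05 *and* the mean subclone CCF is
    ≥0.90. scipy's implementation provides exact enumeration for small
    tie-free samples and mid-rank normal approximation otherwise; identical
    constant samples short-circuit to p = 1.

Samples with clonal ctDNA level ≥0.1% and assay input ≥10 ng are tiered
"high subclone sensitivity"; clonal-architecture conclusions should be
restricted to that tier. A copy-number-naive comparator (mean subclonal VAF
/ mean clonal VAF) is included for benchmarking; on whole-genome-doubled
clonal backgrounds it systematically underestimates subclone CCFs, which the
copy-number-aware estimator corrects — this is demonstrated in the tests.

## Phylogenetic post-processing

*Ancestral presence* is the transitive closure: ancestors of detected clones
are marked present with `inferred` provenance. *CCF nesting* offers two
reconciliations, applied leaf-to-root: the default `paper` mode caps a
parent at the sum of its children's CCFs, reproducing the source procedure
literally; a `pigeonhole` mode instead raises the parent to at least the
children's sum, the standard nesting constraint. The literal rule inverts
the usual inequality and is kept as the default purely for fidelity; users
who want physically consistent trajectories should select `pigeonhole`.

*Dissemination classification* (latest high-subclone-sensitivity
postoperative sample): only primary-tumour subclones count — metastasis-
unique clones from excised lymph nodes or intrapulmonary metastases
represent metastasis-to-metastasis seeding, and poor-quality clones are
dropped. A detected clone is "below 100% CCF" when its rank-sum p against
the clonal cluster is <0.05 *and* its mean CCF is <0.90; "at 100%" is the
complement, so the two outcomes partition. Relapse is **monoclonal** when
the detected clones form a single root-to-leaf chain with none below 100%
(one expanding lineage explains every detection; the seeding clone is the
deepest). Otherwise it is **polyclonal**; the seeding set comprises the
detected-subtree leaves, every below-100% clone, and for each below-100%
clone the lineage carrying its complement (nearest detected ancestor, else
the trunk). Polyclonal relapse is **monophyletic** when the seeding clones
still lie on one chain, **polyphyletic** when they span branches. The
classifier is verified against an independently coded brute-force oracle on
every tree of ≤5 clones × every detected subset × below-100% assignment.

*Clonal illusion*: one tissue region is selected uniformly at random
(seeded); mutations are re-labelled clonal at >90% region CCF, region
annotations replace the multi-region ones, and the deconvolution is re-run
with mutation-specific CCFs only. Region-clonal mutations are labelled
`clonal` (clonal in all regions) or `clonal_illusion`; the plasma CCF is
the discrimination score, summarised by rank-based AUC (mid-rank ties) with
a stratified bootstrap 95% CI (500 resamples — an approximation to repeated
cross-validation, and documented as such).

## Simulator

The generator emulates the study conditions end to end: a random rooted
clone tree whose CCFs are Dirichlet stick-broken so every parent ≥ Σ
children; panels with ~126 clonal and 4 mutations per subclone by default; a
quarter of clonal mutations at multiplicity 2/CNt 4 (whole-genome-doubled),
reproducing the clonal-vs-subclonal multiplicity asymmetry; log-normal
96-class error (median 1e-5, σ 0.8, transitions ×5); and consensus depth
Poisson-distributed around input_ng × 303 × conversion_efficiency (303
haploid genomes per ng at 3.3 pg/genome; efficiency default 0.6, since
library conversion is never stated — it is swept in the benches). All
generators are pure functions of (config, seed).

What the simulator does **not** reproduce: over-dispersed depth across
positions (primer-dependent coverage; the real assay's depth-input relation
is only rank-correlated), UMI family-size effects, inter-position error
correlation, clonal haematopoiesis beyond the VAF exclusion, and consensus
depth above one read per input genome copy (e.g. counting both duplex
strands). Passing benches therefore demonstrate correctness of the
estimators under the declared generative model, not assay performance on
real libraries. The last limitation is material for detection-rate
comparisons at low DNA input: with depth capped at 303 copies/ng, a
4-mutation subclone at 20% CCF in a 0.1%-clonal-level, 10 ng library
carries an expected mutant-read total of ~1.5–2.4 reads against a 2–3-read
calling threshold, which bounds its detection rate near 45% regardless of
implementation quality.

## Problem sizes and numerics

The test and acceptance benches use 200 libraries per LOD condition, 1,000
null libraries, 1,000 absent subclones, and a 70-patient CCF-recovery cohort
(3–8 clones each, clonal level log-normal with median 0.9%, per-variant
depth ~2,200× via 23 ng at conversion 0.32, matching the assay's observed
depth-to-input ratio); the whole suite runs in a couple of minutes on one
CPU. Poisson tails come from `scipy.stats.poisson.sf`; k* is found by a
short upward scan from the Poisson quantile; degenerate inputs (zero depth,
zero passing variants, zero purity, single-mutation clones) return missing
values or negative calls with explicit flags rather than raising. Seeded
runs are bit-reproducible; the CLI derives per-stage child seeds from the
master seed by hashing.
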