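# Methods

This note documents the statistical models, algorithmic choices and known
limitations of `crestmeta`. It is written for a user who wants to know
exactly what each stage computes and what the simulation-based tests do
and do not demonstrate about real data.

## The synthetic compendium

`simulate_expression` draws log2-scale intensities (lognormal on the linear
scale, the usual working model for normalised single-channel arrays):

* Gene baselines μ_g ~ N(`baseline_mean` = 8, `between_gene_sd` = 2) log2
  units. The between-gene spread matters because two filters in the suite
  (reference-gene presence, unexpressed-mRNA removal) are defined against
  per-sample intensity *percentiles*; a realistic multi-log2-unit spread is
  what gives those percentiles meaning.
* Within-gene residual noise s.d. `baseline_sd` = 0.5 log2 units. This is
  the residual within-subtype variability typical of normalised arrays for
  the bulk of genes; with it, a null sample exceeds 2-fold of the opposite
  group's mean ~2–3% of the time. A much larger value would make the
  per-sample 2-fold flags of the Boolean game matrices commonplace under
  the null, which is not how real null arrays behave.
* Planted differential genes (per group pair) receive symmetric
  half-effects: −Δ/2 in the pair's first group and +Δ/2 in its second,
  where Δ = `de_log2fc` (default 3, i.e. 8-fold). The full effect
  separates exactly the designated pair; any third group sits halfway, so
  with 1 ≤ Δ < 2 only the designated pair survives a 2-fold filter.
  "up" always means up in the pair's second group — the same sign
  convention the differential-expression tables use.
* Planted stable genes are re-anchored one between-gene s.d. above the
  baseline mean (so the presence criterion is about variance, not level)
  with a noise s.d. chosen so their linear-scale coefficient of variation
  sits near half of `stable_cv_max` (CV of a lognormal:
  √(exp(σ_ln²) − 1)); sampling noise then stays inside the bound.
* Optional floor genes sit 3 between-gene s.d. below the baseline mean —
  far below every sample's 20th percentile — to exercise the
  unexpressed-mRNA filter.
* Each study gets its own platform with an additive per-platform, per-gene
  shift ~ N(0, `platform_shift_sd`), drawn once per platform. Studies are
  analysed separately and combined only at the gene-list level, mirroring
  separate-platform practice, so the shift cancels within any one study's
  contrast but distinguishes platforms.
* miRNA profiles get a planted group effect (`mirna_de_log2fc`, applied in
  the last group, alternating sign across miRNAs). Each planted target row
  is rewritten as

  `target = baseline − √c · standardized(miRNA) · σ + √(1−c) · σ · ε`

  with c = `mirna_coupling`, so the miRNA explains a fraction c of the
  target's variance with inverted sign (sample correlation ≈ −√c) and the
  miRNA's group effect propagates to its targets with opposite direction —
  exactly the signal an inverse-expression leading-edge screen detects.
  Note that `simulate_mirna` therefore mutates the passed expression
  matrix's target rows in place.

Everything is driven by one integer seed through `numpy.random.default_rng`
and is reproducible bit for bit.

What the generator does **not** emulate: probe-level effects and
many-to-one probe→gene maps, normalisation artefacts, correlated gene
modules beyond the planted structure, heavy-tailed or intensity-dependent
noise, batch effects within a platform, and realistic miRNA target-set
overlap. Passing tests therefore demonstrate algorithmic correctness and
calibration under a clean generative model, not performance on any real
series.

## Differential expression

Tests run on log2 data; fold changes are reported on the linear scale as
ratios of group geometric means (2^Δmean on log2 data), signed: +r for
r-fold up in the second group, −r for r-fold down. The default t-test
pools variances (the classic microarray choice; Welch via
`equal_var=False`). One-way ANOVA p-values are BH-adjusted across genes;
Tukey HSD pairwise p-values come from the studentized-range distribution
with the pooled MSE (for two groups this reduces exactly to the t-test). A
pair flags a gene when adjusted ANOVA p and Tukey p are both < α and the
pairwise |FC| ≥ the threshold. BH is applied per study per comparison, not
pooled across studies, because studies/platforms are analysed separately.
Degenerate genes with zero variance everywhere get p = 1 and a
`zero_variance` flag (p = 0 if their means still differ).

Cross-study intersection keeps genes significant in ≥ `min_studies`
studies with the *same* fold-change sign wherever significant — the only
reading under which signed cross-study tables are well defined — sorted by
incidence count, then gene ID.

## The microarray game

For a contrast (A, B), the Boolean matrix for "up in A" sets entry
(g, sample j of A) to 1 when g's linear expression in j exceeds
`fc_threshold` × the geometric mean of g over all B samples (per-sample
pairing is impossible with unequal group sizes, so the opposite group's
geometric mean is the reference). The reciprocal framing of the same
direction flags B samples where expression falls below reference /
threshold.

The game v(S) = (1/m) · #{samples whose non-empty support ⊆ S} has Shapley
value φ(g) = (1/m) Σ_j x_gj / colsum_j over non-empty columns — each
sample's worth is shared equally among its supporting genes. Samples with
empty support carry no worth; by default they are excluded from the
average with a scale factor that preserves efficiency exactly
(Σφ = non-empty/m); `empty_column_policy="renormalize"` instead averages
over non-empty columns only. Normalisation divides by the maximum raw
value (all-zero matrices return zeros with an `all_empty` flag).

Selection: a gene is an index gene for a direction when its normalised
index reaches the cutoff (default 0.6, inclusive so that cutoff = 1.0
selects exactly the maximal genes) in *both* the direct and the reciprocal
run of that direction; the union over the two directions is reported with
direction labels. The brute-force solver enumerates all coalitions with
the standard |S|!(n−|S|−1)!/n! weights and is capped at 15 genes; it is a
validation oracle, never the production path.

The relative (max-normalised) cutoff means the method always measures
prominence *within* a contrast; under a pure null the maximum itself is
noise, and the double-run requirement is what keeps the null selection
rate negligible.

## Reference-gene screen

"Above 20 percent" is implemented as above the 20th percentile of that
sample's intensity distribution (linear interpolation), per sample across
all genes. The CV is computed across the pooled samples of both groups on
the linear scale — the stricter reading, consistent with reference-gene
semantics. The fold-change criterion uses group means by default
(`fc_statistic="median"` available) and is symmetric (max(r, 1/r) < 1.2),
so swapping the groups cannot change the result.

## GSEA

The default ranking metric is signal-to-noise with the canonical floor
(each group s.d. floored at 0.2 × |group mean|, 0.2 when the mean is 0);
t-statistic and log2-ratio are selectable. Positive scores mean higher in
the second group, and ties are broken by gene ID so rankings are
deterministic.

The running sum increments at set members by |score|^p (p = 1 by default)
normalised over members, and decrements at non-members by 1/(N − N_hit);
the ES is the signed maximum deviation, the first such index on exact
ties. If all member scores are zero the increments fall back to uniform.

The null is *gene-set permutation*: `n_perm` random same-size draws from
the ranked universe (shared between sets of equal size). Nominal p is the
side-matched one-sided frequency, floored at 1/n_perm so a p of zero is
never reported. NES divides the ES by the mean |null ES| of its sign. The
FDR q is the canonical NES-ratio estimate — (fraction of pooled
per-set-normalised null NES at least as extreme) / (fraction of observed
NES at least as extreme), capped at 1 — without the desktop
implementation's final monotonicity sweep, whose exact form is
under-documented. Sets with fewer than 3 measured members are skipped with
a warning.

Leading edge: members at or before the peak for positive ES, at or after
it for negative ES. Cytoband overlap reports significant positional sets
whose name matches a user-supplied aberration label with concordant
direction (gain ↔ ES > 0, loss ↔ ES < 0).

`fisher_ora` is a generic one-sided Fisher over-representation utility
with BH correction — the open counterpart of commercial pathway tools, not
an emulation of any of them.

## miRNA integration

Target tables are merged as a union with a per-pair count of distinct
source databases; `min_sources` recovers stricter intersections (3 = all
three databases of a typical TargetScan/PicTar/MicroCosm merge). The
unexpressed-mRNA filter removes genes below the per-sample 20th percentile
in ≥ 20% of the samples of *both* groups (the same percentile convention
as the reference screen). miRNA differential expression uses ANOVA with
Scheffé post-hoc contrasts (contrast F / (k−1) against F(k−1, N−k)),
which is conservative relative to the omnibus test and collapses to it for
two groups. A significantly changed miRNA's filtered target set is kept
when its GSEA enrichment is significant *and* opposite in sign to the
miRNA's change; the leading-edge members are the selected inverse pairs.

## Clustering

Group profiles are per-gene arithmetic means on the log2 scale. Distances:
Euclidean, squared Euclidean, Manhattan, Chebyshev, and "differential" —
Euclidean between mean-centred profiles, a documented stand-in for a
proprietary pattern-similarity metric whose formula is not public; output
metadata records the metric used. Linkage is average (UPGMA) via scipy,
which resolves ties deterministically. Average linkage is not guaranteed
monotone in general; heights are checked, not enforced. Newick branch
lengths are parent merge height minus child merge height.

## Pipeline

`crestmeta run` executes simulate → DE → Shapley → reference genes → GSEA
→ miRNA → clustering from one YAML config whose thresholds default to the
analysis' standard settings (2-fold, α = 0.05, cutoff 0.6, GSEA p 0.05 /
q 0.25, 1000 permutations). Per-stage seeds are derived from the single
top-level seed, stages communicate only through serialised files, and the
manifest records a sha256 per output so reruns can be verified
byte-for-byte.

## Problem sizes in the test suite

The tests and the acceptance script run on simulations of 120–400 genes,
8–25 samples per group, 100–300 permutations and 5–50 seeds per claim —
the smallest sizes at which the planted conditions (8-fold effects,
coupling 0.9, CV bound 0.2) yield stable recovery and calibration
statistics; all thresholds asserted in tests are the analysis defaults,
not quantities fitted to the simulations.

## Known limitations

* Gene IDs are assumed harmonised across studies; there is no probe
  matching or cross-platform normalisation.
* The Shapley index is relative to the contrast's maximum; it has no
  absolute scale and should be read within, not across, contrasts.
* Phenotype permutation for GSEA is deliberately not implemented
  (gene-set permutation is the method's stated default).
* The Scheffé and Tukey implementations assume homoscedastic groups.
* `simulate_mirna` mutates its expression input (documented above); pass a
  copy if the uncoupled matrix must be preserved.
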