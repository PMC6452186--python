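# Methods

## Problem setting and model

`somascreen` targets post-zygotic single-nucleotide variants present in a
small subset of cells of one sorted population, detected by comparing a
*target* cell type against a *reference* cell type from the same
individual. At the alternate allele fractions of interest (0.5–20%) the
dominant failure mode is not missing variants but accepting artifacts:
sequencing errors, mapping artifacts and germline leakage all live in the
same low-AAF range and outnumber true variants by roughly an order of
magnitude. The pipeline therefore trades sensitivity for specificity at
every stage.

The statistical core is deliberately simple. Read counts at a site are
modelled as binomial in the true allele fraction plus a per-base error
rate. Somatic evidence in a target/reference pair is assessed by the exact
conditional test on the 2×2 read-count table: given both margins, the
number of alternate reads in the target sample is hypergeometric, and the
reported p-value is the upper tail

  P = Σ_{k ≥ alt_t} C(K, k) · C(N−K, n_t−k) / C(N, n_t)

with N the pooled read count, K the pooled alternate count and n_t the
target depth — the one-sided Fisher exact test that also underlies
VarScan2's somatic p-value. The implementation evaluates this through the
hypergeometric survival function; the test suite checks it against
exhaustive exact-integer enumeration for every table with both sample
margins up to 60 (3 572 100 tables) at 1e-12 absolute tolerance.

## Filter engine

All five technical rules are evaluated on every consensus candidate
without short-circuiting, so a failed candidate carries the complete
reason list; per-rule attrition tables are derivable from any report.
Boundary semantics follow the screening design: the target-AAF rule is
inclusive (exactly 0.5% passes), the reference-AAF rule is exclusive
(exactly 0.5% fails), and coverage is required in both samples. AAFs are
computed from the VarScan2 read counts (alt/(alt+ref)); the MuTect2
evidence is retained alongside but its model-based allele fraction is not
used for thresholding. "Detected on both strands" is implemented as at
least one alternate read per strand (the minimum defensible reading; the
per-strand minimum is configurable). MuTect2 filter names are matched
case- and separator-insensitively, and the overrule set defaults to the
two nearby-event filters (`clustered_events`,
`homologous_mapping_event`), which remove genuine clustered mutations.

The recurrence rule counts candidate-level observations per (site, cell
type) across the whole cohort *after* the caller intersection and
*before* the other technical rules, so recurrence counts are not
distorted by which other rule an artifact happens to fail first. A
(patient, target-cell) sample contributes at most one observation per
site.

Default thresholds (coverage 300×, AAF 0.5%, recurrence 2/1) are the
screening-design values; designs with more samples or finer cell subsets
scale them purely through `FilterThresholds`, never through a second
hard-coded profile.

## Prioritization

The population-rarity rule is enforced against every configured database
(a variant common in any one database is deprioritized); ≤ 1% passes,
inclusive. The GDI rule is strict (< 13.84, the published all-disease
cutoff applied to the raw score). Splice classification follows the
annotation table verbatim; no distance-to-junction recomputation is
attempted. A missing annotation is an error, never a silent pass. The
matched germline comparison set is produced by running germline variants
through this same operation, so the somatic/germline contrast is not
confounded by the filters.

## Replication statistics

Confirmation requires the one-sided Fisher p-value below a threshold and
AAF_target > AAF_reference. The Bonferroni denominator defaults to the
number of variants submitted to replication, but the threshold is also
directly settable; the packaged 36-variant table is reproduced with its
printed threshold 5.88 × 10⁻⁴, because that printed value does not equal
0.05 divided by the 66 variants actually submitted and guessing the
intended family size would be worse than honoring the printed rule.

The clonal expansion rate per variant is (AAF_t2 − AAF_t1)/Δt in
percentage points per year; the summary is the median (robust over the
typical handful of longitudinal variants), with the mean reported
alongside and a Wilcoxon signed-rank test against zero. The published
single-number summary for this quantity is internally inconsistent with
its own printed range, so no particular value is asserted; the estimator
is exposed, not calibrated. Screening-vs-replication agreement is the
squared Spearman rank correlation (AAFs are far from normal), with the
Pearson r² returned for reference.

In the packaged variant table the rows replicated in a later blood sample
are exactly the twelve marked rows from three patients, encoded as
`timepoint = later` with Δt = 1.0 year (the study's average interval);
the remaining 24 rows are same-timepoint replications.

## Characterization

Test selection follows the study's conventions: Fisher exact for
categorical contrasts; for continuous variables a Shapiro–Wilk gate at
α = 0.05 on both groups, then Kruskal–Wallis (any non-normal group, the
usual case) or Welch's t (both normal). Identical groups return p = 1
directly, since a rank test on two identical samples carries no evidence.
The substitution spectrum is pyrimidine-referenced: purine-reference
substitutions are complemented on both alleles, an involution-respecting
folding. CpG fractions use only variants with known dinucleotide context;
the packaged table does not record context, so its CpG fraction is
undefined rather than imputed. The synonymous/non-synonymous
co-occurrence table is built over all cohort patients, including
zero-variant patients.

## ddPCR quantification

Droplet counts are converted to mean copies per droplet by
λ = −ln(1 − n₊/n); saturated wells are rejected as unquantifiable rather
than clamped. The default allele-fraction convention is **ALT/REF**,
because it reproduces every printed value of the packaged well table
(11.3/331 = 3.41%, 8.5/129 = 6.59%, 12.6/1000 = 1.26%), whereas
ALT/(ALT+REF) does not; the ratio-to-total convention is available and
agrees to first order as ALT/REF → 0. Reports flag which convention was
used. Allele fractions below the 0.1% limit of detection are flagged
`below_lod` instead of being zeroed; the LoD is configurable. The
heterozygous cell-fraction conversion is 2 × AF, with a warning (not an
error) above AF = 0.5. Fractional channel values from merged replicate
wells are taken as given; the merging rule of the exporting instrument is
not modelled.

## Synthetic cohorts

The generator emulates the screening design: each patient's two cell
types act in turn as target and reference, and every injected site is
written in the same dialects the readers parse (text VCF, VarScan2
`somatic` table, annotation table), so the end-to-end path through the
actual parsers is exercised. Defaults: 10 patients, mean depth 342×
(sd 40, matching the design's median on-target depth), 8 true somatic
variants per patient with AAF log-uniform on [0.5%, 20%] and an 80/20
split between the two cell types, per-base error rate 10⁻³, and artifact
classes sized so artifacts outnumber true variants roughly 10:1
(15 strand-biased, 12 low-coverage, 8 germline leaks, 50 caller-discordant
per patient, plus 6 recurrent sites shared by 3 samples each). Artifact
classes and their generative parameters are the package's own taxonomy —
each class is constructed to violate exactly one filter rule so that
reason-code tallies are interpretable. True sites are guaranteed at least
one alternate read (a site with zero supporting reads would never be
emitted by a caller, so it is not a meaningful false negative).

Gene assignment uses a heavy-tailed (Pareto) per-gene mutability with GDI
increasing in mutability, scaled so 3.25% of genes exceed the 13.84
cutoff; variants therefore concentrate in high-GDI genes well beyond
3.25%, reproducing the qualitative behaviour that motivates the GDI rule.

What the generator does **not** model: read-level effects (mapping,
duplicates, base-quality structure), caller-specific miscalls beyond the
discordant class, indels/MNVs, contamination gradients, and batch
effects. Passing the synthetic regression therefore demonstrates the
engine applies its rules correctly under the intended statistical regime,
not that real-data sensitivity/specificity will match the regression
numbers.

All randomness flows from one seed through deterministic per-patient
substreams; identical configurations produce byte-identical files.

## Numerical and interface choices

- Coordinates are 1-based fully closed (VCF convention); BED segmental-
  duplication input is converted at read time. Chromosome names compare
  equal modulo an optional `chr` prefix.
- AAFs are fractions internally; reports print percent to 2 decimals.
- Multi-allelic VCF records decompose into one candidate per alternate
  allele, conserving summed alternate depth; indel/MNV rows are parsed
  and flagged `non_snv` rather than dropped, keeping filtering counts
  transparent.
- The exact test returns 1 when no alternate evidence exists; empty
  margins are errors. The Wilcoxon test on an all-zero rate vector
  returns p = 1 (the statistic is undefined there).
- Test problem sizes (cohort of 10 patients × ~100 sites each, exhaustive
  Fisher sweep to margin 60, 1000-candidate filter equivalence) were
  chosen so the whole suite completes in well under a minute while still
  sweeping every table the exact-arithmetic oracle can enumerate quickly.

## Known limitations

- The pipeline consumes caller outputs; it cannot compensate for callers
  run with different settings than the documented ones (VarScan2 with
  `--min-var-freq 0`, MuTect2 with a reference-cell panel of normals).
- The recurrence filter's placement before the other technical rules is a
  documented choice; cohorts with many early-failing artifacts would show
  slightly different recurrence counts under the alternative ordering,
  which is config-selectable.
- The clonal expansion estimator assumes linear AAF change between two
  timepoints; with more than two timepoints per variant a regression
  formulation would be preferable.
- Whether population rarity must hold in all databases simultaneously or
  in Kaviar alone is a design choice (default: all configured databases);
  the stricter reading can only shrink the prioritized set.
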