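# somascreen

Detection, filtering, prioritization and confirmation of **low
allele-fraction somatic single-nucleotide variants (SNVs)** in sorted
immune-cell populations.

Somatic variants in non-cancer tissue — for example in the peripheral-blood
T and B cells of autoimmune-disease patients — occur at alternate allele
fractions (AAF) as low as 0.5–1%, a regime where sequencing artifacts
vastly outnumber true variants and single variant callers have unacceptably
low positive predictive value. `somascreen` implements a consensus pipeline
for this regime, aimed at researchers analysing paired targeted-sequencing
data from sorted cell populations of the same individual (a *target* cell
type called against a *reference* cell type, the tumor/normal analogue):

1. **Consensus calling** — candidate SNVs must be reported at the same site
   by both MuTect2 (VCF) and VarScan2 (`somatic` table); the caller outputs
   are consumed, not re-implemented.
2. **Technical filtering** — coverage ≥ 300× in target and reference; AAF
   ≥ 0.5% in the target and < 0.5% in the reference; observed at most twice
   in the same cell type and at most once in the other cell type across the
   cohort; alternate allele detected on both strands; PASS under MuTect2's
   built-in filters (the two nearby-event filters, *clustered events* and
   *homologous mapping event*, may be overruled). Every failed candidate
   carries the complete list of violated rules.
3. **Prioritization** — exonic or splice-site SNVs, rare (≤ 1%) in the
   population databases (1000 Genomes, ESP6500, cg69, ExAC, Kaviar), outside
   segmental duplications, and in genes with gene damage index GDI < 13.84.
4. **Replication** — confirmation from deep amplicon read counts by a
   one-sided Fisher exact test on the 2×2 table
   `[[alt_target, ref_target], [alt_reference, ref_reference]]` under a
   Bonferroni-corrected threshold (P < 5.88 × 10⁻⁴ in the packaged study),
   combined with the direction of effect (AAF_target > AAF_reference);
   clonal expansion rate Δ AAF/Δ t for longitudinal samples; Spearman ρ²
   for screening-vs-replication AAF agreement.
5. **Characterization** — per-patient/cell-type tallies, somatic versus
   matched-germline contrasts (Kaviar novelty, COSMIC, CADD vs MSC, GERP++)
   with Fisher exact / Kruskal–Wallis tests, and the strand-folded
   substitution spectrum.
6. **ddPCR quantification** — Poisson occupancy correction
   λ = −ln(1 − n₊/n) for droplet counts, allele fractions under the
   ALT/REF ratio convention, heterozygous cell-fraction conversion
   (2 × AF), and standard-curve fitting.
7. **Synthetic cohorts** — a seeded generator emits truth-labelled
   MuTect2/VarScan2/annotation files with configurable artifact classes
   (strand-biased, recurrent, low-coverage, germline leakage,
   caller-discordant) so sensitivity and specificity of the whole engine
   are measurable without any external data.

Two small tables from a published 10-patient multiple-sclerosis screening
study ship with the package: the 36 replicated somatic variants and the
ddPCR well records for two of them.

## Worked example

Simulate a small cohort, run the screening stages, and confirm the packaged
replication-phase table:

```
$ somascreen simulate --out cohort/ --seed 11 --patients 4 --true-variants 5
$ somascreen screen --input-dir cohort/ --out screen/
{"mutect2": 250, "varscan2": 370, "consensus": 210, "technical_pass": 13, "prioritized": 5}
$ somascreen replicate --fixture --out rep/
{"n": 36, "confirmed": 36, "threshold": 0.000588}
```

The screening funnel shows the two callers' 250 and 370 raw candidates
collapsing to 210 consensus sites, 13 survivors of the technical filters
and 5 prioritized variants; `screen/truth_score.json` holds the confusion
matrix against the generator's truth labels, and `rep/confirmation.tsv`
the per-variant verdicts (all 36 packaged variants confirm at
P < 5.88 × 10⁻⁴ with positive replication AAF).

The same operations are available as a library:

```python
>>> from somascreen import fisher_exact_one_sided, allele_fraction, cell_fraction
>>> fisher_exact_one_sided(200, 9800, 1, 9999)   # amplicon counts, one-sided
2.3235915781943115e-59
>>> 100 * allele_fraction(8.5, 129)              # ddPCR ALT/REF, percent
6.589...
>>> 100 * cell_fraction(8.5 / 129).value         # heterozygous: 2 x AF
13.17...                                          # ~13.2% of cells affected
```

## Layout

```
src/somascreen/
  callsets.py      caller/annotation parsing, unified data model, reports
  filters.py       consensus intersection + technical filter engine
  prioritize.py    biological prioritization rules
  replication.py   Fisher confirmation, expansion rate, AAF agreement
  characterize.py  cohort summaries, somatic-vs-germline contrasts, spectrum
  ddpcr.py         droplet digital PCR quantification
  simulate.py      truth-labelled synthetic cohort generator
  cli.py           subcommands: simulate / screen / replicate / characterize / ddpcr
  data/            packaged variant and ddPCR well tables
docs/methods.md    model, assumptions, parameter choices, limitations
```
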