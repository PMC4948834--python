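# metasputum

Downstream analysis pipeline for sputum microbiome sequencing of a small
two-group COPD cohort (moderate, GOLD 2, vs severe, GOLD 3), covering both
16S rRNA V4 amplicon data and shotgun metatranscriptome data. The package
implements the full post-alignment workflow — barcode demultiplexing and
quality filtering, taxonomy-table aggregation, negative-control
contamination correction, Shannon diversity and rarefaction, exact
rank-sum group comparison, and a unique-read / coefficient-of-variation
consensus ranking of differential genera — together with a seeded
synthetic-cohort generator so every stage is testable without the
deposited raw sequence data.

## Who this is for

Microbiome researchers analysing small barcoded amplicon or
metatranscriptome cohorts who need the classic "reads → taxon tables →
corrected relative abundances → diversity and group differences"
pipeline, with every filtering rule explicit, deterministic and unit
tested.

## The methods in brief

- **Quality control.** Reads are demultiplexed by their 5′ barcode
  (minimal Hamming distance, ≤ 2 mismatches, unique minimum; ties go to
  *unassigned*), then filtered: mean Phred quality ≥ 20, length ≥ 70 bp,
  no ambiguous bases. Phred scores relate to base-calling error by
  Q = −10·log₁₀ P, so Q20 ⇔ P = 0.01.
- **Taxonomic profiling.** Read→reference assignments are thresholded on
  percent similarity (≥ 90 % for 16S-style, ≥ 95 % for metatranscriptome
  alignments), reduced to one best hit per read, and tallied at any of
  the seven ranks kingdom…species; OTU tables drop OTUs with fewer than
  10 reads; metatranscriptome reads are partitioned into
  human / bacteria / archaea / virus / fungi / others fractions.
- **Contamination correction.** Each taxon's patient relative abundance
  p is corrected against its relative abundance c in a no-template
  negative control: corrected = p·(1 − c). A taxon at 20 % in a patient
  and 2 % in the control becomes 20 × (1 − 0.02) = **19.6 %**. Rows are
  not renormalized by default.
- **Diversity.** Shannon index H = −Σ pᵢ log pᵢ (natural log by
  default), raw and on corrected abundances; per-phylum rarefaction
  curves by subsampling without replacement, with the exact
  hypergeometric expectation Σ_g [1 − C(N−n_g, d)/C(N, d)] available in
  closed form.
- **Group comparison.** Mean ± SD (n−1) summaries per group; exact
  two-sided Wilcoxon rank-sum tests by complete enumeration of the
  permutation distribution (midranks for ties) for the small group
  sizes used here; genera ranked by the absolute difference of
  group-mean relative abundances in percentage points.
- **Unique-read consensus.** "Unique reads" map to exactly one
  reference at or above the similarity threshold; genera must be
  detected in every sample of a group; within each group the
  coefficient of variation CV = σ/μ of per-sample unique-read counts is
  computed and only the lowest CV quartile is kept before ranking
  between-group differences.

## Worked example

```python
import metasputum as ms

design = ms.make_design(n_taxa=20, n_contaminants=2, effect_size=4.0,
                        seed=7, reads_per_sample=5000)
bundle = ms.generate_cohort(design, "demo_cohort", corruption=0.15)

retained, summary = ms.run_qc(bundle.multiplexed_fastq,
                              ms.read_barcode_map(bundle.barcode_path))
assignments = {
    s: ms.best_hit_per_read(ms.filter_by_similarity(ms.read_assignments(p), 90.0))
    for s, p in bundle.assignment_paths.items()
}
groups = bundle.groups
patients = {s: df for s, df in assignments.items() if not s.startswith("control")}
rel = ms.relative_abundance(ms.aggregate_by_rank(patients, "genus", groups=groups))
print(ms.percent_difference_ranking(rel, top_n=5).to_string(index=False))
```

prints (design seed 7 plants fold-4 effects on *Actinomyces* and
*Porphyromonas*):

```
 rank          genus  mean_moderate  mean_severe  difference_pp
    1    Actinomyces       0.138547     0.380388     -24.184096
    2    Haemophilus       0.098018     0.038557       5.946098
    3  Porphyromonas       0.062826     0.016157       4.666853
    4 Staphylococcus       0.069121     0.030981       3.813957
    5    Veillonella       0.071443     0.037187       3.425545
```

Both planted genera surface in the top ranks; `difference_pp` is the
moderate-minus-severe difference of group-mean relative abundance in
percentage points, so the negative value for *Actinomyces* marks it as
severe-enriched. Feeding the per-sample Shannon indices to the exact
rank-sum test gives `p = 0.0286` for this cohort — with four samples
per group the smallest achievable two-sided p is 2/70 ≈ 0.029.

A thin CLI wraps the same functions:

```bash
metasputum simulate --n-taxa 20 --effect-size 4 --seed 7 --out demo_cohort
metasputum qc --fastq demo_cohort/run.fastq --barcodes demo_cohort/barcodes.tsv --out-dir qc_out
metasputum compare --assignments moderate_1=demo_cohort/moderate_1.assignments.tsv ... \
    --metadata demo_cohort/metadata.tsv --top 10
```

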