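# Methods

This note documents the models, conventions and numerical choices behind
the pipeline, in the order the method runs.

## Study design emulated by the synthetic generator

The analysis targets a small sputum cohort: two patient groups of four
samples each (moderate, GOLD 2, and severe, GOLD 3 COPD) plus one
no-template negative control sequenced only in the amplicon arm. The
synthetic module reproduces that design so every downstream stage can be
validated against known ground truth.

**Count model.** Per-sample taxon counts are Dirichlet-multinomial: the
group's expected proportion vector p is jittered by a Dirichlet draw
with concentration p/θ, then `reads_per_sample` reads are drawn
multinomially. The single overdispersion parameter θ (default 0.01)
controls between-sample variability; θ = 0 degenerates to a plain
multinomial, which is the regime used for binomial-oracle tests. The
DM family is the standard parametric model for microbiome count
overdispersion, and a single θ suffices for a generator whose job is to
produce realistic between-sample spread rather than to fit data.

**Group effects.** The severe group's expectation is
p·f / Σ(p·f) for a per-taxon fold-change vector f. `make_design` plants
two differential genera — one at fold f = e, one at 1/e — on the two
most abundant community taxa, enforcing a base abundance of at least 5 %
so the planted effect is observable at realistic depths. Because of the
renormalization, the recoverable abundance ratio for the up-planted
genus is e/Z with Z = Σ(p·f); parameter-recovery tests compare against
that quantity, not raw e.

**Contaminants and the negative control.** Contaminant lineages
(Halomonas, Shewanella, …, genera that typically dominate no-template
controls) are part of the community at trace abundance (their gamma
weights are scaled by 0.01) and carry the entire control expectation, so
control samples contain only contaminant-taxa assignments by
construction.

**Reads.** Reads are 150 bp (V4-amplicon-like) of uniform random
sequence — the generator makes no attempt to simulate real 16S biology,
chimeras or PCR bias — with Phred qualities drawn around a configurable
mean (default 35, clipped to [2, 41]) and an 8-bp sample barcode
prepended. Barcodes are built by seeded greedy search with pairwise
Hamming distance ≥ 5, which makes ≤ 2-mismatch demultiplexing
unambiguous by construction. A configurable corruption fraction spoils
reads by one of four modes, each exercising exactly one downstream
filter: length drawn in [30, 69] bp, 1–3 N bases, mean quality ≈ 12, or
similarity below the floor. Truth tables record each read's lineage
with a similarity drawn uniformly in [floor, 100]; the floor defaults
to 90 (16S-like) and can be set to 95 (metatranscriptome-like). An
optional multi-hit fraction adds a second supra-threshold assignment to
another taxon *present in the same sample*, exercising the unique-read
rule without violating the control-purity invariant. All outputs are
fully determined by the design seed (byte-identical on regeneration).

Because reads are random sequence and similarities are synthetic
labels, passing tests demonstrate the correctness of the filtering and
accounting logic — not the behaviour of any aligner or classifier on
real biological reads.

## Quality control

Demultiplexing assigns a read to the sample whose barcode minimizes
Hamming distance to the read's 5′ prefix, requiring distance ≤ 2 and a
unique minimum; ties and distant prefixes are routed to an unassigned
bin so the assignment is deterministic. Comparison is case-insensitive
and N never matches (including N–N). Barcodes are trimmed on
assignment, and quality is evaluated after trimming, so barcode-region
quality does not influence filtering.

The quality criterion "minimum Phred quality score of 20" is ambiguous
between a per-base minimum and an aggregate. The default is the mean
(mean Phred ≥ 20), with a per-base-min mode selectable: a per-base
minimum at Q20 would discard nearly all realistic reads, and the
classic FASTX-style filters operate on aggregate quality. Length
(≥ 70 bp) and ambiguity (any non-ACGT base) filters are unambiguous.
Paired-end merging and OTU clustering are upstream tool stages and out
of scope; the pipeline consumes merged single-end reads and treats
reference-id groupings as OTU stand-ins.

## Taxonomic profiling

Similarity thresholds are inclusive (≥ 90, ≥ 95). When a read carries
several assignments, only the best-similarity hit is counted, with ties
broken by lexicographic reference id — the accounting must be
deterministic and one read must contribute one count. Assignments
unresolved at the working rank pool into an `unclassified` column, so
column sums at any rank equal the retained assignment count per sample
(conservation). OTU filtering removes OTUs with total count < 10;
exactly 10 survives.

The kingdom partition buckets mapped reads into human / bacteria /
archaea / virus / fungi / others, "others" being anything mapped that
matches none of the named kingdoms. Fractions are computed over the
sample's mapped total — by default the row sum of the kingdom counts,
with an explicit `mapped_totals` denominator available for tables whose
mapped accounting is carried in a separate column.

## Contamination correction

corrected = p·(1 − c), applied cell-wise at genus rank (configurable)
to relative abundances, with c = 0 for taxa absent from the control.
Rows are deliberately **not** renormalized afterwards — the worked
example (20 % → 19.6 %) leaves the other taxa untouched — so corrected
row sums lie in [1 − max c, 1]; a renormalize option exists but
defaults off. The corrected table carries a flag so the correction
cannot be applied twice (applying it twice would multiply by (1 − c)²).
A count-level transform round(count·(1 − c)) is provided for
convenience only: no published count-level correction rule reproduces
the cohort's printed corrected-read integers, so counts corrected this
way feed no downstream statistic.

## Diversity

Shannon H = −Σ pᵢ log pᵢ with natural log by default and the base
configurable; the index is scale-invariant, so it can be computed on
counts directly. Corrected Shannon renormalizes the corrected
abundances internally because entropy is defined only for probability
vectors; no ordering between raw and corrected H is asserted anywhere —
the correction can move diversity either way. Group SDs use the n−1
convention throughout, which is verified against the published
mean ± SD rows.

Rarefaction subsamples reads without replacement (multivariate
hypergeometric draws), defaulting to 10 evenly spaced depths up to the
pooled phylum total and 100 replicates, seeded. The exact expectation
Σ_g [1 − C(N−n_g, d)/C(N, d)] is implemented with integer
combinatorics and doubles as the simulation's oracle in tests (e.g.
counts [5, 5] at depth 2 give 14/9 ≈ 1.556, confirmed by complete
enumeration of all 45 subsamples).

## Group comparison

The exact two-sided Wilcoxon rank-sum p-value is
P(|W − E W| ≥ |w_obs − E W|) under the uniform distribution over all
C(n₁+n₂, n₁) group assignments, with midranks for ties. The null
distribution is built by subset-sum dynamic programming over doubled
midranks (doubling makes them integers), and deviations are compared on
the integer scale n·W₂ − n₁·ΣR₂ to avoid float ties. Combined sizes
above 12 fall back to the normal approximation with a warning. For
4-vs-4 data the implementation is checked against a complete
brute-force enumeration and, on tie-free data, against scipy's exact
Mann-Whitney test.

"Percentage difference" between groups is the absolute difference of
group-mean relative abundances in percentage points — not a ratio,
which would explode for rare genera — with the signed value retained
for direction. Means are taken over per-sample proportions (each sample
weighted equally, matching per-sample relative-abundance framing); a
pooled mode weighting samples by read totals is available. Ranking ties
break lexicographically. No multiple-testing correction is applied, by
design; the comparison surface is descriptive ranking plus the exact
test.

## Unique-read consensus

A unique read has exactly one assignment at or above the similarity
threshold (sub-threshold hits do not count against uniqueness). Genera
must be detected in every sample of a group to enter that group's
records. CV = σ/μ is computed per group on raw unique-read counts (the
analysis is framed in sequence reads, not proportions; a
relative-abundance mode can be had by passing a relative table), with
the n−1 SD convention. "First quantile" is read as the first quartile:
CVs are binned 1–4 by ascending rank (bin = ⌊4·i/n⌋+1 over sorted
positions), ties sharing the lowest bin among their positions, and only
bin 1 survives. Groups with fewer than four eligible genera keep
everything, with a warning. CV filtering runs per group independently
and the default ranking pool is the union of the two retained sets
("retained in either group"), with an intersection mode available;
differences of group-mean counts are ranked by magnitude, ties
lexicographic.

## Problem sizes and defaults

Test cohorts use 20 taxa (2 contaminants), 4 samples per group, 2,000
reads per sample and 15–20 % corruption — small enough for a fast suite
while leaving every filter exercised by hundreds of reads.
Parameter-recovery checks run 100 simulated cohorts at 10,000 reads per
sample at the count-vector level (no read emission), where both planted
fold-4 genera are required in the top-10 ranking in ≥ 90 % of cohorts.
Default generator settings (fold-change 4, base abundance ≥ 5 %,
θ = 0.01) are the regime in which a genus-level difference of this size
is clearly detectable in a 4 + 4 design.

## Known limitations

- The generator emulates count structure, barcodes, qualities and
  corruption modes — not sequence biology. Nothing here validates
  alignment, OTU clustering or database quality.
- The negative-control correction is the study's arithmetic rule;
  model-based decontamination (frequency/prevalence methods) is out of
  scope.
- With four samples per group the exact rank-sum test's smallest
  two-sided p is 2/70 ≈ 0.0286; "significance" at conventional levels
  is nearly out of reach, which is precisely why the consensus ranking
  exists.
- The published per-sample Shannon values cannot be recomputed without
  the raw data (the OTU-vs-genus basis and log base are unstated), so
  diversity checks operate on group summaries of the printed values and
  on synthetic data.
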