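# Methods

## The junction model

Exons are pooled over all transcripts of a gene and merged into disjoint
half-open intervals; book-ended exons (end == next start) merge, since a
zero-length intron is not a splice site. Each gap between consecutive merged
exons is an intron and yields one junction triple:

* **EE** — the last base of the upstream merged exon and the first base of
  the downstream one;
* **IE donor** — the two adjacent bases at the exon|intron transition
  (genomic left edge of the intron);
* **IE acceptor** — the two adjacent bases at the intron|exon transition.

"Donor/acceptor" are used in the genomic sense here (left/right intron
edge); the strand-aware 5′/3′ exon-end label is carried on each junction,
and per-side intron subtotals are emitted so the two ends can be analysed
separately. All internal coordinates are 0-based half-open; GTF input
(1-based inclusive) converts on parse and TSV output is BED-like.

Genes whose spans overlap another gene's span on the **same strand** by at
least 1 bp are removed wholesale before counting (embedded or overlapping
genes make the gene-level ratio ambiguous). Opposite-strand overlaps are
kept: the stranded counting disambiguates antisense signal but cannot
disambiguate sense-strand overlap.

## Counting semantics

An alignment supports an EE junction iff it carries a splice gap (CIGAR `N`)
whose genomic extent equals the intron exactly; it supports an IE junction
iff one aligned block contiguously covers both boundary bases (a deletion
`D` does not interrupt contiguity; `N` does). Secondary, supplementary,
duplicate and QC-fail records are ignored, as are alignments under the MAPQ
floor (default 10). Strand is inferred per mate from the library protocol
(default RF, i.e. TruSeq-stranded: read 2 lies on the transcript strand);
`FR` and `unstranded` are available.

This is deliberately *not* what `bedtools multicov -split` over 2-bp
intervals computes: that command would credit an IE junction with every
spliced read touching the junction's 1-bp exon-side base, making the
intron/exon ratio insensitive to splicing. Requiring contiguous coverage of
both IE bases, and an exact gap match for EE, is the semantics under which
the ratio actually measures read-through versus splicing. One consequence,
exercised in the tests: a read spliced to an unannotated alternative site
inside the intron still counts as acceptor-side read-through if its aligned
block crosses the annotated intron|exon boundary — it is genuine unspliced
signal at that boundary.

Counting is per mate by default, mirroring per-record BED coverage tools; a
`fragment` mode counts a read pair at most once per junction for users who
prefer statistically independent units. Both modes are tested against a
brute-force oracle.

## The gene-level statistic

Per condition, replicates are summed before the ratio: E = Σ EE support,
I = Σ (donor + acceptor) support over all the gene's junctions, rho = I/E,
delta = rho_test − rho_reference. E = 0 yields NA (never ±inf) and NA
propagates into delta; no pseudocounts are added, because the reference-
coverage filter (E_ref ≥ 50, strict "lower than" cutoff, flagged not
deleted) already guarantees a safe denominator for every gene that is
interpreted. A per-replicate ratio table is emitted for dispersion checks
but plays no role in the headline statistic.

A simplified cassette-exon PSI is provided as plumbing:
psi = mean(inclusion EE support) / (mean(inclusion) + exclusion support),
with the exclusion (flank-to-flank) junction counted by exact gap match via
`count_splice_gap`. It is not an event-discovery method.

## Binding propensity and the correlation report

propensity = Σ FE over all peaks overlapping the gene span (≥ 1 bp,
strand-blind, full-interval test — not summit-in-gene) × 1000 / span length.
Gene *span* rather than merged-exon length is used for the kbp
normalisation. The score is intentionally not additive under peak
fragmentation: splitting a peak into two records that each keep the original
FE doubles the sum — callers should score one peak set consistently.
Association with splicing deregulation uses Spearman rank correlation
(robust to the heavy-tailed ratio scale), reported for signed delta and
|delta| over genes that pass the coverage filter and have defined delta;
fewer than 3 usable genes is an error, constant ranks give NA with a
warning.

## Cohort z-scores

For each feature, mean and sample sd (n−1) are computed over its
copy-number-neutral samples (|segment mean| < 0.2) and applied to all
samples. Fewer than 2 neutral samples, or a reference that is constant to
machine precision (sd ≤ 1e−12 relative), yields an NA row with a warning.
Stratification uses strict inequalities — z exactly at the 1.65 threshold is
"unchanged" — and the threshold is interpreted one-sided per tail
(UP: z > t, DOWN: z < −t); 1 − Φ(1.65) ≈ 0.0495. Negating the matrix swaps
UP and DOWN exactly.

## The simulator

The generator emulates a TruSeq-stranded (RF) 2 × 75 bp paired-end design
with three biological replicates per condition. Each gene expresses a
spliced mRNA and an unspliced pre-mRNA; the retention fraction r is the
**molar** fraction of unspliced molecules, and a fragment of length F
originates from the unspliced pool with probability
r·S_u/(r·S_u + (1−r)·S_s), where S = molecule length − F + 1 is the number
of fragment start positions — exactly what uniform shearing of a molecule
pool produces. Two geometric constraints make the boundary-count algebra
exact: terminal exons are at least as long as the maximum fragment (no
boundary is shadowed by a molecule end, so every boundary offers the same
2(L−1) straddling mate placements), and internal exons and introns exceed
the read length (no mate can straddle two boundaries). Under these
conditions E[I]/E[E] = 2r/(1−r) with both IE sides counted, inverted by
r̂ = rho/(2+rho).

Mates carry proper-pair flags and orientations consistent with the chosen
protocol; MAPQ is drawn from a mixture (default 90% 60, 5% 30, 5% 5) whose
sub-threshold mass exercises the quality filter and is excluded from the
truth tallies. Truth is recorded two ways: realized per-junction support
counts (which the pipeline's mate-mode counts must equal exactly) and
analytic expectations given the drawn fragment lengths. Outputs are
byte-deterministic per seed.

What the simulator does **not** model: sequence content, base-call or
alignment error, GC/positional coverage bias, duplicate reads, novel or
partial splice sites, multi-isoform structure beyond the binary
spliced/unspliced mixture, and expression heterogeneity between replicates
beyond sampling noise. Passing recovery tests therefore demonstrate the
correctness of the counting and estimation machinery under the stated
model, not robustness to real-library artifacts.

Peaks are planted wholly inside bound genes' spans with gamma-distributed
fold enrichments (shape 3, scale 2, +1), so planted per-gene FE sums are
exact; fold enrichments are written with 5 decimals, the precision MACS2
prints. The expression-cohort generator plants ±5 sd shifts only in
non-neutral cells so the planted effects cannot contaminate the neutral
reference.

## Standard scenarios and problem sizes

* **default** — 20 genes, retention ladder (0, 0.1, 0.25, 0.5, 0.8) × 4
  genes, ~5,000 informative (junction-supporting) mates per gene across 3
  replicates. Chosen so binomial noise puts r̂ within ±0.02 of r with
  comfortable margin (per-gene sd of r̂ ≈ 0.007 at the ladder midpoint).
* **coupled** — 200 two-intron genes, WT retention 0.1, cKO retention rising
  monotonically with binding-propensity rank up to 0.45, ~250 informative
  mates per gene over 2 replicates: the planted delta range (~0–1.4) dwarfs
  counting noise, so the Spearman correlation is detected decisively.
* **null** — coupling disabled, 100 genes at ~150 informative mates per
  gene (enough that every gene clears the E_wt ≥ 50 filter), 20 seeds for
  the null |rho| distribution.
* **oracle** — 6 genes, < 10⁴ reads, with per-read truth labels, small
  enough for the naive every-(alignment, junction) double-loop oracle.

These sizes are the package's reference experiment definitions; all are
regenerated from a seed at run time, nothing is shipped as data.

## Numerical choices and degenerate inputs

Half-open interval convention throughout; empty exon lists merge to an
empty list; single-exon genes contribute no junctions silently; unknown
contigs in alignments (or annotation contigs missing from a BAM) warn and
skip; a missing BAM index is an error rather than a silent sequential scan,
except for SAM input which is streamed in one pass; NA ratios are excluded
from correlations; Spearman ties are mid-ranked (scipy convention);
stratification of NA z-values is "unchanged". The WT/cKO roles are generic
labels assigned by `--reference-condition`/`--test-condition`, so the
pipeline is reusable for any two-condition design.

## Known limitations

The gene-level ratio conflates introns within a gene (by design: it is a
gene-level efficiency measure) and is undefined for single-exon and
unexpressed genes. Same-strand overlapping gene pairs are dropped entirely
rather than resolved. The per-gene statistic carries no significance test —
the correlation report, not per-gene inference, is the supported readout.
The simplified PSI handles a single cassette exon with annotated flanks,
not general alternative-splicing event graphs.
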