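# spliceff

Junction-based splicing-efficiency analysis for stranded RNA-seq, per-gene
SATB1 ChIP binding-propensity scoring, and cohort z-score stratification —
with a seeded synthetic-data generator so every stage can be verified against
planted ground truth.

## Who this is for

Analysts quantifying **intron retention** between two conditions (e.g.
wild-type vs *Satb1* conditional-knockout thymocytes) from coordinate-sorted
BAM files and a GENCODE-style GTF, and relating per-gene splicing
deregulation to protein–DNA binding measured as MACS2 narrowPeak fold
enrichments. A separate utility standardises tumor-cohort expression against
copy-number-neutral samples and stratifies patients into UP/DOWN groups.

## The statistics

**Splicing efficiency.** For each gene, overlapping exons pooled over all
transcripts are merged; each intron between consecutive merged exons defines
a *2-bp exon–exon junction* (last base of the upstream exon, first base of
the downstream exon) and two *2-bp intron–exon junctions* straddling the
donor- and acceptor-side boundaries. An alignment supports an EE junction
when its splice gap (CIGAR `N`) matches the intron exactly, and an IE
junction when one aligned block contiguously covers both boundary bases.
Counting honours MAPQ ≥ 10, library strandedness (RF by default) and split
alignments. Summing junction support over each gene and all replicates of a
condition gives exon coverage E and intron coverage I, and

    rho = I / E                 (higher rho = more intron read-through)
    delta = rho_cKO - rho_WT    (splicing deregulation)

Genes with summed WT EE coverage below 50 are flagged out. Under the
simulator's uniform-coverage model, a gene whose transcripts are unspliced
with molar fraction r has E[rho] = 2r/(1−r), so `estimate_retention`
recovers r̂ = rho/(2+rho).

**Binding propensity.** Each gene scores the sum of fold enrichments of all
peaks overlapping its span by ≥ 1 bp, normalised per kbp of gene length:
`propensity = Σ FE × 1000 / gene_span`. Association with splicing
deregulation is reported as Spearman rank correlation of propensity against
delta and |delta|.

**Cohort z-score.** `z = (x − mean_neutral) / sd_neutral`, mean and sample
sd taken over the samples whose copy-number segment mean is within ±0.2;
samples are stratified UP (z > 1.65), DOWN (z < −1.65) or unchanged — 1.65
is the one-sided Gaussian 0.0495 tail point.

## Worked example

```python
import tempfile
import spliceff as sf

cfg = sf.SimConfig(seed=5, n_genes=6, target_informative_per_gene=200, replicates=2)
with tempfile.TemporaryDirectory() as tmp:
    genes, _ = sf.make_toy_annotation(cfg, tmp + "/peek.gtf")
    wt = {g.gene_id: 0.10 for g in genes}       # 10% intron retention in WT
    ko = {g.gene_id: 0.40 for g in genes}       # 40% in the knockout
    study = sf.simulate_study(cfg, tmp, conditions={"WT": wt, "cKO": ko},
                              with_peaks=True)

    ann = sf.parse_annotation(study.gtf_path)
    pairs = sf.pair_and_purify(sf.build_junctions(ann), ann)
    jc = sf.count_samples(study.samples, pairs)
    table = sf.splice_table(jc)   # reference WT, test cKO, E_wt >= 50 filter
    print(table[["E_wt", "I_wt", "ratio_wt", "ratio_ko", "delta",
                 "pass_filter"]].round(3))
```

prints

```
          E_wt  I_wt  ratio_wt  ratio_ko  delta  pass_filter
gene_id
SIMG0001   165    34     0.206     1.136  0.930         True
SIMG0002   158    34     0.215     1.038  0.822         True
SIMG0003   153    32     0.209     1.129  0.920         True
SIMG0004   148    36     0.243     1.639  1.396         True
SIMG0005   161    42     0.261     1.136  0.875         True
SIMG0006   160    31     0.194     1.630  1.436         True
```

With WT retention 0.10 the expected ratio is 2·0.1/0.9 ≈ 0.222 and with cKO
retention 0.40 it is ≈ 1.333; the observed ratios scatter around those
values (a few hundred informative reads per gene here), every gene clears
the E_wt ≥ 50 filter, and delta > 0 reflects the planted loss of splicing
efficiency.

The same analysis is available from the shell:

```
spliceff simulate --scenario oracle --seed 2 --outdir sim
spliceff run --gtf sim/annotation.gtf --samples sim/samples.tsv \
    --peaks sim/peaks.narrowPeak --outdir results --test-condition WT
```

which writes `junctions.tsv`, `junction_counts.tsv`,
`splicing_efficiency.tsv`, `per_replicate_ratios.tsv`,
`binding_propensity.tsv`, `binding_correlation.tsv` and
`run_manifest.json` (config hash + input checksums). Subcommands
`junctions`, `count`, `efficiency`, `propensity`, `cohort-z` and `simulate`
expose the individual stages.

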