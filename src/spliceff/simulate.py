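"""Seeded synthetic data for the whole pipeline, with ground truth.

Generates GENCODE-style toy annotations, stranded paired-end alignments with
known per-gene intron retention, MACS2-style narrowPeak files with known fold
enrichments, and tumor expression cohorts with a designated copy-number-
neutral subset — everything the analysis consumes — plus truth tables so
recovery can be tested exactly.

Read model
----------
Each gene expresses two molecule species: the spliced mRNA (all introns
removed) and the unspliced pre-mRNA (contiguous gene span).  The retention
fraction ``r`` is the *molar* fraction of unspliced molecules.  Sequencing
shears molecules uniformly, so a fragment of length F originates from the
unspliced species with probability

    r * S_u(F) / (r * S_u(F) + (1 - r) * S_s(F)),     S = molecule_len - F + 1

i.e. per-base fragment-start density proportional to molar abundance.  Under
this model every exon-exon and intron-exon boundary offers the same number of
read placements that straddle it (terminal exons are kept longer than the
maximum fragment so no boundary is shadowed by a molecule end), giving the
expected gene-level intron/exon junction ratio rho = 2r/(1-r) when both IE
sides are counted — the relation inverted by
:func:`spliceff.efficiency.estimate_retention`.

Emulates a TruSeq-stranded (RF) 2x75 bp paired-end protocol with three
biological replicates per condition by default.  Alignment-level only: no
sequences, error models or aligner artifacts; a configurable MAPQ mixture
(including a sub-threshold mass) exercises the mapping-quality filter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.stats import rankdata

from .cohort import ExpressionCohort

DEFAULT_RETENTION_LADDER = (0.0, 0.1, 0.25, 0.5, 0.8)

__all__ = [
    "SimConfig",
    "GeneSpec",
    "SimTruth",
    "SimStudy",
    "make_toy_annotation",
    "simulate_reads",
    "simulate_peaks",
    "simulate_expression_cohort",
    "simulate_study",
    "default_scenario",
    "coupled_scenario",
    "null_scenario",
    "oracle_scenario",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulator.

    Lengths are bp.  ``target_informative_per_gene`` is the expected number
    of junction-supporting mates per gene per condition (summed over
    replicates); the fragment count is derived from it.  Terminal exons are
    drawn at least as long as ``fragment_max`` so that every junction is
    fully coverable (see module docstring).
    """

    seed: int = 0
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 6)
    internal_exon_length: tuple[int, int] = (130, 240)
    terminal_exon_length: tuple[int, int] = (260, 400)
    intron_length: tuple[int, int] = (150, 400)
    intergenic_gap: tuple[int, int] = (800, 2000)
    contig: str = "chr1"
    read_length: int = 75
    fragment_mean: float = 180.0
    fragment_sd: float = 30.0
    fragment_max: int = 260
    target_informative_per_gene: int = 5000
    replicates: int = 3
    library_type: str = "RF"
    mapq_values: tuple[int, ...] = (60, 30, 5)
    mapq_weights: tuple[float, ...] = (0.90, 0.05, 0.05)
    min_mapq_truth: int = 10
    record_read_labels: bool = False
    plant_overlap: bool = False
    # peak model
    bound_fraction: float = 0.5
    peaks_per_gene: tuple[int, int] = (1, 3)
    peak_length: tuple[int, int] = (200, 600)
    fe_gamma_shape: float = 3.0
    fe_gamma_scale: float = 2.0

    def __post_init__(self) -> None:
        if self.terminal_exon_length[0] < self.fragment_max:
            raise ValueError(
                "terminal exons must be at least fragment_max long so no "
                "junction is shadowed by a molecule end"
            )
        if self.internal_exon_length[0] <= self.read_length:
            raise ValueError("internal exons must exceed the read length")
        if self.intron_length[0] <= self.read_length:
            raise ValueError("introns must exceed the read length")
        if self.fragment_max < self.read_length:
            raise ValueError("fragment_max must be >= read_length")
        if self.library_type not in ("RF", "FR"):
            raise ValueError("library_type must be 'RF' or 'FR'")
        if len(self.mapq_values) != len(self.mapq_weights):
            raise ValueError("mapq_values and mapq_weights lengths differ")


@dataclass(frozen=True)
class GeneSpec:
    """Generator-side truth about one gene's structure."""

    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # genomic, 0-based half-open, disjoint
    n_transcripts: int = 1

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def unspliced_length(self) -> int:
        return self.end - self.start


@dataclass
class SimTruth:
    """Ground truth for one simulated alignment file.

    ``realized`` tallies, per junction key (gene_id, intron_index, side with
    side in {ee, donor, acceptor}), the mates that genuinely support the
    junction and pass the simulator's MAPQ threshold; the pipeline's
    mate-mode counts must equal it exactly.  ``expected`` holds the analytic
    per-junction expectations given the drawn fragment lengths.
    """

    retention: dict[str, float]
    n_fragments: dict[str, int]
    realized: dict[tuple[str, int, str], int]
    expected: dict[tuple[str, int, str], float]
    read_labels: list[tuple[str, int, tuple[str, int, str]]] = field(
        default_factory=list
    )


@dataclass
class SimStudy:
    """Paths and truth for a complete simulated study."""

    outdir: str
    gtf_path: str
    contigs: dict[str, int]
    genes: list[GeneSpec]
    sample_sheet_path: str
    samples: pd.DataFrame
    truths: dict[str, SimTruth]
    retention: dict[str, dict[str, float]]  # condition -> gene -> r
    peaks_path: str | None = None
    peak_truth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# annotation


def make_toy_annotation(
    cfg: SimConfig, gtf_path: str
) -> tuple[list[GeneSpec], dict[str, int]]:
    """Write a deterministic toy GTF; returns gene specs and contig sizes.

    Genes are laid out left to right on one contig, separated by intergenic
    gaps, with alternating strands; a minority of genes carry a second
    transcript listing the same exons, to exercise per-gene exon pooling.
    With ``plant_overlap`` two extra same-strand overlapping genes are
    appended (for purification tests).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    genes: list[GeneSpec] = []
    pos = 1000
    n_total = cfg.n_genes + (2 if cfg.plant_overlap else 0)
    for i in range(cfg.n_genes):
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exons = []
        cur = pos
        for k in range(n_ex):
            lo, hi = (
                cfg.terminal_exon_length
                if k in (0, n_ex - 1)
                else cfg.internal_exon_length
            )
            elen = int(rng.integers(lo, hi + 1))
            exons.append((cur, cur + elen))
            cur += elen
            if k < n_ex - 1:
                cur += int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        genes.append(GeneSpec(
            gene_id=f"SIMG{i + 1:04d}",
            contig=cfg.contig,
            strand="+" if rng.random() < 0.5 else "-",
            exons=tuple(exons),
            n_transcripts=2 if rng.random() < 0.25 else 1,
        ))
        pos = cur + int(rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1))
    if cfg.plant_overlap:
        # two 2-exon genes on the same strand whose spans overlap
        a = pos
        genes.append(GeneSpec(
            gene_id=f"SIMG{cfg.n_genes + 1:04d}", contig=cfg.contig, strand="+",
            exons=((a, a + 300), (a + 500, a + 800)),
        ))
        genes.append(GeneSpec(
            gene_id=f"SIMG{cfg.n_genes + 2:04d}", contig=cfg.contig, strand="+",
            exons=((a + 600, a + 900), (a + 1100, a + 1400)),
        ))
        pos = a + 1400 + cfg.intergenic_gap[0]
    contigs = {cfg.contig: pos + 1000}

    with open(gtf_path, "wt") as fh:
        fh.write("##format: gtf\n")
        for g in genes:
            attrs_gene = f'gene_id "{g.gene_id}";'
            fh.write("\t".join([
                g.contig, "sim", "gene", str(g.start + 1), str(g.end),
                ".", g.strand, ".", attrs_gene,
            ]) + "\n")
            for t in range(g.n_transcripts):
                tid = f"{g.gene_id}.T{t + 1}"
                attrs_tx = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                fh.write("\t".join([
                    g.contig, "sim", "transcript", str(g.start + 1), str(g.end),
                    ".", g.strand, ".", attrs_tx,
                ]) + "\n")
                for (a, b) in g.exons:
                    fh.write("\t".join([
                        g.contig, "sim", "exon", str(a + 1), str(b),
                        ".", g.strand, ".", attrs_tx,
                    ]) + "\n")
    return genes, contigs


# ---------------------------------------------------------------------------
# reads


def _spliced_offsets(gene: GeneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative exon boundaries of the spliced molecule and exon starts."""
    lens = np.array([b - a for a, b in gene.exons])
    cum = np.cumsum(lens)
    starts = np.array([a for a, _ in gene.exons])
    return cum, starts


def _map_spliced(gene: GeneSpec, m0: int, length: int,
                 cum: np.ndarray, starts: np.ndarray) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval to genomic blocks."""
    blocks = []
    lo = m0
    hi = m0 + length
    prev_cum = 0
    for k, c in enumerate(cum):
        if hi <= prev_cum:
            break
        if lo < c:
            a = starts[k] + max(lo, prev_cum) - prev_cum
            b = starts[k] + min(hi, c) - prev_cum
            blocks.append((int(a), int(b)))
        prev_cum = c
    return blocks


def _cigar_from_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    cig = []
    for i, (a, b) in enumerate(blocks):
        if i:
            cig.append((3, a - blocks[i - 1][1]))  # N
        cig.append((0, b - a))  # M
    return cig


def _informative_rate(gene: GeneSpec, cfg: SimConfig, r: float) -> float:
    """Expected junction-supporting mates per fragment (at the mean F)."""
    F = min(max(int(round(cfg.fragment_mean)), cfg.read_length), cfg.fragment_max)
    L = cfg.read_length
    n_b = len(gene.introns)
    if n_b == 0:
        return 0.0
    S_s = gene.spliced_length - F + 1
    S_u = gene.unspliced_length - F + 1
    w_u = r * S_u
    w_s = (1.0 - r) * S_s
    p_u = w_u / (w_u + w_s)
    rate_s = 2.0 * (L - 1) * n_b / S_s
    rate_u = 2.0 * (L - 1) * (2 * n_b) / S_u
    return (1.0 - p_u) * rate_s + p_u * rate_u


def simulate_reads(
    cfg: SimConfig,
    genes: Sequence[GeneSpec],
    retention: Mapping[str, float],
    contigs: Mapping[str, int],
    bam_path: str,
    seed_key: int,
    n_fragments: Mapping[str, int] | None = None,
) -> SimTruth:
    """Simulate one sample's alignments as a coordinate-sorted, indexed BAM.

    ``retention`` maps gene_id -> molar intron-retention fraction r.  Per
    gene, the fragment count is derived from
    ``cfg.target_informative_per_gene / cfg.replicates`` unless given
    explicitly.  Returns the sample's :class:`SimTruth`; mates with
    simulated MAPQ below ``cfg.min_mapq_truth`` are excluded from the
    realized (and expected) counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 211, seed_key]))
    L = cfg.read_length
    mapq_values = np.array(cfg.mapq_values)
    mapq_weights = np.array(cfg.mapq_weights, dtype=float)
    mapq_weights /= mapq_weights.sum()
    q_pass = float(mapq_weights[mapq_values >= cfg.min_mapq_truth].sum())

    truth = SimTruth(retention=dict(retention), n_fragments={},
                     realized={}, expected={})
    records: list[pysam.AlignedSegment] = []
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": int(ln)} for name, ln in contigs.items()],
    })
    tid_of = {name: i for i, name in enumerate(contigs)}

    for gene in genes:
        r = float(retention[gene.gene_id])
        n_introns = len(gene.introns)
        for idx in range(n_introns):
            for side in ("ee", "donor", "acceptor"):
                truth.realized.setdefault((gene.gene_id, idx, side), 0)
                truth.expected.setdefault((gene.gene_id, idx, side), 0.0)
        if n_fragments is not None:
            n_frag = int(n_fragments[gene.gene_id])
        else:
            rate = _informative_rate(gene, cfg, r)
            per_rep = cfg.target_informative_per_gene / cfg.replicates
            n_frag = int(np.ceil(per_rep / rate)) if rate > 0 else 0
        truth.n_fragments[gene.gene_id] = n_frag
        if n_frag == 0 or n_introns == 0:
            continue

        cum, starts = _spliced_offsets(gene)
        Ls, Lu = gene.spliced_length, gene.unspliced_length
        # donor_k is the offset of intron k's first base in pre-mRNA
        # coordinates; acceptor_k the offset of the first exon base after it
        donors_u = np.array([a - gene.start for a, _ in gene.introns])
        acceptors_u = np.array([b - gene.start for _, b in gene.introns])

        F = np.clip(
            np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, n_frag)),
            L, cfg.fragment_max,
        ).astype(int)
        S_s = Ls - F + 1
        S_u = Lu - F + 1
        w_u = r * S_u
        p_u = w_u / (w_u + (1.0 - r) * S_s)
        unspliced = rng.random(n_frag) < p_u
        S = np.where(unspliced, S_u, S_s)
        start_off = (rng.random(n_frag) * S).astype(int)
        mapq = rng.choice(mapq_values, size=(n_frag, 2), p=mapq_weights)

        # analytic expectations given the drawn fragment lengths: each mate
        # straddles a given boundary from L-1 of the S start positions
        exp_per_ee = float(np.sum((1.0 - p_u) * 2.0 * (L - 1) / S_s)) * q_pass
        exp_per_ie = float(np.sum(p_u * 2.0 * (L - 1) / S_u)) * q_pass
        for idx in range(n_introns):
            truth.expected[(gene.gene_id, idx, "ee")] = exp_per_ee
            truth.expected[(gene.gene_id, idx, "donor")] = exp_per_ie
            truth.expected[(gene.gene_id, idx, "acceptor")] = exp_per_ie

        tid = tid_of[gene.contig]
        for i in range(n_frag):
            f, s0, is_u = int(F[i]), int(start_off[i]), bool(unspliced[i])
            qname = f"{gene.gene_id}.f{i}"
            mate_offsets = (s0, s0 + f - L)  # left mate, right mate
            # read1/read2 roles: under RF, read 2 lies on the transcript
            # strand; the genomic-left mate of an innie pair is the '+' mate
            if cfg.library_type == "RF":
                left_is_read2 = gene.strand == "+"
            else:  # FR
                left_is_read2 = gene.strand == "-"
            mate_records = []
            for m, m0 in enumerate(mate_offsets):
                if is_u:
                    blocks = [(gene.start + m0, gene.start + m0 + L)]
                else:
                    blocks = _map_spliced(gene, m0, L, cum, starts)
                a = pysam.AlignedSegment(header)
                a.query_name = qname
                a.reference_id = tid
                a.reference_start = blocks[0][0]
                a.cigartuples = _cigar_from_blocks(blocks)
                a.mapping_quality = int(mapq[i, m])
                is_left = m == 0
                is_read2 = is_left == left_is_read2
                a.flag = (
                    0x1 | 0x2
                    | (0x10 if not is_left else 0)  # right mate is reverse
                    | (0x20 if is_left else 0)      # its mate is reverse
                    | (0x80 if is_read2 else 0x40)
                )
                mate_records.append(a)
                # truth: which boundary (if any) does this mate straddle?
                if int(mapq[i, m]) < cfg.min_mapq_truth:
                    continue
                lo, hi = m0, m0 + L - 1  # inclusive molecule offsets
                if is_u:
                    cands = (
                        ("donor", donors_u), ("acceptor", acceptors_u),
                    )
                else:
                    cands = (("ee", cum[:-1]),)
                for side, offs in cands:
                    k = int(np.searchsorted(offs, lo + 1))
                    if k < len(offs) and offs[k] <= hi:
                        key = (gene.gene_id, int(k), side)
                        truth.realized[key] += 1
                        if cfg.record_read_labels:
                            truth.read_labels.append((qname, m + 1, key))
            r1, r2 = mate_records
            r1.next_reference_id = tid
            r2.next_reference_id = tid
            r1.next_reference_start = r2.reference_start
            r2.next_reference_start = r1.reference_start
            r1.template_length = f
            r2.template_length = -f
            records.extend(mate_records)

    records.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name,
                                a.flag))
    with pysam.AlignmentFile(bam_path, "wb", header=header) as out:
        for a in records:
            out.write(a)
    pysam.index(bam_path)
    return truth


def simulate_cassette_reads(
    seed: int,
    bam_path: str,
    inclusion_rate: float = 0.7,
    n_fragments: int = 2000,
    cfg: SimConfig | None = None,
) -> dict:
    """Alignments over one 3-exon gene with a cassette middle exon.

    Fragments derive from the inclusion isoform (all three exons) with molar
    probability ``inclusion_rate``, else from the skipping isoform (exons 1
    and 3 only); origin is length-weighted as in :func:`simulate_reads`, so
    the expected junction-support PSI equals ``inclusion_rate``.  Returns the
    gene geometry and realized truth counts for the two inclusion junctions
    and the exclusion junction.
    """
    if cfg is None:
        cfg = SimConfig(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 523]))
    L = cfg.read_length
    start = 1000
    exons = ((start, start + 300), (start + 500, start + 650),
             (start + 850, start + 1150))
    gene = GeneSpec(gene_id="CASSG0001", contig=cfg.contig, strand="+",
                    exons=exons)
    isoforms = {
        "inclusion": GeneSpec("CASSG0001", cfg.contig, "+", exons),
        "exclusion": GeneSpec("CASSG0001", cfg.contig, "+", (exons[0], exons[2])),
    }
    contigs = {cfg.contig: exons[-1][1] + 1000}
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": cfg.contig, "LN": contigs[cfg.contig]}],
    })
    # gaps that identify each junction
    inc1 = (exons[0][1], exons[1][0])
    inc2 = (exons[1][1], exons[2][0])
    excl = (exons[0][1], exons[2][0])
    truth = {"inclusion": [0, 0], "exclusion": 0,
             "gene": gene, "gaps": {"inclusion": (inc1, inc2), "exclusion": excl}}

    F = np.clip(np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, n_fragments)),
                L, cfg.fragment_max).astype(int)
    li = isoforms["inclusion"].spliced_length
    le = isoforms["exclusion"].spliced_length
    S_i, S_e = li - F + 1, le - F + 1
    w_i = inclusion_rate * S_i
    p_i = w_i / (w_i + (1.0 - inclusion_rate) * S_e)
    use_inc = rng.random(n_fragments) < p_i
    S = np.where(use_inc, S_i, S_e)
    start_off = (rng.random(n_fragments) * S).astype(int)

    records = []
    for i in range(n_fragments):
        iso = isoforms["inclusion" if use_inc[i] else "exclusion"]
        cum, starts = _spliced_offsets(iso)
        f, s0 = int(F[i]), int(start_off[i])
        for m, m0 in enumerate((s0, s0 + f - L)):
            blocks = _map_spliced(iso, m0, L, cum, starts)
            a = pysam.AlignedSegment(header)
            a.query_name = f"cass.f{i}"
            a.reference_id = 0
            a.reference_start = blocks[0][0]
            a.cigartuples = _cigar_from_blocks(blocks)
            a.mapping_quality = 60
            is_left = m == 0
            is_read2 = is_left  # '+' gene under RF: left mate is read 2
            a.flag = (0x1 | 0x2 | (0x10 if not is_left else 0)
                      | (0x20 if is_left else 0)
                      | (0x80 if is_read2 else 0x40))
            records.append(a)
            _, gaps = _blocks_to_gaps(blocks)
            if inc1 in gaps:
                truth["inclusion"][0] += 1
            if inc2 in gaps:
                truth["inclusion"][1] += 1
            if excl in gaps:
                truth["exclusion"] += 1
    records.sort(key=lambda a: (a.reference_start, a.query_name, a.flag))
    with pysam.AlignmentFile(bam_path, "wb", header=header) as out:
        for a in records:
            out.write(a)
    pysam.index(bam_path)
    return truth


def _blocks_to_gaps(blocks: list[tuple[int, int]]):
    gaps = {(blocks[i - 1][1], blocks[i][0]) for i in range(1, len(blocks))}
    return blocks, gaps


# ---------------------------------------------------------------------------
# peaks


def simulate_peaks(
    cfg: SimConfig,
    genes: Sequence[GeneSpec],
    peaks_path: str,
    bound_genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Write a narrowPeak file with peaks planted inside bound genes' spans.

    Returns the per-gene truth (bound flag, fe_sum, propensity).  Peaks are
    placed fully inside their gene's span and genes never overlap, so the
    truth fold-enrichment sums are exact.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 307]))
    if bound_genes is None:
        n_bound = int(round(cfg.bound_fraction * len(genes)))
        order = rng.permutation(len(genes))
        bound = {genes[i].gene_id for i in order[:n_bound]}
    else:
        bound = set(bound_genes)
    rows = []
    lines = []
    n_peak = 0
    for g in genes:
        fe_sum = 0.0
        n_here = 0
        if g.gene_id in bound:
            n_here = int(rng.integers(cfg.peaks_per_gene[0], cfg.peaks_per_gene[1] + 1))
            for _ in range(n_here):
                span = g.end - g.start
                plen = int(rng.integers(cfg.peak_length[0],
                                        min(cfg.peak_length[1], span - 1) + 1))
                start = g.start + int(rng.integers(0, span - plen + 1))
                fe = float(rng.gamma(cfg.fe_gamma_shape, cfg.fe_gamma_scale) + 1.0)
                summit = int(rng.integers(0, plen))
                n_peak += 1
                lines.append("\t".join([
                    g.contig, str(start), str(start + plen), f"peak_{n_peak}",
                    str(min(1000, int(10 * fe))), ".", f"{fe:.5f}",
                    f"{1.5 * fe:.5f}", f"{1.2 * fe:.5f}", str(summit),
                ]))
                fe_sum += fe
        rows.append({
            "gene_id": g.gene_id, "bound": g.gene_id in bound,
            "n_peaks": n_here, "fe_sum": fe_sum,
            "propensity": fe_sum * 1000.0 / (g.end - g.start),
        })
    with open(peaks_path, "wt") as fh:
        for line in lines:
            fh.write(line + "\n")
    return pd.DataFrame(rows).set_index("gene_id").sort_index()


# ---------------------------------------------------------------------------
# expression cohort


def simulate_expression_cohort(
    seed: int,
    n_features: int = 200,
    n_samples: int = 100,
    neutral_fraction: float = 0.6,
    n_up: int = 10,
    n_down: int = 10,
    effect_sd: float = 5.0,
    zero_variance_features: int = 0,
) -> tuple[ExpressionCohort, pd.DataFrame]:
    """A tumor-cohort expression matrix with planted UP/DOWN cells.

    Per feature, a ``neutral_fraction`` of samples is copy-number neutral
    (these form the z-score reference); planted shifts of ``effect_sd``
    standard deviations are applied to randomly chosen *non-neutral* cells so
    they do not contaminate the reference.  Returns the cohort plus a truth
    frame of planted labels ('UP'/'DOWN'/'unchanged') per (feature, sample).
    """
    n_neutral = int(round(neutral_fraction * n_samples))
    if n_neutral < 2:
        raise ValueError("neutral fraction must give at least 2 neutral samples")
    if n_up + n_down > n_features * (n_samples - n_neutral):
        raise ValueError("more planted effects than non-neutral cells")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 401]))
    features = [f"F{i + 1:05d}" for i in range(n_features)]
    samples = [f"T{i + 1:04d}" for i in range(n_samples)]
    mu = rng.uniform(6.0, 12.0, n_features)
    sd = rng.uniform(0.5, 1.5, n_features)
    values = rng.normal(mu[:, None], sd[:, None], (n_features, n_samples))

    seg = np.empty((n_features, n_samples))
    mask = np.zeros((n_features, n_samples), dtype=bool)
    for i in range(n_features):
        idx = rng.permutation(n_samples)
        neu = idx[:n_neutral]
        mask[i, neu] = True
        seg[i] = rng.uniform(0.3, 1.0, n_samples) * rng.choice([-1, 1], n_samples)
        seg[i, neu] = rng.uniform(-0.15, 0.15, n_neutral)

    labels = np.full((n_features, n_samples), "unchanged", dtype=object)
    non_neutral = np.argwhere(~mask)
    pick = rng.permutation(len(non_neutral))[: n_up + n_down]
    for j, flat in enumerate(pick):
        i, s = non_neutral[flat]
        if j < n_up:
            values[i, s] += effect_sd * sd[i]
            labels[i, s] = "UP"
        else:
            values[i, s] -= effect_sd * sd[i]
            labels[i, s] = "DOWN"
    for i in range(zero_variance_features):
        values[i] = mu[i]
        labels[i] = "unchanged"
    values = np.clip(values, 0.0, None)

    matrix = pd.DataFrame(values, index=features, columns=samples)
    neutral = pd.DataFrame(np.abs(seg) < 0.2, index=features, columns=samples)
    truth = pd.DataFrame(labels, index=features, columns=samples)
    return ExpressionCohort(matrix=matrix, neutral_mask=neutral), truth


# ---------------------------------------------------------------------------
# whole studies and scenario presets


def simulate_study(
    cfg: SimConfig,
    outdir: str,
    conditions: Mapping[str, Mapping[str, float]],
    with_peaks: bool = True,
    bound_genes: Iterable[str] | None = None,
) -> SimStudy:
    """Simulate a whole study: annotation, per-replicate BAMs for each
    condition's retention map, optional peaks, sample sheet, truth."""
    os.makedirs(outdir, exist_ok=True)
    gtf_path = os.path.join(outdir, "annotation.gtf")
    genes, contigs = make_toy_annotation(cfg, gtf_path)

    truths: dict[str, SimTruth] = {}
    sheet_rows = []
    for ci, (cond, retention) in enumerate(conditions.items()):
        for rep in range(1, cfg.replicates + 1):
            sample_id = f"{cond}_rep{rep}"
            bam = os.path.join(outdir, f"{sample_id}.bam")
            truths[sample_id] = simulate_reads(
                cfg, genes, retention, contigs, bam,
                seed_key=1000 * (ci + 1) + rep,
            )
            sheet_rows.append({
                "sample_id": sample_id, "condition": cond,
                "replicate": str(rep), "path": bam,
            })
    samples = pd.DataFrame(sheet_rows).set_index("sample_id")
    sheet_path = os.path.join(outdir, "samples.tsv")
    samples.reset_index().to_csv(sheet_path, sep="\t", index=False)

    peaks_path = None
    peak_truth = None
    if with_peaks:
        peaks_path = os.path.join(outdir, "peaks.narrowPeak")
        peak_truth = simulate_peaks(cfg, genes, peaks_path, bound_genes=bound_genes)

    return SimStudy(
        outdir=outdir, gtf_path=gtf_path, contigs=contigs, genes=genes,
        sample_sheet_path=sheet_path, samples=samples, truths=truths,
        retention={c: dict(r) for c, r in conditions.items()},
        peaks_path=peaks_path, peak_truth=peak_truth,
    )


def _ladder_map(genes: Sequence[GeneSpec],
                ladder: Sequence[float] = DEFAULT_RETENTION_LADDER) -> dict[str, float]:
    """Assign ladder values in blocks: genes 1..k get ladder[0], and so on."""
    n = len(genes)
    per = max(1, n // len(ladder))
    return {
        g.gene_id: float(ladder[min(i // per, len(ladder) - 1)])
        for i, g in enumerate(genes)
    }


def default_scenario(seed: int, outdir: str) -> SimStudy:
    """The reference condition of the standard recovery experiment: 20 genes
    over the retention ladder (0, 0.1, 0.25, 0.5, 0.8), four genes each,
    ~5,000 informative mates per gene across three replicates."""
    cfg = SimConfig(seed=seed, n_genes=20, target_informative_per_gene=5000)
    genes, _ = _peek_genes(cfg)
    ladder = _ladder_map(genes)
    return simulate_study(cfg, outdir, conditions={"WT": ladder}, with_peaks=False)


def _peek_genes(cfg: SimConfig) -> tuple[list[GeneSpec], dict[str, int]]:
    """Gene structures for a config without writing anything permanent."""
    import tempfile
    with tempfile.TemporaryDirectory() as tmp:
        return make_toy_annotation(cfg, os.path.join(tmp, "peek.gtf"))


def _coupling_retention(
    cfg: SimConfig,
    genes: Sequence[GeneSpec],
    peak_truth: pd.DataFrame,
    base_r: float,
    max_extra: float,
) -> dict[str, float]:
    """cKO retention: base plus an increment monotone in propensity rank."""
    prop = peak_truth["propensity"].reindex([g.gene_id for g in genes])
    ranks = rankdata(prop.to_numpy())  # ties (unbound zeros) share a mid rank
    extra = max_extra * (ranks - 1) / (len(genes) - 1)
    return {g.gene_id: float(min(base_r + extra[i], 0.95))
            for i, g in enumerate(genes)}


def coupled_scenario(
    seed: int,
    outdir: str,
    n_genes: int = 200,
    base_r: float = 0.1,
    max_extra: float = 0.35,
    coupled: bool = True,
) -> SimStudy:
    """Two-condition study for the binding/splicing association experiment.

    WT retention is ``base_r`` everywhere; with coupling on, cKO retention
    rises monotonically with each gene's binding-propensity rank (up to
    ``base_r + max_extra``), else cKO equals WT.  Two-intron genes and a
    lighter depth (~250 informative mates per gene) keep 200-gene studies
    tractable.
    """
    cfg = SimConfig(
        seed=seed, n_genes=n_genes, exons_per_gene=(3, 3),
        target_informative_per_gene=250, replicates=2,
    )
    genes, _ = _peek_genes(cfg)
    wt = {g.gene_id: base_r for g in genes}
    # peaks must exist before cKO retention can depend on them
    os.makedirs(outdir, exist_ok=True)
    peaks_path = os.path.join(outdir, "peaks.narrowPeak")
    peak_truth = simulate_peaks(cfg, genes, peaks_path)
    ko = (
        _coupling_retention(cfg, genes, peak_truth, base_r, max_extra)
        if coupled else dict(wt)
    )
    study = simulate_study(
        cfg, outdir, conditions={"WT": wt, "cKO": ko}, with_peaks=False,
    )
    study.peaks_path = peaks_path
    study.peak_truth = peak_truth
    return study


def null_scenario(seed: int, outdir: str, n_genes: int = 100) -> SimStudy:
    """Coupling disabled: cKO retention equals WT, peaks independent."""
    cfg = SimConfig(
        seed=seed, n_genes=n_genes, exons_per_gene=(3, 3),
        target_informative_per_gene=150, replicates=2,
    )
    genes, _ = _peek_genes(cfg)
    wt = {g.gene_id: 0.1 for g in genes}
    study = simulate_study(cfg, outdir, conditions={"WT": wt, "cKO": dict(wt)},
                           with_peaks=True)
    return study


def oracle_scenario(seed: int, outdir: str) -> SimStudy:
    """A small study (<10^4 reads) for brute-force equivalence checks."""
    cfg = SimConfig(
        seed=seed, n_genes=6, target_informative_per_gene=300,
        replicates=1, record_read_labels=True,
    )
    genes, _ = _peek_genes(cfg)
    ladder = _ladder_map(genes, (0.0, 0.15, 0.4))
    return simulate_study(cfg, outdir, conditions={"WT": ladder}, with_peaks=True)
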