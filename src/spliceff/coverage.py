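"""Junction coverage counting from coordinate-sorted alignments.

For every junction of the model, counts the alignments that support splicing
(exon-exon, EE) versus intron read-through (intron-exon, IE):

* EE support: the alignment carries a splice gap (CIGAR ``N``) whose genomic
  extent equals the intron exactly — one aligned block ends at the junction's
  ``base_a``, the next begins at ``base_b``;
* IE support: one aligned block contiguously covers both bases of the 2-bp
  boundary junction.

Counting honours a minimum mapping quality (default 10), library strandedness
(default RF, i.e. TruSeq-stranded: mate 2 matches the transcript strand) and
split alignments.  Secondary, supplementary, duplicate and QC-fail records are
ignored.  Note this is deliberately stricter than running ``bedtools multicov
-split`` over 2-bp intervals, which would also credit IE junctions with
spliced reads via their 1-bp exon-side block and so blunt the intron/exon
ratio; here IE requires contiguous coverage of both bases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation import JunctionPair

SIDES = ("ee", "donor", "acceptor")

__all__ = [
    "CoverageConfig",
    "JunctionCounts",
    "read_strand",
    "alignment_blocks_and_gaps",
    "classify_read_support",
    "count_junction_coverage",
    "count_samples",
    "read_sample_sheet",
    "write_counts_tsv",
]


@dataclass(frozen=True)
class CoverageConfig:
    """Counting parameters.

    min_mapq: alignments below this mapping quality are ignored (default 10).
    library_type: 'RF' (read 2 matches the transcript strand; stranded
        TruSeq), 'FR' (read 1 matches), or 'unstranded'.
    count_unit: 'mate' counts each mate independently; 'fragment' counts a
        read pair at most once per junction.
    require_exact_splice_match: EE support requires the splice gap to equal
        the intron exactly (default on).
    """

    min_mapq: int = 10
    library_type: str = "RF"
    count_unit: str = "mate"
    require_exact_splice_match: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if self.library_type not in ("RF", "FR", "unstranded"):
            raise ValueError(f"unknown library_type {self.library_type!r}")
        if self.count_unit not in ("mate", "fragment"):
            raise ValueError(f"unknown count_unit {self.count_unit!r}")


def junction_key(pair: JunctionPair, side: str) -> tuple[str, int, str]:
    """Stable identifier of one junction: (gene_id, intron_index, side)."""
    return (pair.gene_id, pair.intron_index, side)


@dataclass
class JunctionCounts:
    """Per-(sample, junction) counts, zero-filled over the whole model.

    ``counts`` is indexed by (gene_id, intron_index, side) with one integer
    column per sample; ``samples`` maps sample_id -> condition / replicate.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)

    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def for_condition(self, condition: str) -> list[str]:
        sel = self.samples[self.samples["condition"] == condition]
        return list(sel.index)


def read_strand(aln: pysam.AlignedSegment, library_type: str) -> str:
    """Transcript strand implied by one mate under the library protocol.

    RF: mate 2 is on the transcript strand (mate 1 opposite); FR: the
    reverse.  Unpaired reads are treated as mate 1.  Unstranded libraries
    return '.', which matches any junction strand.
    """
    if library_type == "unstranded":
        return "."
    mate2 = aln.is_paired and aln.is_read2
    phys = "-" if aln.is_reverse else "+"
    flip = (library_type == "RF") != mate2  # RF flips mate1; FR flips mate2
    if flip:
        return "-" if phys == "+" else "+"
    return phys


def alignment_blocks_and_gaps(
    aln: pysam.AlignedSegment,
) -> tuple[list[tuple[int, int]], set[tuple[int, int]]]:
    """Reference-contiguous aligned blocks and splice gaps of one alignment.

    Blocks are maximal runs of reference-consuming, non-skip operations
    (M/=/X/D — a deletion does not interrupt contiguity); each CIGAR ``N``
    closes a block and records a half-open gap interval.
    """
    blocks: list[tuple[int, int]] = []
    gaps: set[tuple[int, int]] = set()
    pos = aln.reference_start
    block_start = pos
    for op, length in aln.cigartuples or ():
        if op in (0, 2, 7, 8):  # M, D, =, X consume reference
            pos += length
        elif op == 3:  # N: splice gap
            if pos > block_start:
                blocks.append((block_start, pos))
            gaps.add((pos, pos + length))
            pos += length
            block_start = pos
        # I, S, H, P consume no reference
    if pos > block_start:
        blocks.append((block_start, pos))
    return blocks, gaps


def _usable(aln: pysam.AlignedSegment, cfg: CoverageConfig) -> bool:
    return not (
        aln.is_unmapped
        or aln.is_secondary
        or aln.is_supplementary
        or aln.is_duplicate
        or aln.is_qcfail
        or aln.mapping_quality < cfg.min_mapq
    )


def classify_read_support(
    aln: pysam.AlignedSegment,
    pair: JunctionPair,
    cfg: CoverageConfig = CoverageConfig(),
    _blocks_gaps: tuple | None = None,
    _strand: str | None = None,
) -> frozenset[str]:
    """Which of one intron's junctions this alignment supports.

    Returns a (possibly empty) subset of {'ee', 'donor', 'acceptor'}.  An
    alignment failing the MAPQ/flag filters or mismatching the junction
    strand supports nothing.
    """
    if not _usable(aln, cfg):
        return frozenset()
    strand = _strand if _strand is not None else read_strand(aln, cfg.library_type)
    if strand != "." and strand != pair.ee.strand:
        return frozenset()
    blocks, gaps = (
        _blocks_gaps if _blocks_gaps is not None else alignment_blocks_and_gaps(aln)
    )
    out = set()
    if cfg.require_exact_splice_match:
        if pair.intron in gaps:
            out.add("ee")
    else:
        a, b = pair.intron
        if any(ga <= a and gb >= b for ga, gb in gaps):
            out.add("ee")
    for side, j in (("donor", pair.ie_donor), ("acceptor", pair.ie_acceptor)):
        for s, e in blocks:
            if s <= j.base_a and e >= j.base_b + 1:
                out.add(side)
                break
    return frozenset(out)


def _pair_trees(
    pairs: Sequence[JunctionPair],
) -> dict[str, IntervalTree]:
    """Per-contig interval tree over each pair's donor..acceptor extent."""
    trees: dict[str, IntervalTree] = {}
    for p in pairs:
        t = trees.setdefault(p.ee.contig, IntervalTree())
        # any read supporting this pair must overlap [base_a, base_b+1)
        t[p.ee.base_a:p.ee.base_b + 1] = p
    return trees


def count_junction_coverage(
    alignments: str | pysam.AlignmentFile,
    pairs: Sequence[JunctionPair],
    cfg: CoverageConfig = CoverageConfig(),
) -> dict[tuple[str, int, str], int]:
    """Count junction support in one alignment file.

    Every qualifying alignment increments every junction it supports (a long
    or spliced read may support several); in fragment mode the two mates of a
    pair supporting the same junction count once.  Returns a zero-filled
    mapping (gene_id, intron_index, side) -> count.
    """
    own = isinstance(alignments, str)
    af = pysam.AlignmentFile(alignments) if own else alignments
    try:
        if af.is_bam and not af.has_index():
            raise FileNotFoundError(
                f"{af.filename.decode()}: BAM index required (samtools index)"
            )
        counts: dict[tuple[str, int, str], int] = {
            junction_key(p, side): 0 for p in pairs for side in SIDES
        }
        trees = _pair_trees(pairs)
        bam_contigs = set(af.references)
        for contig in bam_contigs - set(trees):
            warnings.warn(f"contig {contig} absent from the junction model; skipped")
        for contig in set(trees) - bam_contigs:
            warnings.warn(f"annotation contig {contig} absent from alignments; skipped")
        seen_fragments: set[tuple] = set()

        def _count_stream(stream, tree_of) -> None:
            for aln in stream:
                if not _usable(aln, cfg):
                    continue
                tree = tree_of(aln)
                if tree is None:
                    continue
                strand = read_strand(aln, cfg.library_type)
                bg = alignment_blocks_and_gaps(aln)
                if not bg[0]:
                    continue
                lo, hi = bg[0][0][0], bg[0][-1][1]
                for iv in tree.overlap(lo, hi):
                    p: JunctionPair = iv.data
                    for side in classify_read_support(
                        aln, p, cfg, _blocks_gaps=bg, _strand=strand
                    ):
                        key = junction_key(p, side)
                        if cfg.count_unit == "fragment":
                            fkey = (aln.query_name, key)
                            if fkey in seen_fragments:
                                continue
                            seen_fragments.add(fkey)
                        counts[key] += 1

        if af.has_index():
            for contig, tree in trees.items():
                if contig in bam_contigs:
                    _count_stream(af.fetch(contig), lambda a, t=tree: t)
        else:  # SAM or unindexed stream: a single pass, dispatch by contig
            _count_stream(
                af.fetch(until_eof=True),
                lambda a: trees.get(a.reference_name),
            )
        return counts
    finally:
        if own:
            af.close()


def count_splice_gap(
    alignments: str | pysam.AlignmentFile,
    contig: str,
    gap: tuple[int, int],
    strand: str | None = None,
    cfg: CoverageConfig = CoverageConfig(),
) -> int:
    """Count alignments whose splice gap equals ``gap`` exactly.

    Supports junctions outside the consecutive-exon model — e.g. the
    flank-to-flank exclusion junction of a cassette exon.  ``strand``
    restricts to reads on that transcript strand (under ``cfg.library_type``);
    the usual MAPQ/flag filters apply.
    """
    own = isinstance(alignments, str)
    af = pysam.AlignmentFile(alignments) if own else alignments
    try:
        if af.has_index():
            stream = af.fetch(contig, max(0, gap[0] - 1), gap[1] + 1)
        else:
            stream = (a for a in af.fetch(until_eof=True)
                      if a.reference_name == contig)
        n = 0
        seen: set[str] = set()
        for aln in stream:
            if not _usable(aln, cfg):
                continue
            if strand is not None:
                s = read_strand(aln, cfg.library_type)
                if s != "." and s != strand:
                    continue
            _, gaps = alignment_blocks_and_gaps(aln)
            if gap in gaps:
                if cfg.count_unit == "fragment":
                    if aln.query_name in seen:
                        continue
                    seen.add(aln.query_name)
                n += 1
        return n
    finally:
        if own:
            af.close()


def read_sample_sheet(path: str) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, condition, replicate, path."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "replicate", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    return df.set_index("sample_id")


def count_samples(
    samples: pd.DataFrame,
    pairs: Sequence[JunctionPair],
    cfg: CoverageConfig = CoverageConfig(),
) -> JunctionCounts:
    """Run :func:`count_junction_coverage` over a sample sheet."""
    index = pd.MultiIndex.from_tuples(
        [junction_key(p, side) for p in pairs for side in SIDES],
        names=["gene_id", "intron_index", "side"],
    )
    data = {}
    for sample_id, row in samples.iterrows():
        c = count_junction_coverage(row["path"], pairs, cfg)
        data[sample_id] = [c[k] for k in index]
    df = pd.DataFrame(data, index=index, dtype="int64")
    return JunctionCounts(counts=df, samples=samples)


def write_counts_tsv(
    jc: JunctionCounts, pairs: Sequence[JunctionPair], path: str
) -> None:
    """Counts TSV: junction key columns plus one count column per sample."""
    meta_rows = []
    for p in pairs:
        for side, j in (("ee", p.ee), ("donor", p.ie_donor), ("acceptor", p.ie_acceptor)):
            meta_rows.append({
                "contig": j.contig, "base_a": j.base_a, "base_b": j.base_b,
                "kind": j.kind, "side": side, "gene_id": j.gene_id,
                "strand": j.strand, "intron_index": p.intron_index,
            })
    meta = pd.DataFrame(meta_rows).set_index(
        pd.MultiIndex.from_tuples(
            [junction_key(p, s) for p in pairs for s in SIDES],
            names=["gene_id", "intron_index", "side"],
        )
    )
    out = pd.concat([meta, jc.counts.loc[meta.index]], axis=1)
    out.to_csv(path, sep="\t", index=False)
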