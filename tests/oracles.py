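"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive and written against pysam/numpy primitives only, not
against the package's own classification or counting code paths.
"""

from __future__ import annotations

import numpy as np
import pysam


def brute_merge(intervals):
    """Union of half-open intervals via per-base boolean marking."""
    if not intervals:
        return []
    lo = min(a for a, _ in intervals)
    hi = max(b for _, b in intervals)
    marked = np.zeros(hi - lo, dtype=bool)
    for a, b in intervals:
        marked[a - lo:b - lo] = True
    out = []
    i = 0
    n = len(marked)
    while i < n:
        if marked[i]:
            j = i
            while j < n and marked[j]:
                j += 1
            out.append((i + lo, j + lo))
            i = j
        else:
            i += 1
    return out


def brute_junction_coordinates(merged_exons):
    """Expected (ee, donor, acceptor) base coordinates per intron, enumerated
    directly from consecutive merged exons."""
    out = []
    for k in range(len(merged_exons) - 1):
        up_end = merged_exons[k][1]
        down_start = merged_exons[k + 1][0]
        ee = (up_end - 1, down_start)
        donor = (up_end - 1, up_end)
        acceptor = (down_start - 1, down_start)
        out.append((ee, donor, acceptor))
    return out


def brute_overlap_filter(genes):
    """Gene ids to drop: all-pairs same-strand span-overlap test."""
    bad = set()
    for g in genes:
        for h in genes:
            if g is h or g.contig != h.contig or g.strand != h.strand:
                continue
            if g.start < h.end and h.start < g.end:
                bad.add(g.gene_id)
                bad.add(h.gene_id)
    return bad


def _brute_strand(aln: pysam.AlignedSegment, library_type: str) -> str:
    if library_type == "unstranded":
        return "."
    rev = bool(aln.flag & 0x10)
    read2 = bool(aln.flag & 0x1) and bool(aln.flag & 0x80)
    phys = "-" if rev else "+"
    if library_type == "RF":
        on_transcript = read2
    else:  # FR
        on_transcript = not read2
    if on_transcript:
        return phys
    return "+" if phys == "-" else "-"


def _brute_gaps(aln: pysam.AlignedSegment):
    """N-gap intervals recomputed by walking the CIGAR string."""
    gaps = set()
    pos = aln.reference_start
    num = ""
    for ch in aln.cigarstring or "":
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "MDX=":
            pos += n
        elif ch == "N":
            gaps.add((pos, pos + n))
            pos += n
    return gaps


def brute_classify(aln, pair, min_mapq=10, library_type="RF"):
    """Naive per-(alignment, junction-pair) support labels."""
    if aln.flag & (0x4 | 0x100 | 0x800 | 0x400 | 0x200):
        return set()
    if aln.mapping_quality < min_mapq:
        return set()
    strand = _brute_strand(aln, library_type)
    if strand != "." and strand != pair.ee.strand:
        return set()
    labels = set()
    if (pair.ee.base_a + 1, pair.ee.base_b) in _brute_gaps(aln):
        labels.add("ee")
    positions = set(aln.get_reference_positions())
    for side, j in (("donor", pair.ie_donor), ("acceptor", pair.ie_acceptor)):
        # adjacent bases both aligned implies contiguous coverage
        if j.base_a in positions and j.base_b in positions:
            labels.add(side)
    return labels


def brute_count(bam_path, pairs, min_mapq=10, library_type="RF",
                count_unit="mate"):
    """Naive double loop over every alignment and every junction pair."""
    counts = {(p.gene_id, p.intron_index, s): 0
              for p in pairs for s in ("ee", "donor", "acceptor")}
    seen = set()
    with pysam.AlignmentFile(bam_path) as af:
        for aln in af.fetch(until_eof=True):
            for p in pairs:
                if p.ee.contig != aln.reference_name:
                    continue
                for side in brute_classify(aln, p, min_mapq, library_type):
                    key = (p.gene_id, p.intron_index, side)
                    if count_unit == "fragment":
                        fk = (aln.query_name, key)
                        if fk in seen:
                            continue
                        seen.add(fk)
                    counts[key] += 1
    return counts


def brute_zscores(values, mask):
    """Two-pass per-row standardisation against masked columns."""
    values = np.asarray(values, float)
    mask = np.asarray(mask, bool)
    z = np.full(values.shape, np.nan)
    for i in range(values.shape[0]):
        ref = [values[i, j] for j in range(values.shape[1]) if mask[i, j]]
        n = len(ref)
        if n < 2:
            continue
        mean = sum(ref) / n
        var = sum((x - mean) ** 2 for x in ref) / (n - 1)
        if var == 0:
            continue
        sd = var ** 0.5
        for j in range(values.shape[1]):
            z[i, j] = (values[i, j] - mean) / sd
    return z
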