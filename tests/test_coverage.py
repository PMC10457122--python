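"""Junction counting: strand inference, EE/IE classification, and exact
agreement with both the generator's truth labels and a brute-force oracle."""

import warnings

import pysam
import pytest

import spliceff as sf
from oracles import brute_count

HEADER = pysam.AlignmentHeader.from_dict({
    "HD": {"VN": "1.6", "SO": "coordinate"},
    "SQ": [{"SN": "chr1", "LN": 100_000}],
})


def _aln(start, cigar, flag=0x1 | 0x2 | 0x20 | 0x80, mapq=60, qname="r1"):
    """A mate on the forward strand; default flags make it read 2 of a pair,
    i.e. transcript strand '+' under RF."""
    a = pysam.AlignedSegment(HEADER)
    a.query_name = qname
    a.reference_id = 0
    a.reference_start = start
    a.cigarstring = cigar
    a.flag = flag
    a.mapping_quality = mapq
    return a


def _pair(exons=((100, 200), (300, 400)), strand="+"):
    ann = sf.GenomeAnnotation(genes=(sf.GeneModel(
        gene_id="G", contig="chr1", strand=strand,
        start=exons[0][0], end=exons[-1][1], merged_exons=tuple(exons)),))
    return sf.build_junctions(ann)[0]


@pytest.mark.parametrize("library_type, is_read2, is_reverse, expected", [
    ("RF", False, True, "+"),   # RF: reversed read 1 -> '+' transcript
    ("RF", False, False, "-"),
    ("RF", True, False, "+"),   # RF: forward read 2 -> '+'
    ("FR", False, True, "-"),   # FR is the mirror protocol
    ("FR", True, True, "+"),
    ("unstranded", False, True, "."),
])
def test_read_strand(library_type, is_read2, is_reverse, expected):
    flag = 0x1 | (0x80 if is_read2 else 0x40) | (0x10 if is_reverse else 0)
    a = _aln(1000, "75M", flag=flag)
    assert sf.read_strand(a, library_type) == expected


@pytest.mark.parametrize("start, cigar, mapq, expected", [
    (180, "50M", 60, {"donor"}),          # block covers bases 199 and 200
    (180, "20M100N30M", 60, {"ee"}),      # gap [200,300) matches the intron
    (180, "20M100N30M", 5, set()),        # below the MAPQ 10 floor
    # gap [200,290) != intron: no EE support, but the downstream block
    # covers intronic base 299 and exonic base 300, a true acceptor read-through
    (180, "20M90N40M", 60, {"acceptor"}),
    (180, "20M90N10M", 60, set()),        # gap mismatch, block ends at 300
    (210, "50M", 60, set()),              # fully intronic: no boundary
    (260, "75M", 60, {"acceptor"}),       # covers bases 299 and 300
    (150, "50M", 60, set()),              # ends at 199: donor base 200 missing
])
def test_classify_read_support_examples(start, cigar, mapq, expected):
    pair = _pair()
    assert sf.classify_read_support(_aln(start, cigar, mapq=mapq), pair) == expected


def test_classify_requires_matching_strand():
    pair = _pair(strand="-")
    a = _aln(180, "50M")  # transcript strand '+' under RF
    assert sf.classify_read_support(a, pair) == set()
    cfg = sf.CoverageConfig(library_type="unstranded")
    assert sf.classify_read_support(a, pair, cfg) == {"donor"}


def test_classify_ignores_secondary_and_duplicate_reads():
    pair = _pair()
    for extra in (0x100, 0x400, 0x200, 0x800, 0x4):
        a = _aln(180, "50M", flag=0x1 | 0x2 | 0x20 | 0x80 | extra)
        assert sf.classify_read_support(a, pair) == set()


def test_empty_bam_yields_zero_filled_counts(tmp_path):
    bam = str(tmp_path / "empty.bam")
    with pysam.AlignmentFile(bam, "wb", header=HEADER):
        pass
    pysam.index(bam)
    pair = _pair()
    counts = sf.count_junction_coverage(bam, [pair])
    assert set(counts.values()) == {0}
    assert len(counts) == 3


def test_counts_equal_generator_truth_exactly(oracle_study, oracle_counts):
    """Pipeline mate-mode counts on the emitted BAM must equal the
    simulator's per-read truth tallies for every junction and sample."""
    for sample_id, truth in oracle_study.truths.items():
        got = oracle_counts.counts[sample_id]
        for key, expected in truth.realized.items():
            assert got.loc[key] == expected
        assert int(got.sum()) == sum(truth.realized.values())
        # truth labels, where recorded, tally to the realized counts
        if truth.read_labels:
            from collections import Counter
            tally = Counter(k for _, _, k in truth.read_labels)
            assert dict(tally) == {k: v for k, v in truth.realized.items() if v}


@pytest.mark.parametrize("count_unit", ["mate", "fragment"])
def test_counts_equal_bruteforce_oracle(oracle_study, oracle_model, count_unit):
    """Exact equivalence with the naive every-(alignment, junction) loop."""
    _, pairs = oracle_model
    bam = str(oracle_study.samples["path"].iloc[0])
    cfg = sf.CoverageConfig(count_unit=count_unit)
    got = sf.count_junction_coverage(bam, pairs, cfg)
    expected = brute_count(bam, pairs, count_unit=count_unit)
    assert got == expected


def test_raising_min_mapq_never_increases_counts(oracle_study, oracle_model):
    _, pairs = oracle_model
    bam = str(oracle_study.samples["path"].iloc[0])
    previous = None
    for mapq in (0, 10, 40, 100):
        counts = sf.count_junction_coverage(
            bam, pairs, sf.CoverageConfig(min_mapq=mapq))
        if previous is not None:
            assert all(counts[k] <= previous[k] for k in counts)
        previous = counts
    assert set(previous.values()) == {0}  # nothing maps at MAPQ 100


def test_counts_invariant_to_read_order(oracle_study, oracle_model, tmp_path, rng):
    """A shuffled, unindexed SAM gives identical counts to the sorted BAM."""
    _, pairs = oracle_model
    bam = str(oracle_study.samples["path"].iloc[0])
    with pysam.AlignmentFile(bam) as af:
        records = list(af.fetch(until_eof=True))
        header = af.header
    order = rng.permutation(len(records))
    sam = str(tmp_path / "shuffled.sam")
    with pysam.AlignmentFile(sam, "w", header=header) as out:
        for i in order:
            out.write(records[i])
    assert sf.count_junction_coverage(sam, pairs) == \
        sf.count_junction_coverage(bam, pairs)


def test_antisense_library_counts_zero(tmp_path):
    """Reads simulated under FR but counted as RF land on the wrong strand
    for every junction, so all counts are zero."""
    cfg = sf.SimConfig(seed=9, n_genes=4, target_informative_per_gene=200,
                       replicates=1, library_type="FR")
    genes, contigs = sf.make_toy_annotation(cfg, str(tmp_path / "ann.gtf"))
    retention = {g.gene_id: 0.3 for g in genes}
    bam = str(tmp_path / "fr.bam")
    sf.simulate_reads(cfg, genes, retention, contigs, bam, seed_key=1)
    ann = sf.parse_annotation(str(tmp_path / "ann.gtf"))
    pairs = sf.build_junctions(ann)
    counts_rf = sf.count_junction_coverage(bam, pairs, sf.CoverageConfig())
    assert set(counts_rf.values()) == {0}
    counts_fr = sf.count_junction_coverage(
        bam, pairs, sf.CoverageConfig(library_type="FR"))
    assert sum(counts_fr.values()) > 0


def test_fragment_mode_counts_a_pair_once(tmp_path):
    """Both mates spanning the donor boundary: +2 in mate mode, +1 in
    fragment mode."""
    pair = _pair()
    bam = str(tmp_path / "pair.bam")
    with pysam.AlignmentFile(bam, "wb", header=HEADER) as out:
        out.write(_aln(170, "60M", flag=0x1 | 0x2 | 0x20 | 0x80, qname="f1"))
        r1 = _aln(176, "60M", flag=0x1 | 0x2 | 0x10 | 0x40, qname="f1")
        out.write(r1)
    pysam.index(bam)
    mate = sf.count_junction_coverage(bam, [pair])
    frag = sf.count_junction_coverage(
        bam, [pair], sf.CoverageConfig(count_unit="fragment"))
    assert mate[("G", 0, "donor")] == 2
    assert frag[("G", 0, "donor")] == 1


def test_missing_bam_index_is_an_error(tmp_path):
    bam = str(tmp_path / "noindex.bam")
    with pysam.AlignmentFile(bam, "wb", header=HEADER) as out:
        out.write(_aln(180, "50M"))
    with pytest.raises(FileNotFoundError, match="index"):
        sf.count_junction_coverage(bam, [_pair()])


def test_unknown_contig_warns_and_skips(tmp_path):
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "chr1", "LN": 100_000}, {"SN": "chrUn", "LN": 5_000}],
    })
    bam = str(tmp_path / "extra.bam")
    with pysam.AlignmentFile(bam, "wb", header=header) as out:
        a = pysam.AlignedSegment(header)
        a.query_name = "r"
        a.reference_id = 1
        a.reference_start = 100
        a.cigarstring = "75M"
        a.flag = 0x1 | 0x2 | 0x20 | 0x80
        a.mapping_quality = 60
        out.write(a)
    pysam.index(bam)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        counts = sf.count_junction_coverage(bam, [_pair()])
    assert any("chrUn" in str(w.message) for w in caught)
    assert set(counts.values()) == {0}
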