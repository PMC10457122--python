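"""Gene-model construction: GTF parsing, exon merging, junction building,
overlapping-gene purification, and the junctions TSV round trip."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spliceff as sf
from oracles import brute_junction_coordinates, brute_merge, brute_overlap_filter

# Three genes, hand-checked: A has two transcripts sharing an exon plus one
# transcript-specific extension; C has book-ended exons that must merge.
TOY_GTF = """\
chr1\ttoy\texon\t101\t200\t.\t+\t.\tgene_id "GA"; transcript_id "GA.1";
chr1\ttoy\texon\t301\t400\t.\t+\t.\tgene_id "GA"; transcript_id "GA.1";
chr1\ttoy\texon\t101\t250\t.\t+\t.\tgene_id "GA"; transcript_id "GA.2";
chr1\ttoy\texon\t301\t400\t.\t+\t.\tgene_id "GA"; transcript_id "GA.2";
chrX\ttoy\texon\t501\t800\t.\t-\t.\tgene_id "GB"; transcript_id "GB.1";
chr2\ttoy\texon\t1001\t1100\t.\t+\t.\tgene_id "GC"; transcript_id "GC.1";
chr2\ttoy\texon\t1101\t1200\t.\t+\t.\tgene_id "GC"; transcript_id "GC.1";
"""

EXPECTED_MODELS = {
    # gene_id: (contig, strand, span, merged exons)
    "GA": ("chr1", "+", (100, 400), ((100, 250), (300, 400))),
    "GB": ("chrX", "-", (500, 800), ((500, 800),)),
    "GC": ("chr2", "+", (1000, 1200), ((1000, 1200),)),
}


def test_parse_annotation_builds_expected_gene_models(tmp_path):
    """Exons pool over transcripts, GTF 1-based coordinates convert to
    0-based half-open, and book-ended exons merge."""
    gtf = tmp_path / "toy.gtf"
    gtf.write_text(TOY_GTF)
    ann = sf.parse_annotation(str(gtf))
    assert sorted(g.gene_id for g in ann.genes) == sorted(EXPECTED_MODELS)
    for g in ann.genes:
        contig, strand, span, exons = EXPECTED_MODELS[g.gene_id]
        assert (g.contig, g.strand, g.span, g.merged_exons) == (
            contig, strand, span, exons)


def test_parse_annotation_is_gzip_transparent(tmp_path):
    import gzip
    gz = tmp_path / "toy.gtf.gz"
    with gzip.open(gz, "wt") as fh:
        fh.write(TOY_GTF)
    ann = sf.parse_annotation(str(gz))
    assert len(ann.genes) == 3


@pytest.mark.parametrize("content, match", [
    ("chr1\ttoy\texon\t1\t100\t.\t+\t.\ttranscript_id \"T\";\n", "line 1"),
    (TOY_GTF + "chr1\ttoy\texon\t1\t9\t.\t+\t.\tnothing here\n", "line 8"),
    ("", "no features"),
    ("# only a comment\n", "no features"),
])
def test_parse_annotation_errors_name_the_line(tmp_path, content, match):
    gtf = tmp_path / "bad.gtf"
    gtf.write_text(content)
    with pytest.raises(sf.AnnotationError, match=match):
        sf.parse_annotation(str(gtf))


@pytest.mark.parametrize("raw, expected", [
    ([(100, 200), (150, 250)], [(100, 250)]),            # overlapping
    ([(100, 200), (200, 300)], [(100, 300)]),            # book-ended
    ([(300, 400), (100, 200)], [(100, 200), (300, 400)]),  # disjoint, unsorted
    ([], []),                                            # empty is not an error
])
def test_merge_exons_examples(raw, expected):
    assert sf.merge_exons(raw) == expected


def test_merge_exons_matches_per_base_oracle(rng):
    starts = rng.integers(0, 10_000, 1000)
    lengths = rng.integers(1, 300, 1000)
    ivals = [(int(a), int(a + l)) for a, l in zip(starts, lengths)]
    merged = sf.merge_exons(ivals)
    # per-base marking merges overlapping and book-ended intervals alike
    assert merged == brute_merge(ivals)
    assert all(merged[i][1] < merged[i + 1][0] for i in range(len(merged) - 1))


@given(st.lists(
    st.tuples(st.integers(0, 5000), st.integers(1, 500)).map(
        lambda t: (t[0], t[0] + t[1])),
    max_size=60,
))
@settings(max_examples=200, deadline=None)
def test_merge_exons_idempotent_and_order_invariant(ivals):
    merged = sf.merge_exons(ivals)
    assert sf.merge_exons(merged) == merged
    assert sf.merge_exons(list(reversed(ivals))) == merged


def _gene(gene_id, exons, strand="+", contig="chr1"):
    return sf.GeneModel(gene_id=gene_id, contig=contig, strand=strand,
                        start=exons[0][0], end=exons[-1][1],
                        merged_exons=tuple(exons))


def test_build_junctions_coordinates():
    """A gene with merged exons [100,200), [300,400): EE bases {199, 300},
    donor {199, 200}, acceptor {299, 300}; single-exon genes yield none."""
    ann = sf.GenomeAnnotation(genes=(
        _gene("G2", [(100, 200), (300, 400)]),
        _gene("G1", [(500, 900)], contig="chr2"),
    ))
    pairs = sf.build_junctions(ann)
    assert len(pairs) == 1
    p = pairs[0]
    assert (p.ee.base_a, p.ee.base_b) == (199, 300)
    assert (p.ie_donor.base_a, p.ie_donor.base_b) == (199, 200)
    assert (p.ie_acceptor.base_a, p.ie_acceptor.base_b) == (299, 300)
    assert p.intron == (200, 300)


def test_build_junctions_matches_enumeration(oracle_study):
    """One pair per intron, coordinates equal to independent enumeration
    from the merged-exon lists, for every simulated gene."""
    ann = sf.parse_annotation(oracle_study.gtf_path)
    pairs = sf.build_junctions(ann)
    n_introns = sum(len(g.merged_exons) - 1 for g in ann.genes)
    assert len(pairs) == n_introns
    by_gene = {}
    for p in pairs:
        by_gene.setdefault(p.gene_id, []).append(p)
    for g in ann.genes:
        expected = brute_junction_coordinates(g.merged_exons)
        got = sorted(by_gene.get(g.gene_id, []), key=lambda p: p.intron_index)
        assert len(got) == len(expected) == len(g.merged_exons) - 1
        for p, (ee, donor, acceptor) in zip(got, expected):
            assert (p.ee.base_a, p.ee.base_b) == ee
            assert (p.ie_donor.base_a, p.ie_donor.base_b) == donor
            assert (p.ie_acceptor.base_a, p.ie_acceptor.base_b) == acceptor


@pytest.mark.parametrize("strand_b, both_removed", [("+", True), ("-", False)])
def test_pair_and_purify_same_strand_overlap(strand_b, both_removed):
    """Same-strand span overlap removes both genes; antisense overlap is
    kept because counting is strand-aware."""
    ann = sf.GenomeAnnotation(genes=(
        _gene("GA", [(0, 400), (600, 1000)], strand="+"),
        _gene("GB", [(500, 900), (1100, 1500)], strand=strand_b),
    ))
    pairs = sf.pair_and_purify(sf.build_junctions(ann), ann)
    kept_genes = {p.gene_id for p in pairs}
    assert kept_genes == (set() if both_removed else {"GA", "GB"})


def test_pair_and_purify_matches_bruteforce(tmp_path):
    """With a planted overlapping gene pair, survivors equal the all-pairs
    interval-overlap oracle."""
    cfg = sf.SimConfig(seed=3, n_genes=8, plant_overlap=True)
    genes, _ = sf.make_toy_annotation(cfg, str(tmp_path / "ann.gtf"))
    ann = sf.parse_annotation(str(tmp_path / "ann.gtf"))
    pairs = sf.pair_and_purify(sf.build_junctions(ann), ann)
    bad = brute_overlap_filter(ann.genes)
    planted = {f"SIMG{cfg.n_genes + 1:04d}", f"SIMG{cfg.n_genes + 2:04d}"}
    assert bad == planted
    assert {p.gene_id for p in pairs} == {g.gene_id for g in ann.genes} - bad
    # no dangling members: every pair is complete and self-consistent
    for p in pairs:
        assert p.ee.base_a == p.ie_donor.base_a
        assert p.ee.base_b == p.ie_acceptor.base_b


def test_junctions_tsv_round_trip(oracle_model, tmp_path):
    _, pairs = oracle_model
    path = tmp_path / "junctions.tsv"
    sf.write_junctions_tsv(pairs, str(path))
    back = sf.read_junctions_tsv(str(path))
    assert back == list(pairs)
    path2 = tmp_path / "again.tsv"
    sf.write_junctions_tsv(back, str(path2))
    assert path.read_bytes() == path2.read_bytes()
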