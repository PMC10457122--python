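"""Gene models and the exon-intron junction model.

Builds, from a GENCODE-style GTF, one gene model per ``gene_id`` with exons
pooled over all transcripts and merged into disjoint intervals.  Each intron
between consecutive merged exons yields one :class:`JunctionPair`:

* an exon-exon (EE) junction — the last base of the upstream merged exon and
  the first base of the downstream one, supported by reads whose splice gap
  matches the intron exactly;
* two intron-exon (IE) junctions — two genomically adjacent bases straddling
  the exon|intron (donor-side) and intron|exon (acceptor-side) boundaries,
  supported by reads aligned contiguously across both bases.

All internal coordinates are 0-based half-open; GTF input (1-based inclusive)
is converted on parse, and any BED-like output is 0-based half-open.
Book-ended exons (end == next start) are merged: a zero-length intron is not
a splice site.
"""

from __future__ import annotations

import gzip
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gffutils

EE = "EE"
IE = "IE"

__all__ = [
    "AnnotationError",
    "GeneModel",
    "GenomeAnnotation",
    "Junction",
    "JunctionPair",
    "parse_annotation",
    "merge_exons",
    "build_junctions",
    "pair_and_purify",
    "write_junctions_tsv",
    "read_junctions_tsv",
]


class AnnotationError(ValueError):
    """Raised for malformed or unusable annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: strand, genomic span and merged exon/intron structure."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    merged_exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        for (a, b) in self.merged_exons:
            if not (self.start <= a < b <= self.end):
                raise AnnotationError(
                    f"gene {self.gene_id}: exon [{a},{b}) outside span "
                    f"[{self.start},{self.end})"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive merged exons, in genomic order."""
        ex = self.merged_exons
        return tuple((ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1))


@dataclass(frozen=True)
class GenomeAnnotation:
    """A set of gene models plus contig names and lengths (bp)."""

    genes: tuple[GeneModel, ...]
    contigs: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            length = self.contigs.get(g.contig)
            if length is not None and g.end > length:
                raise AnnotationError(
                    f"gene {g.gene_id} extends past contig {g.contig} "
                    f"({g.end} > {length})"
                )

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class Junction:
    """A 2-bp junction: ``base_a`` is the last base of the upstream feature,
    ``base_b`` the first base of the downstream one (0-based positions).

    For IE junctions the two bases are genomically adjacent
    (``base_b == base_a + 1``); for EE junctions they are separated by the
    intron.  ``exon_end_label`` records which end of its exon, relative to
    gene strand, the boundary sits at (5prime or 3prime).
    """

    kind: str
    gene_id: str
    contig: str
    strand: str
    base_a: int
    base_b: int
    exon_end_label: str

    def __post_init__(self) -> None:
        if self.kind == IE and self.base_b != self.base_a + 1:
            raise AnnotationError("IE junction bases must be adjacent")
        if self.kind == EE and self.base_b <= self.base_a + 1:
            raise AnnotationError("EE junction bases must flank an intron")


@dataclass(frozen=True)
class JunctionPair:
    """One intron's EE junction plus its donor- and acceptor-side IE junctions.

    'Donor' and 'acceptor' are genomic: the donor-side boundary is the
    exon|intron transition at the intron's left edge, the acceptor-side the
    intron|exon transition at its right edge.
    """

    ee: Junction
    ie_donor: Junction
    ie_acceptor: Junction
    intron_index: int

    def __post_init__(self) -> None:
        same_gene = self.ee.gene_id == self.ie_donor.gene_id == self.ie_acceptor.gene_id
        same_contig = self.ee.contig == self.ie_donor.contig == self.ie_acceptor.contig
        if not (same_gene and same_contig):
            raise AnnotationError("junction pair members disagree on gene/contig")
        if self.ee.base_a != self.ie_donor.base_a or self.ee.base_b != self.ie_acceptor.base_b:
            raise AnnotationError("junction pair coordinates inconsistent")

    @property
    def gene_id(self) -> str:
        return self.ee.gene_id

    @property
    def intron(self) -> tuple[int, int]:
        """The intron interval [base_a+1, base_b), half-open."""
        return (self.ee.base_a + 1, self.ee.base_b)


def merge_exons(raw_exons: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted; book-ended intervals are merged.

    Empty input yields an empty list. Idempotent and order-invariant.
    """
    ivals = sorted((int(a), int(b)) for a, b in raw_exons)
    merged: list[tuple[int, int]] = []
    for a, b in ivals:
        if b <= a:
            raise AnnotationError(f"empty or inverted exon interval [{a},{b})")
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _prescan_gtf(path: str, feature_filter: Sequence[str]) -> None:
    """Validate the GTF before the real parse so errors can name lines."""
    n_features = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 9 tab-separated GTF fields, "
                    f"got {len(fields)}"
                )
            if fields[2] not in feature_filter:
                continue
            n_features += 1
            if "gene_id" not in fields[8]:
                raise AnnotationError(
                    f"{path}: line {lineno}: {fields[2]} feature has no gene_id attribute"
                )
    if n_features == 0:
        raise AnnotationError(
            f"{path}: no features of type {'/'.join(feature_filter)} found"
        )


def parse_annotation(
    path: str,
    feature_filter: Sequence[str] = ("exon",),
    contigs: dict[str, int] | None = None,
) -> GenomeAnnotation:
    """Parse a GTF into a :class:`GenomeAnnotation` (gzip-transparent).

    Exons are collected from *all* transcripts of a gene, pooled, and merged
    (:func:`merge_exons`).  The gene span is the hull of its merged exons.
    Contig lengths are taken from ``contigs`` when given, otherwise inferred
    as the rightmost exon end per contig.
    """
    _prescan_gtf(path, feature_filter)

    tmp_name = None
    src = str(path)
    try:
        if src.endswith(".gz"):
            # gffutils' line iterator is not gzip-transparent for GTF dialects
            with _open_text(path) as fh, tempfile.NamedTemporaryFile(
                "wt", suffix=".gtf", delete=False
            ) as tmp:
                tmp.write(fh.read())
                tmp_name = src = tmp.name
        db = gffutils.create_db(
            src,
            ":memory:",
            force=True,
            keep_order=False,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    finally:
        if tmp_name is not None:
            os.unlink(tmp_name)

    raw: dict[str, dict] = {}
    for ftype in feature_filter:
        for feat in db.all_features(featuretype=ftype):
            gid = feat.attributes["gene_id"][0]
            rec = raw.setdefault(
                gid, {"contig": feat.seqid, "strand": feat.strand, "exons": []}
            )
            if rec["contig"] != feat.seqid or rec["strand"] != feat.strand:
                raise AnnotationError(
                    f"gene {gid}: features on multiple contigs or strands"
                )
            # GTF is 1-based inclusive; convert to 0-based half-open
            rec["exons"].append((feat.start - 1, feat.end))

    genes = []
    inferred: dict[str, int] = {}
    for gid in sorted(raw):
        rec = raw[gid]
        exons = tuple(merge_exons(rec["exons"]))
        g = GeneModel(
            gene_id=gid,
            contig=rec["contig"],
            strand=rec["strand"],
            start=exons[0][0],
            end=exons[-1][1],
            merged_exons=exons,
        )
        genes.append(g)
        inferred[g.contig] = max(inferred.get(g.contig, 0), g.end)
    return GenomeAnnotation(genes=tuple(genes), contigs=dict(contigs or inferred))


def build_junctions(ann: GenomeAnnotation) -> list[JunctionPair]:
    """One :class:`JunctionPair` per intron; single-exon genes contribute none."""
    pairs: list[JunctionPair] = []
    for g in ann.genes:
        # genomic-left boundary touches the upstream exon's genomic 3' end on
        # '+', its 5' end on '-'
        left_label = "3prime" if g.strand == "+" else "5prime"
        right_label = "5prime" if g.strand == "+" else "3prime"
        for idx, (i_start, i_end) in enumerate(g.introns):
            common = dict(gene_id=g.gene_id, contig=g.contig, strand=g.strand)
            ee = Junction(
                kind=EE, base_a=i_start - 1, base_b=i_end,
                exon_end_label=left_label, **common,
            )
            donor = Junction(
                kind=IE, base_a=i_start - 1, base_b=i_start,
                exon_end_label=left_label, **common,
            )
            acceptor = Junction(
                kind=IE, base_a=i_end - 1, base_b=i_end,
                exon_end_label=right_label, **common,
            )
            pairs.append(JunctionPair(ee=ee, ie_donor=donor,
                                      ie_acceptor=acceptor, intron_index=idx))
    return pairs


def pair_and_purify(
    pairs: list[JunctionPair], ann: GenomeAnnotation
) -> list[JunctionPair]:
    """Drop all junctions of genes whose span overlaps another gene's span on
    the same strand (embedded/overlapping genes); opposite-strand overlap is
    retained because coverage counting is strand-aware.
    """
    bad: set[str] = set()
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in ann.genes:
        by_key.setdefault((g.contig, g.strand), []).append(g)
    for genes in by_key.values():
        genes = sorted(genes, key=lambda g: g.start)
        for i, g in enumerate(genes):
            for h in genes[i + 1:]:
                if h.start >= g.end:
                    break
                bad.add(g.gene_id)
                bad.add(h.gene_id)
    return [p for p in pairs if p.gene_id not in bad]


# ---------------------------------------------------------------------------
# junction TSV round-trip

_TSV_HEADER = "#contig\tbase_a\tbase_b\tkind\tside\tgene_id\tstrand\tintron_index"


def _iter_rows(pairs: Iterable[JunctionPair]) -> Iterator[tuple]:
    for p in pairs:
        for side, j in (("ee", p.ee), ("donor", p.ie_donor), ("acceptor", p.ie_acceptor)):
            yield (j.contig, j.base_a, j.base_b, j.kind, side,
                   j.gene_id, j.strand, p.intron_index)


def write_junctions_tsv(pairs: Iterable[JunctionPair], path: str) -> None:
    """Write the junction set as a BED-like TSV (0-based, '#' header)."""
    with open(path, "wt") as fh:
        fh.write(_TSV_HEADER + "\n")
        for row in _iter_rows(pairs):
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_junctions_tsv(path: str) -> list[JunctionPair]:
    """Inverse of :func:`write_junctions_tsv`."""
    by_pair: dict[tuple[str, int], dict] = {}
    meta: dict[tuple[str, int], tuple] = {}
    with open(path, "rt") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            contig, a, b, kind, side, gid, strand, idx = line.rstrip("\n").split("\t")
            key = (gid, int(idx))
            meta[key] = (contig, strand)
            by_pair.setdefault(key, {})[side] = (kind, int(a), int(b))
    pairs = []
    for key in by_pair:  # insertion order == file order, so round-trips are exact
        gid, idx = key
        contig, strand = meta[key]
        parts = by_pair[key]
        if set(parts) != {"ee", "donor", "acceptor"}:
            raise AnnotationError(
                f"junction TSV: incomplete pair for gene {gid} intron {idx}"
            )

        def _mk(side: str, label: str) -> Junction:
            kind, a, b = parts[side]
            return Junction(kind=kind, gene_id=gid, contig=contig, strand=strand,
                            base_a=a, base_b=b, exon_end_label=label)

        left = "3prime" if strand == "+" else "5prime"
        right = "5prime" if strand == "+" else "3prime"
        pairs.append(JunctionPair(
            ee=_mk("ee", left), ie_donor=_mk("donor", left),
            ie_acceptor=_mk("acceptor", right), intron_index=idx,
        ))
    return pairs
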