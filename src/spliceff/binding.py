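"""SATB1 binding propensity and its relation to splicing deregulation.

The binding propensity of a gene is the sum of fold-change enrichments (FE,
the MACS2 summit enrichment over a local-lambda Poisson background) of all
peaks overlapping the gene span by at least one base, normalised to 1 kbp of
gene length:

    propensity = sum(FE of overlapping peaks) * 1000 / gene_span_bp

Peaks are unstranded, so the overlap test is strand-blind.  Note the score is
deliberately not additive under peak fragmentation: splitting one peak of FE
f into two peaks each reported with FE f doubles the summed enrichment.

The association between binding and splicing deregulation is summarised by
Spearman rank correlation of propensity against the splicing-efficiency
delta (both signed and absolute), over genes passing the coverage filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation import GenomeAnnotation

__all__ = [
    "Peak",
    "read_narrowpeak",
    "gene_binding_propensity",
    "correlate_binding_splicing",
]

_NARROWPEAK_COLUMNS = (
    "contig", "start", "end", "name", "score",
    "strand", "fold_enrichment", "pvalue", "qvalue", "summit_offset",
)


@dataclass(frozen=True)
class Peak:
    """One ENCODE narrowPeak record (0-based half-open interval)."""

    contig: str
    start: int
    end: int
    name: str
    score: int
    fold_enrichment: float
    summit_offset: int  # bp from start; -1 in the file means undefined

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"peak {self.name}: empty interval")
        if self.fold_enrichment <= 0:
            raise ValueError(f"peak {self.name}: fold_enrichment must be > 0")
        if not (0 <= self.summit_offset < self.end - self.start):
            raise ValueError(f"peak {self.name}: summit outside interval")

    @property
    def summit(self) -> int:
        return self.start + self.summit_offset


def read_narrowpeak(path: str) -> list[Peak]:
    """Parse a 10-column MACS2 narrowPeak file.

    Column 7 is the fold enrichment, column 10 the summit offset; a summit of
    -1 (undefined) is replaced by the interval midpoint.  An empty file
    yields an empty list.
    """
    peaks: list[Peak] = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 10:
                raise ValueError(
                    f"{path}: line {lineno}: expected 10 narrowPeak columns, "
                    f"got {len(fields)}"
                )
            rec = dict(zip(_NARROWPEAK_COLUMNS, fields))
            start, end = int(rec["start"]), int(rec["end"])
            summit = int(rec["summit_offset"])
            if summit == -1:
                summit = (end - start) // 2
            peaks.append(Peak(
                contig=rec["contig"], start=start, end=end, name=rec["name"],
                score=int(rec["score"]),
                fold_enrichment=float(rec["fold_enrichment"]),
                summit_offset=summit,
            ))
    return peaks


def gene_binding_propensity(
    peaks: list[Peak], ann: GenomeAnnotation
) -> pd.DataFrame:
    """Per-gene peak count, FE sum and length-normalised propensity.

    A peak contributes its full fold enrichment to every gene whose span it
    overlaps by >= 1 bp, regardless of strand.  Genes without peaks score 0.
    """
    trees: dict[str, IntervalTree] = {}
    for i, p in enumerate(peaks):
        trees.setdefault(p.contig, IntervalTree())[p.start:p.end] = i
    rows = []
    for g in ann.genes:
        hits = trees[g.contig].overlap(g.start, g.end) if g.contig in trees else ()
        fe_sum = float(sum(peaks[iv.data].fold_enrichment for iv in hits))
        rows.append({
            "gene_id": g.gene_id,
            "n_peaks": len(hits),
            "fe_sum": fe_sum,
            "propensity": fe_sum * 1000.0 / (g.end - g.start),
        })
    return pd.DataFrame(rows).set_index("gene_id").sort_index()


def correlate_binding_splicing(
    splice: pd.DataFrame, prop: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation of binding propensity with splicing deregulation.

    Uses genes passing the coverage filter with a defined delta; reports rho,
    two-sided p and n for both the signed delta and |delta|.  Fewer than 3
    usable genes is an error; constant propensity yields rho = NaN (degenerate
    ranks).
    """
    usable = splice[splice["pass_filter"] & splice["delta"].notna()]
    merged = usable.join(prop, how="inner")
    n = len(merged)
    if n < 3:
        raise ValueError(f"only {n} usable genes; need at least 3 to correlate")
    rows = []
    for label, y in (("delta", merged["delta"]), ("abs_delta", merged["delta"].abs())):
        if merged["propensity"].nunique() <= 1 or y.nunique() <= 1:
            import warnings
            warnings.warn(f"degenerate ranks for {label}; rho undefined")
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(merged["propensity"], y)
        rows.append({"measure": label, "rho": rho, "pvalue": p, "n": n})
    return pd.DataFrame(rows).set_index("measure")
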