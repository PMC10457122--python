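"""Gene-level splicing efficiency from junction counts.

The splicing-efficiency statistic is the per-gene intron/exon junction
coverage ratio rho = I/E, where E sums exon-exon (EE) junction support and I
sums intron-exon (IE; donor- plus acceptor-side) support over all the gene's
junctions and all replicates of a condition.  Higher rho means more intron
read-through, i.e. *less* efficient splicing.  Deregulation between two
conditions is the difference delta = rho_test - rho_reference.

Genes whose summed reference-condition EE coverage is below 50 (all EE
junctions, all biological replicates) are flagged out; undefined ratios
(E = 0) propagate as NA — no pseudocounts.

Under the simulation model (both IE sides counted, uniform fragment
sampling), a gene with molar intron-retention fraction r has expected
rho = 2r/(1-r), inverted by :func:`estimate_retention`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coverage import JunctionCounts

__all__ = [
    "gene_aggregate",
    "filter_low_coverage",
    "splicing_ratio_and_delta",
    "splice_table",
    "per_replicate_ratios",
    "cassette_psi",
    "estimate_retention",
]


def _condition_sums(jc: JunctionCounts, condition: str) -> pd.DataFrame:
    """Per-gene E, I and per-side I subtotals for one condition (replicates summed)."""
    cols = jc.for_condition(condition)
    if not cols:
        raise ValueError(f"no samples with condition {condition!r}")
    per_junction = jc.counts[cols].sum(axis=1)
    by = per_junction.groupby(level=["gene_id", "side"]).sum().unstack("side", fill_value=0)
    for side in ("ee", "donor", "acceptor"):
        if side not in by:
            by[side] = 0
    return pd.DataFrame({
        "E": by["ee"],
        "I": by["donor"] + by["acceptor"],
        "I_donor": by["donor"],
        "I_acceptor": by["acceptor"],
    })


def gene_aggregate(
    jc: JunctionCounts,
    reference: str = "WT",
    test: str = "cKO",
) -> pd.DataFrame:
    """Sum junction counts to the gene level for both conditions.

    Columns follow the reference/test roles: ``E_wt``/``I_wt`` for the
    reference condition and ``E_ko``/``I_ko`` for the test condition,
    whatever the actual labels are, plus per-side I subtotals.
    """
    ref = _condition_sums(jc, reference)
    tst = _condition_sums(jc, test)
    table = pd.DataFrame({
        "I_wt": ref["I"], "E_wt": ref["E"],
        "I_ko": tst["I"], "E_ko": tst["E"],
        "I_wt_donor": ref["I_donor"], "I_wt_acceptor": ref["I_acceptor"],
        "I_ko_donor": tst["I_donor"], "I_ko_acceptor": tst["I_acceptor"],
    })
    table.index.name = "gene_id"
    return table.sort_index()


def splicing_ratio_and_delta(table: pd.DataFrame) -> pd.DataFrame:
    """Add ratio_wt, ratio_ko and delta columns; E = 0 yields NA, never inf."""
    out = table.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio_wt"] = np.where(out["E_wt"] > 0, out["I_wt"] / out["E_wt"], np.nan)
        out["ratio_ko"] = np.where(out["E_ko"] > 0, out["I_ko"] / out["E_ko"], np.nan)
    out["delta"] = out["ratio_ko"] - out["ratio_wt"]
    return out


def filter_low_coverage(table: pd.DataFrame, threshold: int = 50) -> pd.DataFrame:
    """Flag genes with summed reference EE coverage below ``threshold``.

    Coverage exactly at the threshold is retained ("lower than" is strict).
    Flagged rows are kept in the table with ``pass_filter = False``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = table.copy()
    out["pass_filter"] = out["E_wt"] >= threshold
    return out


def splice_table(
    jc: JunctionCounts,
    reference: str = "WT",
    test: str = "cKO",
    wt_exon_min: int = 50,
) -> pd.DataFrame:
    """Aggregate, compute ratios/delta, and apply the coverage filter."""
    t = gene_aggregate(jc, reference=reference, test=test)
    t = splicing_ratio_and_delta(t)
    return filter_low_coverage(t, threshold=wt_exon_min)


def per_replicate_ratios(jc: JunctionCounts) -> pd.DataFrame:
    """Per-gene, per-sample I/E ratios for dispersion diagnostics."""
    by = jc.counts.groupby(level=["gene_id", "side"]).sum()
    rows = {}
    for sample_id in jc.sample_ids():
        s = by[sample_id].unstack("side", fill_value=0)
        e = s.get("ee", 0)
        i = s.get("donor", 0) + s.get("acceptor", 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rows[sample_id] = np.where(e > 0, i / e, np.nan)
    out = pd.DataFrame(rows, index=by[jc.sample_ids()[0]].unstack("side").index)
    out.index.name = "gene_id"
    return out


def cassette_psi(inclusion: "np.typing.ArrayLike", exclusion: float) -> float:
    """Percent-spliced-in of a cassette exon from junction support counts.

    psi = mean(inclusion) / (mean(inclusion) + exclusion), where
    ``inclusion`` holds the EE support of the exon's two flanking junctions
    and ``exclusion`` the support of the flank-to-flank skipping junction.
    Returns NaN when the denominator is zero.
    """
    inc = np.asarray(inclusion, dtype=float)
    if inc.size < 1:
        raise ValueError("at least one inclusion junction count required")
    if (inc < 0).any() or exclusion < 0:
        raise ValueError("junction counts must be non-negative")
    m = inc.mean()
    denom = m + exclusion
    return float(m / denom) if denom > 0 else float("nan")


def estimate_retention(ratio: "np.typing.ArrayLike") -> np.ndarray | float:
    """Invert the expected intron/exon ratio: r_hat = rho / (2 + rho).

    Valid when both IE sides are counted and coverage is uniform, where a
    gene with retention fraction r has expected rho = 2r/(1-r).
    """
    rho = np.asarray(ratio, dtype=float)
    out = rho / (2.0 + rho)
    return float(out) if out.ndim == 0 else out
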