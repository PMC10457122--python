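"""End-to-end orchestration: annotation -> counting -> efficiency ->
propensity -> correlation, with a run manifest.

Outputs are written atomically (to a temporary name in the output directory,
then renamed), so an aborted run leaves no truncated tables.  The manifest
records the configuration, input checksums and package version; re-running
on identical inputs produces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .annotation import (
    build_junctions, pair_and_purify, parse_annotation, write_junctions_tsv,
)
from .binding import correlate_binding_splicing, gene_binding_propensity, read_narrowpeak
from .coverage import CoverageConfig, count_samples, read_sample_sheet, write_counts_tsv
from .efficiency import per_replicate_ratios, splice_table

log = logging.getLogger("spliceff")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``reference_condition`` / ``test_condition`` assign the WT/cKO roles to
    the sample sheet's condition labels; ``wt_exon_min`` is the minimum
    summed reference EE coverage (default 50).
    """

    gtf: str
    sample_sheet: str
    outdir: str
    peaks: str | None = None
    coverage: CoverageConfig = field(default_factory=CoverageConfig)
    reference_condition: str = "WT"
    test_condition: str = "cKO"
    wt_exon_min: int = 50
    log_level: str = "INFO"

    def validate(self) -> None:
        for label, path in (("gtf", self.gtf), ("sample_sheet", self.sample_sheet),
                            ("peaks", self.peaks)):
            if path is not None and not os.path.exists(path):
                raise PipelineError(f"config: {label} path does not exist: {path}")


def _run_stage(name: str, fn):
    try:
        return fn()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name}: {exc}") from exc


def _atomic_write_df(df: pd.DataFrame, path: str, **to_csv_kw) -> None:
    tmp = path + ".tmp"
    df.to_csv(tmp, sep="\t", **to_csv_kw)
    os.replace(tmp, path)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Run every stage; returns a name -> path map of the written outputs.

    Any stage error is re-raised as :class:`PipelineError` naming the stage.
    """
    logging.basicConfig(level=cfg.log_level)
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    out: dict[str, str] = {}

    def stage_junctions():
        ann = parse_annotation(cfg.gtf)
        built = build_junctions(ann)
        kept = pair_and_purify(built, ann)
        path = os.path.join(cfg.outdir, "junctions.tsv")
        write_junctions_tsv(kept, path + ".tmp")
        os.replace(path + ".tmp", path)
        out["junctions"] = path
        log.info("junctions: %d genes in, %d junction pairs kept (%d built)",
                 len(ann.genes), len(kept), len(built))
        return ann, kept

    ann, kept = _run_stage("junctions", stage_junctions)

    def stage_count():
        samples = read_sample_sheet(cfg.sample_sheet)
        known = {cfg.reference_condition, cfg.test_condition}
        for sid, row in samples.iterrows():
            if row["condition"] not in known:
                raise PipelineError(
                    f"stage count: sample sheet row {sid!r} has unknown "
                    f"condition {row['condition']!r} (expected one of {sorted(known)})"
                )
        jc = count_samples(samples, kept, cfg.coverage)
        path = os.path.join(cfg.outdir, "junction_counts.tsv")
        write_counts_tsv(jc, kept, path + ".tmp")
        os.replace(path + ".tmp", path)
        out["counts"] = path
        log.info("count: %d samples x %d junctions",
                 len(samples), len(jc.counts))
        return jc

    jc = _run_stage("count", stage_count)

    def stage_efficiency():
        table = splice_table(
            jc, reference=cfg.reference_condition, test=cfg.test_condition,
            wt_exon_min=cfg.wt_exon_min,
        )
        path = os.path.join(cfg.outdir, "splicing_efficiency.tsv")
        _atomic_write_df(table, path)
        out["efficiency"] = path
        path = os.path.join(cfg.outdir, "per_replicate_ratios.tsv")
        _atomic_write_df(per_replicate_ratios(jc), path)
        out["per_replicate_ratios"] = path
        log.info("efficiency: %d genes, %d pass the coverage filter",
                 len(table), int(table["pass_filter"].sum()))
        return table

    table = _run_stage("efficiency", stage_efficiency)

    if cfg.peaks is not None:
        def stage_propensity():
            peaks = read_narrowpeak(cfg.peaks)
            p = gene_binding_propensity(peaks, ann)
            path = os.path.join(cfg.outdir, "binding_propensity.tsv")
            _atomic_write_df(p, path)
            out["propensity"] = path
            log.info("propensity: %d peaks over %d genes", len(peaks), len(p))
            return p

        prop = _run_stage("propensity", stage_propensity)

        def stage_correlation():
            report = correlate_binding_splicing(table, prop)
            path = os.path.join(cfg.outdir, "binding_correlation.tsv")
            _atomic_write_df(report, path)
            out["correlation"] = path
            log.info("correlation: rho=%.3f (|delta|), p=%.3g, n=%d",
                     report.loc["abs_delta", "rho"],
                     report.loc["abs_delta", "pvalue"],
                     int(report.loc["abs_delta", "n"]))

        _run_stage("correlation", stage_correlation)

    def stage_manifest():
        cfg_dict = dataclasses.asdict(cfg)
        payload = {
            "tool": "spliceff",
            "version": __version__,
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()
            ).hexdigest(),
            "inputs": {
                p: _checksum(p)
                for p in [cfg.gtf, cfg.sample_sheet, cfg.peaks]
                if p is not None
            },
            "outputs": dict(out),
        }
        path = os.path.join(cfg.outdir, "run_manifest.json")
        with open(path + ".tmp", "wt") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(path + ".tmp", path)
        out["manifest"] = path

    _run_stage("manifest", stage_manifest)
    return out
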