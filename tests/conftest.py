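"""Shared simulated studies, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import spliceff as sf


@pytest.fixture(scope="session")
def oracle_study(tmp_path_factory):
    """Small study (<10^4 reads) with per-read truth labels and peaks."""
    outdir = tmp_path_factory.mktemp("oracle")
    return sf.oracle_scenario(11, str(outdir))


@pytest.fixture(scope="session")
def oracle_model(oracle_study):
    """Parsed annotation and purified junction pairs of the oracle study."""
    ann = sf.parse_annotation(oracle_study.gtf_path)
    pairs = sf.pair_and_purify(sf.build_junctions(ann), ann)
    return ann, pairs


@pytest.fixture(scope="session")
def oracle_counts(oracle_study, oracle_model):
    _, pairs = oracle_model
    return sf.count_samples(oracle_study.samples, pairs)


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """The standard recovery experiment: 20 genes over the retention ladder
    (0, 0.1, 0.25, 0.5, 0.8), ~5,000 informative mates per gene."""
    outdir = tmp_path_factory.mktemp("default")
    return sf.default_scenario(1, str(outdir))


@pytest.fixture(scope="session")
def default_splice_table(default_study):
    ann = sf.parse_annotation(default_study.gtf_path)
    pairs = sf.pair_and_purify(sf.build_junctions(ann), ann)
    jc = sf.count_samples(default_study.samples, pairs)
    return sf.splice_table(jc, reference="WT", test="WT")


@pytest.fixture(scope="session")
def two_condition_study(tmp_path_factory):
    """Small WT/cKO study with peaks, for pipeline and delta tests."""
    outdir = tmp_path_factory.mktemp("twocond")
    cfg = sf.SimConfig(seed=5, n_genes=6, target_informative_per_gene=200,
                       replicates=2)
    genes, _ = sf.make_toy_annotation(cfg, str(outdir / "peek.gtf"))
    wt = {g.gene_id: 0.1 for g in genes}
    ko = {g.gene_id: 0.4 for g in genes}
    return sf.simulate_study(cfg, str(outdir), conditions={"WT": wt, "cKO": ko},
                             with_peaks=True)


@pytest.fixture(scope="session")
def cassette_bam(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cassette")
    bam = str(outdir / "cassette.bam")
    truth = sf.simulate_cassette_reads(7, bam, inclusion_rate=0.7,
                                      n_fragments=2000)
    return bam, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
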