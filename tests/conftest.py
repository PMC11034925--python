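import logging

import numpy as np
import pytest

from cnekit.pipeline import Pipeline, PipelineConfig
from cnekit.simulate import SimConfig

logging.getLogger("cnekit").setLevel(logging.ERROR)


def reduced_config(seed: int) -> PipelineConfig:
    """A small cohort (8 species, ~0.4 Mb root genome) for multi-seed checks."""
    sim = SimConfig(
        seed=seed,
        genome_length=400_000,
        n_genes=24,
        n_cne_vertebrate=16,
        n_cne_neopterygian=18,
        n_cne_3r=28,
        dev_genes_per_chrom=3,
        novel_dev_per_chrom=2,
        cluster_span=6_000,
        n_paralog_pairs_root=2,
    )
    cfg = PipelineConfig(simulate=sim)
    cfg.assoc.n_bootstrap = 2_000
    return cfg


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default cohort, shared across tests."""
    out = tmp_path_factory.mktemp("default_run")
    pl = Pipeline(PipelineConfig(), out_dir=out)
    res = pl.run()
    return pl, res


@pytest.fixture(scope="session")
def reduced_runs():
    """Reduced-cohort pipeline results over several seeds (shared)."""
    results = {}
    for seed in (11, 12, 13, 14):
        results[seed] = Pipeline(reduced_config(seed)).run()
    return results


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
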