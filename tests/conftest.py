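import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale planted cohort shared by the end-to-end tests."""
    from srnavar.simulate import planted_config
    cfg, catalogue = planted_config(
        seed=11, n_samples=24, n_mirna=12, n_snorna=6, n_other=4,
        n_pseudogene=3, n_unannotated=4, genome_length=260_000,
        read_depth_mean=2000.0, n_null_snps=10)
    return cfg, catalogue


@pytest.fixture(scope="session")
def quant(small_cfg):
    """One full quantification run (dual-matcher consensus) reused across
    the end-to-end assertions."""
    from srnavar import pipeline
    cfg, catalogue = small_cfg
    return pipeline.run_quantification(cfg, catalogue)


@pytest.fixture(scope="session")
def resolved_per_sample(quant):
    """Per-sample counts of reads resolved to a non-contaminant stratum."""
    from collections import Counter
    per_sample = Counter()
    for rid, (status, _w, _k) in quant.resolution.items():
        if status not in ("CONTAMINANT", "UNMAPPED"):
            per_sample[quant.read_sample[rid]] += 1
    return per_sample


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
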