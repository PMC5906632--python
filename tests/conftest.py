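import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from h33course.genome_io import GeneCatalog, GeneModel, SampleSheet
from h33course.synthetic import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def sheet7() -> SampleSheet:
    return SampleSheet.reprogramming_7pt()


@pytest.fixture(scope="session")
def succ_labels(sheet7) -> list:
    return sheet7.successful_route("chip_ip")


@pytest.fixture(scope="session")
def toy_catalog() -> GeneCatalog:
    return GeneCatalog(
        [
            GeneModel("GeneA", "chr1", 10_000, 20_000, "+"),
            GeneModel("GeneB", "chr1", 30_000, 40_000, "-"),
            GeneModel("GeneC", "chr2", 5_000, 9_000, "+"),
        ]
    )


@pytest.fixture(scope="session")
def clean_bundle():
    """Zero-noise synthetic course: every planted label must be recoverable."""
    cfg = SimulationConfig(
        seed=11, n_genes=300, fpkm_log_sd=0.0, count_dispersion=0.0, presence_flip=0.0
    )
    return simulate_bundle(cfg)


@pytest.fixture(scope="session")
def onset_oracle():
    """Literal restatement of the D-onwards rule, independent of the
    implementation: used to check classify_onset over all boolean patterns."""

    def oracle(pattern):
        if pattern[0]:
            return ("constitutive", None)
        if not any(pattern):
            return ("never", None)
        for t in range(1, len(pattern)):
            if not any(pattern[:t]) and all(pattern[t:]):
                return ("onset", t)
        return ("unsustained", None)

    return oracle
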