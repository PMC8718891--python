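import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from aadrisk import CohortConfig, aggregate, generate_cohort
from aadrisk.tables import CountTable

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_study():
    """One cohort from the paper-calibrated default configuration."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def family_profile(default_study):
    return aggregate(default_study.count_table, "family")


@pytest.fixture(scope="session")
def baseline_config():
    """Default study conditions restricted to the baseline day (for
    simulations that only consume day-0 data)."""
    return CohortConfig.from_dict({**CohortConfig().to_dict(), "days": (0,)})


@pytest.fixture
def toy_table():
    """Hand-built 5-feature, 3-sample count table with a missing genus."""
    counts = pd.DataFrame(
        {
            "s1": [3, 7, 0, 2, 5],
            "s2": [2, 0, 3, 0, 5],
            "s3": [1, 1, 1, 1, 1],
        },
        index=["f1", "f2", "f3", "f4", "f5"],
    )
    lineages = pd.Series(
        {
            "f1": "d__Bacteria;p__Firmicutes;c__Clostridia;o__Oscillospirales;"
                  "f__Ruminococcaceae;g__Faecalibacterium;s__",
            "f2": "d__Bacteria;p__Firmicutes;c__Clostridia;o__Oscillospirales;"
                  "f__Ruminococcaceae;g__Subdoligranulum;s__",
            "f3": "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;"
                  "o__Enterobacterales;f__Enterobacteriaceae;g__Escherichia-Shigella;s__",
            "f4": "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;"
                  "f__Bacteroidaceae;g__;s__",
            "f5": "Bacteria;Firmicutes;Clostridia;Lachnospirales;"
                  "Lachnospiraceae;Blautia",  # bare labels, short lineage
        }
    )
    metadata = pd.DataFrame(
        {
            "subject_id": ["A", "A", "B"],
            "day": [0, 2, 0],
            "group": ["AAD", "AAD", "non-AAD"],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return CountTable(counts, lineages, metadata)
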