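import numpy as np
import pandas as pd
import pytest

from rnamonitor import CountMatrix
from rnamonitor.config import default_cohort_config
from rnamonitor.simulate import CohortDesign, sample_signature, simulate_counts

ALPHA_GRID = [("a000", 0.0), ("a025", 0.25), ("a050", 0.5), ("a075", 0.75), ("a100", 1.0)]


def make_meta(sample_ids, groups, times=None, phases=None):
    return pd.DataFrame(
        {
            "group": groups,
            "time_months": times if times is not None else [0.0] * len(sample_ids),
            "phase": phases if phases is not None else ["pre"] * len(sample_ids),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


@pytest.fixture
def toy_counts():
    """The fixed 5-gene x 4-sample filter example."""
    counts = pd.DataFrame(
        {
            "s1": [0, 12, 1, 11, 0],
            "s2": [0, 15, 2, 11, 100],
            "s3": [0, 20, 3, 11, 100],
            "s4": [5, 11, 0, 9, 100],
        },
        index=["g1", "g2", "g3", "g4", "g5"],
    )
    meta = make_meta(list(counts.columns), ["baseline", "baseline", "control", "control"])
    return CountMatrix(counts, meta)


@pytest.fixture
def small_design():
    """A small, fast cohort design with the default group structure."""
    return CohortDesign(
        n_genes=300,
        n_baseline=3,
        n_control=4,
        treated_alphas=list(ALPHA_GRID),
        library_size_mean=300_000.0,
        dispersion=0.05,
        seed=11,
    )


@pytest.fixture
def small_cohort(small_design):
    sig = sample_signature(300, n_up=40, n_down=30, effect_low=1.5,
                           effect_high=3.0, seed=11)
    return simulate_counts(small_design, sig)


@pytest.fixture
def default_config():
    return default_cohort_config()
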