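import warnings

import numpy as np
import pytest

from deepsoma.calls import VariantCall
from deepsoma.simulate import CohortCloneSpec, make_panel, simulate_cohort

# the spectrum-calibration fallback warning is expected in stress conditions
warnings.filterwarnings("ignore", message="no alpha in the grid matched")


@pytest.fixture(scope="session")
def small_panel():
    return make_panel(12, 1500, seed=2)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    """A small default-condition cohort shared by read-only tests."""
    return simulate_cohort(
        small_panel, 2, 2, depth_range=(2000.0, 2600.0), seed=17
    )


@pytest.fixture(scope="session")
def noise_only_cohort(small_panel):
    """Same shape but with a vanishing clone burden (background noise only)."""
    return simulate_cohort(
        small_panel,
        1,
        1,
        depth_range=(2000.0, 2400.0),
        clone_spec=CohortCloneSpec(burden_slope=1e-9),
        seed=23,
    )


def make_call(**kw) -> VariantCall:
    """A plausible passing SNV call; keyword overrides for failure cases."""
    defaults = dict(
        subject_id="S1",
        chrom="chr1",
        pos=500,
        ref="C",
        alt="T",
        depth=2000,
        alt_count=20,
        alt_fwd=10,
        alt_rev=10,
        ref_fwd=990,
        ref_rev=990,
        gene="GENE0001",
        consequence="nonsynonymous_SNV",
        cadd=25.0,
        polyphen="D",
        pop_af=0.0,
        context="ACG",
    )
    defaults.update(kw)
    return VariantCall(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
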