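import warnings

import numpy as np
import pytest

from fetalkin import synthetic
from fetalkin.synthetic import DesignConfig, EffectSpec

# statsmodels REML emits convergence chatter on degenerate variance
# components; keep test output readable
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def small_designs():
    """A reproducible 40-subject design (roughly 56 scans)."""
    return synthetic.generate_design(40, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_flat_effects(**kwargs) -> EffectSpec:
    """EffectSpec with zero baseline/effects unless overridden."""
    kwargs.setdefault("baseline_log_amt", 0.0)
    kwargs.setdefault("sd_subject", 0.0)
    kwargs.setdefault("sd_scan_within_position", 0.0)
    kwargs.setdefault("sd_residual", 0.0)
    return EffectSpec(**kwargs)
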