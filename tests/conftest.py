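import numpy as np
import pytest

from afibcea import accumulate, load_parameters, run_all_strategies


@pytest.fixture(scope="session")
def ps():
    """Packaged base-case parameter set (read-only; copy before mutating)."""
    return load_parameters()


@pytest.fixture(scope="session")
def traces(ps):
    """Base-case cohort traces for all four strategies."""
    return run_all_strategies(ps)


@pytest.fixture(scope="session")
def results(ps, traces):
    return {s: accumulate(tr, ps) for s, tr in traces.items()}


@pytest.fixture()
def quiet_ps(ps):
    """Copy with every event rate and background mortality zeroed."""
    z = ps.copy_deep()
    ev = z.events
    ev.stroke_rate_in_range = 0.0
    ev.bleed_rate_in_range = 0.0
    ev.stroke_rate_aspirin = 0.0
    for f in ("mi_rate_warfarin", "mi_rate_aspirin", "mi_rate_d150", "mi_rate_d110"):
        setattr(ev, f, 0.0)
    z.config.mortality_multiplier = 0.0
    z.ranges = {}
    return z
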