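import dataclasses

import numpy as np
import pytest

from osteoquant import rpi, synthetic


@pytest.fixture(scope="session")
def default_trace():
    """Noiseless 10-cycle trace at the default (normal-group) settings."""
    return synthetic.generate_rpi_trace(synthetic.RPITraceParams())


@pytest.fixture(scope="session")
def default_summary(default_trace):
    trace, _truth = default_trace
    return rpi.analyze_trace(trace)


@pytest.fixture(scope="session")
def small_study():
    """A reduced two-group study (full AFM grid design, one unit elsewhere)."""
    return synthetic.generate_group_study(
        n_per_group=2,
        seed=7,
        n_rpi_sites=1,
        n_raman_sites=1,
        n_fibril_fields=1,
        n_fibrils_per_field=4,
    )


def summary_fields():
    return [f.name for f in dataclasses.fields(rpi.RPISummary)]


def rel_err(got, want):
    return abs(got - want) / abs(want)


def ks_oracle(a, b):
    """Exhaustive ECDF-difference oracle: sup over every sample point."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    best = 0.0
    for x in np.concatenate([a, b]):
        d = abs(
            np.searchsorted(a, x, side="right") / a.size
            - np.searchsorted(b, x, side="right") / b.size
        )
        best = max(best, d)
    return best
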