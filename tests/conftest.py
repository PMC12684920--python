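"""Shared fixtures; the expensive dynamic cell-file runs are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

import rootga as rg


@pytest.fixture(scope="session")
def params():
    return rg.default_params()


@pytest.fixture(scope="session")
def template(params):
    return rg.build_steady_template(params.growth, params.zones, params.birth_length_range)


@pytest.fixture(scope="session")
def continuum_baseline(params):
    return rg.solve_steady(params)


@pytest.fixture(scope="session")
def discrete_baseline(params):
    """Cycling steady state of the dynamic cell file (wild type)."""
    return rg.run_to_steady_profile(params)


@pytest.fixture(scope="session")
def discrete_pplas3(params):
    """Dynamic steady state with plasmodesmatal permeability tripled."""
    from rootga.scenarios import builtin_scenarios, effective_params

    sc = builtin_scenarios()["h2o2"]
    return rg.run_to_steady_profile(effective_params(params, sc), sc, rtol=1e-6)


def rel_l2(x, a, b, x_max=None):
    """Relative L2 distance of field a from reference b on [0, x_max]."""
    m = np.ones_like(x, dtype=bool) if x_max is None else x <= x_max
    num = np.sqrt(np.trapezoid((a[m] - b[m]) ** 2, x[m]))
    den = np.sqrt(np.trapezoid(b[m] ** 2, x[m]))
    return num / den
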