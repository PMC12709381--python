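"""Shared fixtures: reference solutions, ground truths and instruments."""

import pytest

from sfbkit import electrolyte, reference, simulate


@pytest.fixture(scope="session")
def kcl_001m() -> electrolyte.SolutionSpec:
    """0.01 molal KCl in water at 298.15 K."""
    return electrolyte.aqueous(kcl_molal=0.01)


@pytest.fixture(scope="session")
def instrument() -> simulate.InstrumentSpec:
    """Default instrument: R = 10 mm, k_N = 150 N/m, 0.05 nm drive step."""
    return simulate.InstrumentSpec()


@pytest.fixture(scope="session")
def row_pro007() -> reference.ReferenceFit:
    return reference.by_composition(0.07, 0.0)


@pytest.fixture(scope="session")
def row_pro090() -> reference.ReferenceFit:
    return reference.by_composition(0.90, 0.0)


@pytest.fixture(scope="session")
def row_mixture() -> reference.ReferenceFit:
    return reference.by_composition(0.46, 0.01)
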