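"""Shared fixtures: small networks and a medium wild-type ensemble.

The session-scoped ensemble keeps the expensive integration work shared
across state-classification, phase and stability tests.
"""

from __future__ import annotations

import pytest
from hypothesis import settings as hyp_settings

from nafld_grn.ensemble import run_ensemble

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")
from nafld_grn.network import (
    INHIBITION,
    Edge,
    RegulatoryNetwork,
    literature_model,
    wildtype_network,
)


@pytest.fixture(scope="session")
def wildtype():
    return wildtype_network()


@pytest.fixture(scope="session")
def lit_model():
    return literature_model()


@pytest.fixture(scope="session")
def toggle_switch():
    """Two-gene mutual-inhibition circuit."""
    return RegulatoryNetwork(
        ("A", "B"), (Edge("A", "B", INHIBITION), Edge("B", "A", INHIBITION))
    )


@pytest.fixture(scope="session")
def isolated_node():
    return RegulatoryNetwork(("A",), ())


@pytest.fixture(scope="session")
def wt_ensemble(wildtype):
    """Medium wild-type ensemble shared by classification/stability tests."""
    return run_ensemble(wildtype, n_models=1500, n_init=100, seed=11)


@pytest.fixture(scope="session")
def wt_phases(wt_ensemble):
    from nafld_grn.states import label_states

    return label_states(wt_ensemble)
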