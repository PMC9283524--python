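"""Shared fixtures.

The staged-protocol run for the three default ligand classes is expensive
(tens of seconds), so it is computed once per session and shared by the
analysis and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import gamdpipe as gp
from gamdpipe.config import ProtocolConfig


@pytest.fixture(scope="session")
def default_profiles():
    return gp.default_profiles()


@pytest.fixture(scope="session")
def default_run(default_profiles):
    """Full default-protocol GaMD run (3 production replicas) for each
    default ligand profile, master seed 7."""
    out = {}
    for profile in default_profiles:
        model = gp.build_activation_landscape(profile)
        result = gp.run_gamd_protocol(model, ProtocolConfig(), master_seed=7,
                                      label=profile.name)
        out[profile.name] = (profile, model, result)
    return out


@pytest.fixture(scope="session")
def mixing_well_run():
    """A well-mixing double well (low barrier, modest bias) sampled with the
    default protocol: enough barrier crossings for tight free-energy
    comparisons."""
    profile = gp.LigandProfile("mixing_well", landscape_bias=-1.0,
                               barrier_height=3.0, assay_relative_max=0.5,
                               assay_ec50=1e-8, association_rate_k=1e-3)
    model = gp.build_activation_landscape(profile)
    result = gp.run_gamd_protocol(model, ProtocolConfig(), master_seed=11,
                                  label=profile.name)
    return profile, model, result


def analytic_bin_profile(model, pmf):
    """Boltzmann-quadrature reference profile on the PMF's own bins,
    anchored over the included bins."""
    from gamdpipe.config import KBT_310
    edges = pmf.bin_edges[0]
    out = np.empty(len(edges) - 1)
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        x = np.linspace(a, b, 51)
        out[i] = -KBT_310 * np.log(
            np.trapezoid(np.exp(-model.values(x) / KBT_310), x))
    out -= out[~pmf.excluded].min()
    return out
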