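"""Shared fixtures: geometry models and (expensive) simulated swallows."""

import numpy as np
import pytest

from peribracket.flow_solver import SwallowCycle, simulate_swallow
from peribracket.geometry import ApplianceSpec, DomainSpec, GeometryModel, build_domain


@pytest.fixture(scope="session")
def default_model():
    """Default 10 x 10 x 1.4 mm domain at 0.2 mm, bracket without wire."""
    return build_domain()


@pytest.fixture(scope="session")
def coarse_model():
    """Coarse variant: 1.6 mm film at 0.4 mm cells (0.4 divides all extents)."""
    return build_domain(DomainSpec(depth=1.6, cell_size=0.4))


@pytest.fixture(scope="session")
def refined_model():
    """The coarse variant's geometry at half the cell size (0.2 mm)."""
    return build_domain(DomainSpec(depth=1.6, cell_size=0.2))


@pytest.fixture(scope="session")
def gingival_result(default_model):
    """One gingival swallow over the default geometry (the workhorse run)."""
    return simulate_swallow(default_model, SwallowCycle("gingival"), n_outputs=11)


@pytest.fixture(scope="session")
def coarse_gingival_result(coarse_model):
    return simulate_swallow(coarse_model, SwallowCycle("gingival"), n_outputs=11)


@pytest.fixture(scope="session")
def refined_gingival_result(refined_model):
    return simulate_swallow(refined_model, SwallowCycle("gingival"), n_outputs=11)


def obstacle_free_model(
    length_md=10.0, length_og=10.0, depth=1.4, cell_size=0.2
) -> GeometryModel:
    """A domain with no solid at all (metrics/solver oracle geometry)."""
    dom = DomainSpec(length_md, length_og, depth, cell_size)
    return GeometryModel(
        domain=dom,
        appliance=ApplianceSpec(),
        solid_mask=np.zeros(dom.shape, dtype=bool),
        region_labels=np.zeros(dom.shape[:2], dtype=np.int8),
    )


@pytest.fixture()
def empty_model():
    return obstacle_free_model()
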