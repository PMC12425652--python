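"""Shared fixtures: one small synthetic study reused across test modules."""

import numpy as np
import pytest

import gtsdm as g


@pytest.fixture(scope="session")
def stack():
    """60x60 scene, 100 m cells, six continuous layers + 15-level categorical."""
    return g.generate_landscape(11, 60, 60, 100.0)


@pytest.fixture(scope="session")
def species(stack):
    """Strong-signal virtual species: positive env1, negative env2 effect."""
    return g.define_virtual_species(
        stack, "L", (2.0, -1.0, 0.0, 0.0, 0.0, 0.0), target_prevalence=0.3, seed=21
    )


@pytest.fixture(scope="session")
def study(stack, species):
    """Filtered occurrences, extent, background and checkerboard partition."""
    occ = g.sample_presence_records(species, stack, 400, seed=31)
    kept, _ = g.filter_occurrences(occ, stack)
    extent = g.build_study_extent(kept, stack, buffer_distance=3000.0)
    bg = g.sample_background(extent, stack, n=2000, seed=41)
    part = g.checkerboard1(kept.xy, bg.xy, stack, aggregation_factor=10)
    return {"occ": kept, "extent": extent, "bg": bg, "partition": part}


@pytest.fixture(scope="session")
def fitted(stack, study):
    """A converged LQ rm=1 fit on the shared study."""
    model = g.MaxEnt.from_points(stack, study["occ"].xy, study["bg"].xy, "LQ", rm=1.0)
    return model, model.fit()
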