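"""Shared phantom fixtures.

The PDE stages are deterministic, so the expensive solves are computed once
per session and shared across test modules.
"""

import numpy as np
import pytest

from lapthick import (
    PhantomSpec,
    make_buried_sulcus,
    make_folded_random,
    make_slab,
    make_spherical_shell,
    solve_laplace,
    solve_lengths,
    tangent_field,
    thickness_pipeline,
)


@pytest.fixture(scope="session")
def slab():
    return make_slab(PhantomSpec.slab(5.0, (1.0, 1.0, 1.0), cross_section=20))


@pytest.fixture(scope="session")
def slab_field(slab):
    return solve_laplace(slab.volume)


@pytest.fixture(scope="session")
def slab_tangent(slab, slab_field):
    return tangent_field(slab_field, slab.volume)


@pytest.fixture(scope="session")
def slab_thickness(slab, slab_tangent):
    return solve_lengths(slab_tangent, slab.volume)


@pytest.fixture(scope="session")
def shell():
    return make_spherical_shell(PhantomSpec.shell(8.0, 12.0, (0.5, 0.5, 0.5)))


@pytest.fixture(scope="session")
def shell_field(shell):
    return solve_laplace(shell.volume)


@pytest.fixture(scope="session")
def shell_tangent(shell, shell_field):
    return tangent_field(shell_field, shell.volume)


@pytest.fixture(scope="session")
def shell_thickness(shell, shell_tangent):
    return solve_lengths(shell_tangent, shell.volume)


@pytest.fixture(scope="session")
def folded():
    return make_folded_random(PhantomSpec.folded(seed=3))


@pytest.fixture(scope="session")
def sulcus_sealed():
    return make_buried_sulcus(PhantomSpec.buried_sulcus(), sealed=True)


@pytest.fixture(scope="session")
def sulcus_open():
    return make_buried_sulcus(PhantomSpec.buried_sulcus(), sealed=False)


@pytest.fixture(scope="session")
def base_map48():
    """PDE thickness map of the default cohort base geometry (48^3 slab)."""
    from lapthick.cohort import CohortSpec

    spec = CohortSpec()
    from lapthick import make_phantom

    return thickness_pipeline(make_phantom(spec.base).volume)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
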