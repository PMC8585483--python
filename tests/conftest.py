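"""Shared fixtures: synthetic scenes, rendered stacks, reconstructions.

Expensive artifacts (rendering, reconstruction, cup fixtures) are session
scoped so the acceptance tests and the unit tests share one computation.
"""

import pytest

from mptfm.elasticity import ElasticBody
from mptfm.reconstruction import reconstruct_particle
from mptfm.synthetic import (
    Imaging,
    SceneSpec,
    make_cup_fixture,
    make_deformed_sphere,
    render_stack,
)

RADIUS = 3.7  # um, reference target radius used throughout


@pytest.fixture(scope="session")
def body():
    return ElasticBody(RADIUS, 1400.0, 0.49)


@pytest.fixture(scope="session")
def sphere_spec():
    return SceneSpec(radius_um=RADIUS)


@pytest.fixture(scope="session")
def sphere_mesh(sphere_spec):
    return make_deformed_sphere(sphere_spec)


@pytest.fixture(scope="session")
def sphere_stack(sphere_mesh, sphere_spec):
    return render_stack(sphere_mesh, sphere_spec, "volume", channel="particle")


@pytest.fixture(scope="session")
def noisy_sphere_pair():
    """(spec, stack) for a sphere imaged at SNR ~ 10 (Poisson, seeded)."""
    spec = SceneSpec(radius_um=RADIUS, imaging=Imaging(photon_scale=100.0, noise_seed=3))
    mesh = make_deformed_sphere(spec)
    return spec, render_stack(mesh, spec, "volume", channel="particle")


@pytest.fixture(scope="session")
def reconstructed_sphere(sphere_stack):
    return reconstruct_particle(sphere_stack)


@pytest.fixture(scope="session")
def cup_bundle():
    """Half-engulfed cup with 10 rim teeth, band and spots (truth mesh)."""
    return make_cup_fixture(0.5, 10)


@pytest.fixture(scope="session")
def aligned_cup(cup_bundle):
    from mptfm import mapping

    b = cup_bundle
    mask = mapping.compute_contact_mask(b.mesh, b.vertex_exposed, b.vertex_actin)
    cup = mapping.align_to_axis(
        b.mesh, mask, signals={"actin": b.vertex_actin, "exposed": b.vertex_exposed}
    )
    cup.mesh.compute_vertex_fields()
    return cup
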