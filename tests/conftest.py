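"""Shared fixtures: analytic meshes and small synthetic cohorts."""

import warnings

import numpy as np
import pytest
import trimesh

from rootaxis.geometry import DegeneracyWarning, TriangleMesh
from rootaxis.synthetic import CohortSpec, ToothShapeParams, generate_cohort, generate_tooth


@pytest.fixture(autouse=True)
def _quiet_degeneracy_warnings():
    # degeneracy warnings are asserted explicitly where they matter
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegeneracyWarning)
        yield


def icosphere(radius: float = 1.0, subdivisions: int = 3) -> TriangleMesh:
    return TriangleMesh.from_trimesh(trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius))


@pytest.fixture(scope="session")
def unit_sphere() -> TriangleMesh:
    return icosphere(1.0, 4)


@pytest.fixture(scope="session")
def cube_mesh() -> TriangleMesh:
    return TriangleMesh.from_trimesh(trimesh.creation.box(extents=(1.0, 1.0, 1.0)))


@pytest.fixture(scope="session")
def straight_tooth():
    """Incisor with a perfectly straight root (truth = construction axis)."""
    return generate_tooth(11, ToothShapeParams(apical_curve_deg=0.0), seed=7)


@pytest.fixture(scope="session")
def curved_canine():
    return generate_tooth(13, seed=7)


@pytest.fixture(scope="session")
def clean_cohort():
    """Small cohort without degradation or jitter (pure-geometry truth)."""
    return generate_cohort(
        CohortSpec(
            n_subjects=3,
            teeth=(11, 21, 31, 41),
            voxel_spacing=None,
            jitter_sigma_mm=0.0,
            seed=42,
        )
    )
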