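import numpy as np
import pytest

from facesup import FaceParams, GrowthParams, apply_growth, generate_face
from facesup.transforms import RigidTransform

#: moderate acquisition pose difference used across tests
MISALIGNMENT = RigidTransform.from_axis_angle([0.3, 1.0, 0.1], 4.0, [2.0, -3.0, 1.0])


@pytest.fixture(scope="session")
def face():
    """One default synthetic face: (mesh, landmarks, landmark vertex indices)."""
    return generate_face(FaceParams())


@pytest.fixture(scope="session")
def clean_subject(face):
    """Noise-free stable-growth subject with a known misalignment."""
    mesh, lms, idx = face
    growth = GrowthParams(
        lower_face_protrusion=2.0, noise_sigma=0.0, misalignment=MISALIGNMENT, seed=1
    )
    return apply_growth(mesh, lms, growth, landmark_indices=idx, subject_id="clean")


@pytest.fixture(scope="session")
def noisy_subject(face):
    """Stable-growth subject at the default acquisition noise level."""
    mesh, lms, idx = face
    growth = GrowthParams(
        lower_face_protrusion=2.0, noise_sigma=0.05, misalignment=MISALIGNMENT, seed=7
    )
    return apply_growth(mesh, lms, growth, landmark_indices=idx, subject_id="noisy")


@pytest.fixture(scope="session")
def flat_patch():
    """An open flat square grid in the z = 0 plane (normals +z)."""
    from facesup import SurfaceMesh

    n = 21
    g = np.linspace(-10.0, 10.0, n)
    xx, yy = np.meshgrid(g, g)
    vertices = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    faces = []
    for j in range(n - 1):
        for i in range(n - 1):
            a = j * n + i
            faces.append((a, a + 1, a + n + 1))
            faces.append((a, a + n + 1, a + n))
    return SurfaceMesh(vertices, np.array(faces), mesh_id="flat")
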