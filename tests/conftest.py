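"""Shared fixtures.

Simulations are the expensive part of this suite, so acquisitions that
several tests interrogate are session-scoped: a small clean scene (no decay,
no off-resonance) for exact-recovery checks and a full-physics scene for
artifact checks.
"""

import numpy as np
import pytest

from epighost import (
    EpiProtocol,
    acquire,
    girf_preset,
    ideal_reference,
    make_phantom,
    reconstruct,
)

MATRIX = 48
FOV = 0.1
ESP = 0.8e-3


@pytest.fixture(scope="session")
def protocol():
    return EpiProtocol(
        fov_m=FOV, matrix_read=MATRIX, matrix_phase=MATRIX,
        echo_spacing_s=ESP, ramp_sampling=True,
    )


@pytest.fixture(scope="session")
def protocol_no_ramp(protocol):
    from dataclasses import replace

    return replace(protocol, ramp_sampling=False)


@pytest.fixture(scope="session")
def scene():
    """Full-physics scene: T2* decay and a well-shimmed B0 field."""
    return make_phantom(MATRIX, 4, "good", seed=1, fov_m=FOV)


@pytest.fixture(scope="session")
def clean_scene(scene):
    """Same object without decay or off-resonance (exact-recovery oracle)."""
    return scene.ideal_variant()


@pytest.fixture(scope="session")
def shim_coupled():
    return girf_preset("shim_coupled")


@pytest.fixture(scope="session")
def ideal_data(clean_scene, protocol):
    """Identity-hardware, noise-free acquisition of the clean scene."""
    return acquire(clean_scene, protocol, None, 0.0, seed=0)


@pytest.fixture(scope="session")
def corrupted_data(clean_scene, protocol, shim_coupled):
    """Coupled-resonance acquisition of the clean scene."""
    return acquire(clean_scene, protocol, shim_coupled, 0.0, seed=0)


@pytest.fixture(scope="session")
def clean_reference(clean_scene, protocol):
    return ideal_reference(clean_scene, protocol)


@pytest.fixture(scope="session")
def corrupted_recon(corrupted_data, clean_scene):
    return reconstruct(corrupted_data, clean_scene)


def nrmse(a, b):
    return np.linalg.norm(a - b) / np.linalg.norm(b)
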