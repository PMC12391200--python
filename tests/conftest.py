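"""Shared fixtures: reference materials, protocols, and cached FE runs."""

from __future__ import annotations

import numpy as np
import pytest

from discbiphasic import BiphasicMaterial, LoadProtocol

# Per-region FE material table used throughout (aggregate modulus MPa,
# permeability 1e-16 m^4/Ns, solid fraction, FCD mM)
TABLE1 = {
    "NP": dict(H_A=0.44e6, k=2.96e-16, phi_s=0.127, fcd=182.2),
    "AF": dict(H_A=0.57e6, k=2.75e-16, phi_s=0.183, fcd=135.5),
    "CEP": dict(H_A=1.19e6, k=1.93e-16, phi_s=0.307, fcd=286.7),
}

MEAN_SWELLING_KPA = {"NP": 97.86, "AF": 161.37, "CEP": 193.57}
MEAN_THICKNESS_MM = {"NP": 1.17, "AF": 1.17, "CEP": 0.92}


@pytest.fixture(scope="session")
def region_materials() -> dict:
    return {
        name: BiphasicMaterial(H_A=v["H_A"], k=v["k"], nu=0.2,
                               phi_w0=1.0 - v["phi_s"], c_F0=v["fcd"])
        for name, v in TABLE1.items()
    }


@pytest.fixture(scope="session")
def protocol() -> LoadProtocol:
    return LoadProtocol()


@pytest.fixture(scope="session")
def disc_mesh_res8():
    from discbiphasic.disc_fem import DiscGeometry, build_disc_mesh
    return build_disc_mesh(DiscGeometry(), resolution=8)


@pytest.fixture(scope="session")
def disc_biphasic_result(disc_mesh_res8, region_materials):
    """Full ramp-and-hold biphasic disc run (no swelling), reused by
    several tests and the acceptance suite."""
    from discbiphasic.disc_fem import solve_biphasic
    from discbiphasic.disc_fem.solver import CompressionProtocol
    return solve_biphasic(disc_mesh_res8, region_materials,
                          CompressionProtocol(), swelling=False)


@pytest.fixture(scope="session")
def disc_swelling_result(disc_mesh_res8, region_materials):
    from discbiphasic.disc_fem import solve_biphasic
    from discbiphasic.disc_fem.solver import CompressionProtocol
    return solve_biphasic(disc_mesh_res8, region_materials,
                          CompressionProtocol(), swelling=True)


@pytest.fixture(scope="session")
def noise_free_cohort(tmp_path_factory):
    """Small noise-free synthetic dataset + ground truth (written once)."""
    from discbiphasic.synth_experiment import generate_cohort
    root = tmp_path_factory.mktemp("cohort_nf")
    truth = generate_cohort(root, {"AF": 6, "NP": 5, "CEP": 5},
                            master_seed=11, quantize=False)
    return root, truth


def rel_err(a, b):
    return np.abs(np.asarray(a) / np.asarray(b) - 1.0)
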