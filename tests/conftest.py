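"""Shared fixtures: packaged models, toy systems, small synthetic ensembles."""

import numpy as np
import pytest

from doseuq import (
    BiokineticModel,
    Compartment,
    DecayChain,
    EmissionLine,
    Radionuclide,
    builtin_cerium_model,
    builtin_nuclides,
)
from doseuq.synthetic import SyntheticPhantomSpec, generate_phantom_library


@pytest.fixture(scope="session")
def cerium_model() -> BiokineticModel:
    return builtin_cerium_model()


@pytest.fixture(scope="session")
def ce141_chain() -> DecayChain:
    return builtin_nuclides()["Ce-141"]


@pytest.fixture(scope="session")
def ce144_chain() -> DecayChain:
    return builtin_nuclides()["Ce-144"]


def make_model(n: int, transfers: dict, intake: int = 0) -> BiokineticModel:
    """A bare n-compartment model; every compartment is its own source region."""
    comps = tuple(
        Compartment(id=i, name=f"c{i}", source_region=f"c{i}") for i in range(n)
    )
    return BiokineticModel(
        compartments=comps, transfers=transfers, intake_compartment=intake
    )


def single_line_nuclide(
    name: str = "toy",
    half_life: float = 10.0,
    rad_type: str = "electron",
    energy: float = 1.0,
    yld: float = 1.0,
) -> Radionuclide:
    return Radionuclide(
        name=name,
        half_life=half_life,
        emissions=(EmissionLine(rad_type, energy, yld),),
    )


@pytest.fixture(scope="session")
def small_phantom_spec() -> SyntheticPhantomSpec:
    """A reduced organ roster for fast S-value tests."""
    masses = {
        "liver": 1.8,
        "stomach_wall": 0.15,
        "st_content": 0.25,
        "kidneys": 0.31,
        "blood": 5.6,
        "total_body": 73.0,
    }
    return SyntheticPhantomSpec(
        n_phantoms=3,
        base_masses=masses,
        targets=("liver", "stomach_wall", "kidneys"),
        sources=("blood", "st_content", "liver"),
        mass_gsd=1.15,
        saf_gsd=1.3,
        seed=20250926,
    )


@pytest.fixture(scope="session")
def small_phantoms(small_phantom_spec):
    return generate_phantom_library(small_phantom_spec)
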