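import numpy as np
import pytest

from tetrafit.sedeq import AssociationScheme, Buffer, SchemeKind, Species
from tetrafit.simulate import NoiseModel, simulate_scans


@pytest.fixture
def pbs_cold():
    """PBS-like solvent at 4 °C."""
    return Buffer(density=1.005, temperature=277.0)


@pytest.fixture
def monomer():
    """A ~150-residue coiled-coil fragment monomer, 280-nm detection."""
    return Species("frag", monomer_mass=17000.0, vbar=0.726, epsilon=10000.0)


@pytest.fixture
def dimer_scheme(monomer):
    return AssociationScheme(SchemeKind.MONOMER_DIMER, [monomer], kd=40e-9)


@pytest.fixture
def hetero_scheme():
    receptor = Species("B2", monomer_mass=34000.0, vbar=0.726,
                       epsilon=20000.0)
    ligand = Species("A", monomer_mass=13880.0, vbar=0.731, epsilon=8000.0)
    return AssociationScheme(SchemeKind.HETERO_2_2, [receptor, ligand],
                             kd=1e-12)


@pytest.fixture
def make_single_scans(pbs_cold):
    """Factory for single-species scans at standard speeds."""

    def _make(species, conc=5e-6, rpms=(20000, 30000, 40000), sd=0.0,
              seed=0):
        scheme = AssociationScheme(SchemeKind.SINGLE, [species])
        noise = NoiseModel(sd=sd, seed=seed) if sd > 0 else None
        return simulate_scans(scheme, [conc], rpms, pbs_cold, noise=noise)

    return _make
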