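import numpy as np
import pytest

from titramd.electrostatics import ElectrostaticsConfig, MultipoleElectrostatics
from titramd.fixtures import FixtureSpec, make_fixture
from titramd.io import ForceField
from titramd.model import Atom, MultipoleSet
from titramd.system import PolarizableSystem


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def charge_system(positions, charges, cell=None):
    atoms = [Atom(i, "X", 1, p) for i, p in enumerate(positions)]
    mp = [MultipoleSet(q, np.zeros(3), np.zeros((3, 3))) for q in charges]
    return PolarizableSystem(atoms, ForceField(), cell, multipoles=mp)


def electrostatics_for(system, **kw):
    return MultipoleElectrostatics(system, ElectrostaticsConfig(**kw))


@pytest.fixture(scope="session")
def cys_fixture():
    return make_fixture(FixtureSpec("model-compound", residue="CYS"))


@pytest.fixture(scope="session")
def his_fixture():
    return make_fixture(FixtureSpec("model-compound", residue="HIS"))


@pytest.fixture(scope="session")
def dipeptide_fixture():
    return make_fixture(FixtureSpec("dipeptide-crystal-toy"))


@pytest.fixture(scope="session")
def ionic_fixture():
    return make_fixture(FixtureSpec("ionic-lattice"))
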