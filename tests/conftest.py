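import numpy as np
import pytest

from oxycav import synthdata
from oxycav.structures import AtomRecord, Proton, ProtonSet, Site, SiteGeometry


@pytest.fixture(scope="session")
def five_sites() -> SiteGeometry:
    """Five paramagnet sites, 1-3 in cavity 4 and 4-5 in cavity 3."""
    return synthdata.default_sites()


@pytest.fixture(scope="session")
def geometry():
    """A generic 50-proton synthetic geometry around the five sites."""
    return synthdata.gen_geometry(n_protons=50, seed=11)


@pytest.fixture()
def single_site() -> SiteGeometry:
    return SiteGeometry([Site(1, np.array([0.0, 0.0, 0.0]), 4)])


def make_proton(label: str, position, group: str = "amide", methyl_id=None) -> Proton:
    return Proton(label=label, residue_number=1, group=group,
                  methyl_id=methyl_id, position=np.asarray(position, dtype=float))


def make_residue_atoms(resname: str, resnum: int, names, origin=(0.0, 0.0, 0.0)):
    """Atom records for one residue: given atom names at distinct positions."""
    out = []
    for i, name in enumerate(names):
        element = "H" if name.startswith("H") else name[0]
        pos = np.asarray(origin, dtype=float) + np.array([0.3 * i, 0.1 * i, 0.0])
        out.append(AtomRecord(resnum, resname, name, element, pos))
    return out
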