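import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from halomotif.pipeline import RunConfig, build_family_bundle

FAMILY_SEED = 1


@pytest.fixture(scope="session")
def bundle():
    """Synthetic family bundle (profiles, class models, site maps, references).

    Session-scoped: the bundle is deterministic for a fixed seed and building
    the reference feature vectors costs a few seconds.
    """
    return build_family_bundle(RunConfig(seed=FAMILY_SEED))


@pytest.fixture(scope="session")
def profiles(bundle):
    return bundle.group_profiles


@pytest.fixture(scope="session")
def references(bundle):
    return bundle.references


def pdb_line(record, serial, name, altloc, resname, chain, resseq, x, y, z,
             occ=1.0, element="C"):
    """One fixed-column PDB coordinate line."""
    return (f"{record:<6}{serial:>5} {name:^4}{altloc:1}{resname:>3} {chain:1}"
            f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{10.0:6.2f}"
            f"          {element:>2}")


@pytest.fixture
def synthetic_pdb(tmp_path):
    """A small synthetic coordinate file: a Gln residue and a Trp ligand."""
    lines = [
        "HEADER    SYNTHETIC TEST STRUCTURE",
        pdb_line("ATOM", 1, "N", " ", "GLN", "A", 160, 0, 0, 0, element="N"),
        pdb_line("ATOM", 2, "CA", " ", "GLN", "A", 160, 1, 0, 0),
        pdb_line("ATOM", 3, "CG", " ", "GLN", "A", 160, 2, 0, 0),
        pdb_line("ATOM", 4, "NE2", "A", "GLN", "A", 160, 3, 4, 0, occ=0.6, element="N"),
        pdb_line("ATOM", 5, "NE2", "B", "GLN", "A", 160, 9, 9, 9, occ=0.4, element="N"),
        pdb_line("HETATM", 6, "O", " ", "TRP", "A", 500, 0, 0, 0, element="O"),
        pdb_line("HETATM", 7, "OXT", " ", "TRP", "A", 500, 6, 8, 0, element="O"),
        "END",
    ]
    path = tmp_path / "synthetic.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
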