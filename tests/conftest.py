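import numpy as np
import pytest

from epifoot.interface import ContactCriteria
from epifoot.synthetic import PlantedContact, ToyComplexSpec, make_toy_complex

# default planted-contact distances chosen so the construction yields
# exactly the planted set and nothing else
ALL_KINDS = (
    PlantedContact("hbond", 2.9),
    PlantedContact("cation_pi", 4.5),
    PlantedContact("pi_stack", 5.0),
    PlantedContact("hydrophobic", 4.0),
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.177  -5.040  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  SER A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  OG ASER A   1      12.000   7.000  -4.000  0.60  0.00           O
ATOM      4  OG BSER A   1      13.000   8.000  -3.000  0.40  0.00           O
END
"""

WATER_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.177  -5.040  1.00  0.00           C
HETATM    4  O   HOH A 101       2.000   2.000   2.000  1.00  0.00           O
HETATM    5  O   HOH A 102       4.000   4.000   4.000  1.00  0.00           O
END
"""


@pytest.fixture(scope="session")
def planted_complex():
    """Two-helix complex with one planted contact of every kind."""
    spec = ToyComplexSpec(planted_contacts=ALL_KINDS, seed=1)
    structure, truth = make_toy_complex(spec)
    return structure, truth


@pytest.fixture(scope="session")
def touching_complex():
    """Two helices close enough to bury surface (no planted devices)."""
    structure, _ = make_toy_complex(
        ToyComplexSpec(inter_chain_gap=9.0, n_residues_per_chain=15)
    )
    return structure


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def transform_structure(structure, rotation, translation):
    """Rigid-body transform of every atom (returns a new Structure)."""
    from epifoot.structure import Atom, Residue, Structure

    chains = []
    for cid, residues in structure.chains:
        new_res = []
        for r in residues:
            atoms = tuple(
                Atom(
                    a.serial,
                    a.name,
                    a.element,
                    tuple(rotation @ a.xyz + translation),
                    a.occupancy,
                    a.altloc,
                    a.is_hetero,
                )
                for a in r.atoms
            )
            new_res.append(Residue(r.chain_id, r.seq_id, r.res_name, atoms, r.insertion_code))
        chains.append((cid, new_res))
    return Structure(id=structure.id, chains=chains, metadata=dict(structure.metadata))
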