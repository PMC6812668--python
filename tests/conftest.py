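import gemmi
import numpy as np
import pytest

from rotasuite.catalog import load_catalog
from rotasuite.nerf import place_atom
from rotasuite.templates import build_template

# backbone internal coordinates shared by the synthetic chain builder
_GEO = {
    "O5'-C5'": (1.440, None, None),
    "C5'-C4'": (1.510, 111.5, None),
    "C4'-C3'": (1.524, 115.5, "gamma"),
    "C3'-O3'": (1.423, 110.6, "delta"),
    "O3'-P": (1.607, 119.7, "epsilon"),
    "P-O5'": (1.593, 104.0, "zeta"),
    "O5'-C5'n": (1.440, 120.9, "alpha"),
    "C5'-C4'n": (1.510, 111.5, "beta"),
}


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def template_aa():
    return build_template("AA")


def build_backbone_chain(sequence: str, suite_torsions, breaks=(), offset=50.0, numbering=None):
    """NeRF-construct a backbone-only RNA chain as a gemmi.Structure.

    ``suite_torsions``: one 7-tuple (d1, e1, z1, al, be, ga, d2) per
    consecutive residue pair; consecutive suites must agree on the shared
    delta.  Residues listed in ``breaks`` (1-based position in
    ``sequence``) start a new fragment translated by ``offset`` Angstrom
    (a chain break under the bonding cutoff).  ``numbering`` overrides the
    author residue numbers (e.g. to model an unobserved residue as a
    numbering gap).
    """
    n = len(sequence)
    assert len(suite_torsions) == n - 1
    for a, b in zip(suite_torsions, suite_torsions[1:]):
        if abs(a[6] - b[0]) > 1e-9:
            raise ValueError("consecutive suites disagree on the shared delta")

    residues = []  # list of dicts name->xyz
    shift = np.zeros(3)
    prev = None
    for i in range(n):
        if i + 1 in breaks:
            shift = shift + np.array([offset, 0.0, 0.0])
            prev = None
        atoms = {}
        if prev is None:
            atoms["O5'"] = np.zeros(3) + shift
            atoms["C5'"] = atoms["O5'"] + np.array([1.440, 0.0, 0.0])
            th = np.radians(111.5)
            atoms["C4'"] = atoms["C5'"] + 1.510 * np.array([-np.cos(th), np.sin(th), 0.0])
            gamma = 54.0
        else:
            e1, z1, al, be = (suite_torsions[i - 1][k] for k in (1, 2, 3, 4))
            p = place_atom(prev["C4'"], prev["C3'"], prev["O3'"], 1.607, 119.7, e1)
            o5 = place_atom(prev["C3'"], prev["O3'"], p, 1.593, 104.0, z1)
            c5 = place_atom(prev["O3'"], p, o5, 1.440, 120.9, al)
            c4 = place_atom(p, o5, c5, 1.510, 111.5, be)
            atoms.update({"P": p, "O5'": o5, "C5'": c5, "C4'": c4})
            gamma = suite_torsions[i - 1][5]
        delta = suite_torsions[i][0] if i < n - 1 else suite_torsions[i - 1][6]
        atoms["C3'"] = place_atom(atoms["O5'"], atoms["C5'"], atoms["C4'"], 1.524, 115.5, gamma)
        atoms["O3'"] = place_atom(atoms["C5'"], atoms["C4'"], atoms["C3'"], 1.423, 110.6, delta)
        residues.append(atoms)
        prev = atoms

    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")
    numbering = numbering or list(range(1, n + 1))
    for num, resname, atoms in zip(numbering, sequence, residues):
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(num, " ")
        for name, pos in atoms.items():
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.pos = gemmi.Position(*pos)
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    return st
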