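"""Idealized dinucleotide (DN) templates for conformer sampling.

One template per dinucleotide sequence (16 over {A, C, G, U}) built
programmatically from standard bond lengths and angles.  Each template is
a heavy-atom model of two nucleotides with the seven suite torsions
(delta_{i-1} ... delta_i) resolvable to atom quadruples and rotatable as
rigid subtrees.

The molecule is stored as a NeRF construction tree.  All tree bonds and
the bond angles they define are exactly conserved under torsion rotation.
The ribose ring closure (O4'-C1') is a *soft* bond: it is part of the bond
graph used for clash-exclusion topology but not of the rigid tree, because
a rigid rotation about C4'-C3' (the delta torsion) is geometrically
incompatible with a closed five-ring.  Base rings are placed as rigid
planar bodies and never deform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .catalog import TORSION_NAMES
from .nerf import place_atom

__all__ = ["DNTemplate", "TemplateDefinitionError", "build_template", "enumerate_templates", "BASES"]

BASES = ("A", "C", "G", "U")

# standard heavy-atom bond lengths (A) and angles (deg) for the RNA backbone
_R = {
    ("O5'", "C5'"): 1.440, ("C5'", "C4'"): 1.510, ("C4'", "C3'"): 1.524,
    ("C4'", "O4'"): 1.453, ("C3'", "O3'"): 1.423, ("C3'", "C2'"): 1.525,
    ("C2'", "C1'"): 1.528, ("C2'", "O2'"): 1.413, ("C1'", "N"): 1.475,
    ("O3'", "P"): 1.607, ("P", "O5'"): 1.593, ("P", "OP"): 1.485,
}
_ELEMENT = {"P": "P", "O": "O", "C": "C", "N": "N"}

_VDW_DEFAULT = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80}


class TemplateDefinitionError(ValueError):
    """Template torsion definitions do not resolve to a valid rigid subtree."""


def _ring_polygon(n: int, bond: float) -> list[complex]:
    """Vertices of a regular n-gon with given side, first vertex at origin,
    second along +x rotated to put the ring in the upper half plane."""
    r = bond / (2.0 * math.sin(math.pi / n))
    center = complex(r, 0.0)
    start = math.pi  # first vertex at origin
    step = -2.0 * math.pi / n
    return [center + r * complex(math.cos(start + k * step), math.sin(start + k * step)) for k in range(n)]


def _fused_hexagon(p_a: complex, p_b: complex, away_from: complex) -> list[complex]:
    """Four new vertices completing a regular hexagon on the edge p_a-p_b,
    on the side away from ``away_from``."""
    edge = p_b - p_a
    mid = (p_a + p_b) / 2.0
    normal = edge / abs(edge) * 1j
    if ((mid + normal) - away_from).real ** 2 + ((mid + normal) - away_from).imag ** 2 < (
        (mid - normal) - away_from
    ).real ** 2 + ((mid - normal) - away_from).imag ** 2:
        normal = -normal
    center = mid + normal * (abs(edge) * math.sqrt(3.0) / 2.0)
    # walk the remaining 4 vertices from p_b around the center
    out = []
    v = p_b - center
    rot = complex(math.cos(-math.pi / 3.0), math.sin(-math.pi / 3.0))
    # choose walking direction that does not immediately return to p_a
    if abs((center + v * rot) - p_a) < 1e-6:
        rot = rot.conjugate()
    for _ in range(4):
        v = v * rot
        out.append(center + v)
    return out


def _base_layout(base: str) -> tuple[list[tuple[str, str, complex]], list[tuple[str, str]]]:
    """Planar heavy-atom layout of a nucleobase.

    Glycosidic nitrogen at the origin, ring extending toward +x; returns
    (atoms, ring/exocyclic bond list by atom name).  Idealized regular-ring
    geometry: bases act as rigid bodies here, so only bulk shape matters.
    """
    if base in ("A", "G"):
        n9, c8, n7, c5, c4 = _ring_polygon(5, 1.37)
        hex_new = _fused_hexagon(c4, c5, n9)  # C6, N1, C2, N3 (from C5 side)
        c6, n1, c2, n3 = hex_new
        atoms = [
            ("N9", "N", n9), ("C8", "C", c8), ("N7", "N", n7),
            ("C5", "C", c5), ("C4", "C", c4), ("C6", "C", c6),
            ("N1", "N", n1), ("C2", "C", c2), ("N3", "N", n3),
        ]
        bonds = [
            ("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C4"), ("C4", "N9"),
            ("C4", "N3"), ("N3", "C2"), ("C2", "N1"), ("N1", "C6"), ("C6", "C5"),
        ]
        hex_center = sum([c4, c5, c6, n1, c2, n3]) / 6.0
        if base == "A":
            atoms.append(("N6", "N", c6 + (c6 - hex_center) / abs(c6 - hex_center) * 1.34))
            bonds.append(("C6", "N6"))
        else:
            atoms.append(("O6", "O", c6 + (c6 - hex_center) / abs(c6 - hex_center) * 1.24))
            atoms.append(("N2", "N", c2 + (c2 - hex_center) / abs(c2 - hex_center) * 1.34))
            bonds.extend([("C6", "O6"), ("C2", "N2")])
        return atoms, bonds
    if base in ("C", "U"):
        n1, c2, n3, c4, c5, c6 = _ring_polygon(6, 1.38)
        center = sum([n1, c2, n3, c4, c5, c6]) / 6.0
        atoms = [
            ("N1", "N", n1), ("C2", "C", c2), ("N3", "N", n3),
            ("C4", "C", c4), ("C5", "C", c5), ("C6", "C", c6),
            ("O2", "O", c2 + (c2 - center) / abs(c2 - center) * 1.24),
        ]
        bonds = [
            ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"),
            ("C5", "C6"), ("C6", "N1"), ("C2", "O2"),
        ]
        if base == "C":
            atoms.append(("N4", "N", c4 + (c4 - center) / abs(c4 - center) * 1.34))
            bonds.append(("C4", "N4"))
        else:
            atoms.append(("O4", "O", c4 + (c4 - center) / abs(c4 - center) * 1.24))
            bonds.append(("C4", "O4"))
        return atoms, bonds
    raise KeyError(f"unknown base {base!r}")


@dataclass
class DNTemplate:
    """A rigid-geometry dinucleotide with rotatable suite torsions."""

    sequence: str
    atom_names: list[str]          # e.g. "C4'" ; base atoms e.g. "N9"
    elements: list[str]
    slots: list[int]               # residue slot: 0 = i-1, 1 = i
    coords: np.ndarray             # (n_atoms, 3), Angstrom
    parent: list[int | None]       # NeRF construction tree
    rigid_bonds: list[tuple[int, int]]
    closure_bonds: list[tuple[int, int]]
    torsion_atoms: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)

    @property
    def bonds(self) -> list[tuple[int, int]]:
        """Full bond graph (rigid tree plus soft closures)."""
        return self.rigid_bonds + self.closure_bonds

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def index_of(self, slot: int, name: str) -> int:
        for i, (s, n) in enumerate(zip(self.slots, self.atom_names)):
            if s == slot and n == name:
                return i
        raise KeyError(f"atom {name!r} in residue slot {slot} not found")

    def downstream_of(self, torsion: str) -> np.ndarray:
        """Indices of atoms that move when ``torsion`` is rotated.

        The rotation bond is the middle bond of the torsion quadruple; the
        moving set is the rigid-tree subtree rooted at its distal atom.
        """
        if torsion not in self.torsion_atoms:
            raise TemplateDefinitionError(f"torsion {torsion!r} not defined")
        _, j, k, _ = self.torsion_atoms[torsion]
        if self.parent[k] != j:
            raise TemplateDefinitionError(
                f"torsion {torsion!r}: rotation bond {j}-{k} is not a tree edge"
            )
        children: dict[int, list[int]] = {}
        for idx, par in enumerate(self.parent):
            if par is not None:
                children.setdefault(par, []).append(idx)
        out: list[int] = []
        stack = [k]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(children.get(node, []))
        out.remove(k)  # the axis atom itself does not move
        if not out:
            raise TemplateDefinitionError(f"torsion {torsion!r}: empty downstream set")
        return np.array(sorted(out), dtype=int)

    def graph_distances(self) -> np.ndarray:
        """All-pairs bond-count distances over the full bond graph."""
        import scipy.sparse as sp
        import scipy.sparse.csgraph as csgraph

        n = self.n_atoms
        rows, cols = zip(*self.bonds)
        adj = sp.coo_matrix(
            (np.ones(len(self.bonds)), (rows, cols)), shape=(n, n)
        )
        adj = adj + adj.T
        return csgraph.shortest_path(adj, method="D", unweighted=True)

    def countable_pairs(self) -> np.ndarray:
        """Boolean mask of atom pairs scored by clash detection.

        Only inter-residue pairs are scored: intra-residue geometry is
        either invariant under suite-torsion rotation or distorted by the
        soft ring closure (a delta rotation re-orients half the sugar),
        so intra-residue contacts carry no suite-conformation signal.
        """
        slots = np.asarray(self.slots)
        return slots[:, None] != slots[None, :]

    def vdw_radii(self, table: dict[str, float] | None = None) -> np.ndarray:
        table = table or _VDW_DEFAULT
        try:
            return np.array([table[e] for e in self.elements])
        except KeyError as exc:
            raise KeyError(f"no van der Waals radius for element {exc}") from None


class _Builder:
    def __init__(self, sequence: str):
        self.sequence = sequence
        self.names: list[str] = []
        self.elements: list[str] = []
        self.slots: list[int] = []
        self.coords: list[np.ndarray] = []
        self.parent: list[int | None] = []
        self.closures: list[tuple[int, int]] = []

    def add(self, slot: int, name: str, pos: np.ndarray, parent: int | None) -> int:
        self.names.append(name)
        self.elements.append(_ELEMENT[name[0] if name[0] != "O" else "O"])
        self.slots.append(slot)
        self.coords.append(np.asarray(pos, dtype=float))
        self.parent.append(parent)
        return len(self.names) - 1

    def nerf(self, slot: int, name: str, a: int, b: int, c: int,
             r: float, theta: float, phi: float) -> int:
        pos = place_atom(self.coords[a], self.coords[b], self.coords[c], r, theta, phi)
        return self.add(slot, name, pos, parent=c)


# Branch-torsion offsets that close the ribose ring (|O4'-C1'| = 1.42 A)
# when the sugar is built at the pucker midpoint delta = 115 deg.  Solved
# numerically for the standard bond lengths/angles above; the closure then
# flexes only between ~1.42 and ~1.72 A over the whole C3'-endo..C2'-endo
# delta range.
_O4_OFFSET = -40.0       # torsion(O5'-C5'-C4'-O4') = gamma + offset
_C2_OFFSET = 131.0       # torsion(C5'-C4'-C3'-C2') = delta + offset
_NU2 = 26.25             # torsion(C4'-C3'-C2'-C1')
_DELTA_BUILD = 115.0     # construction delta (pucker midpoint)


def _build_sugar_and_base(
    bld: _Builder, slot: int, base: str,
    i_prev2: int, i_prev1: int, i_c4: int,
    gamma_built: float,
    chi: float = 240.0,
    base_spin: float = 150.0,
) -> tuple[int, int]:
    """Attach O4', C3', O3', C2', O2', C1' and a rigid planar base to C4'.

    ``i_prev2``/``i_prev1`` are the two backbone atoms before C4' (for NeRF
    reference).  Returns (index of C3', index of O3').
    """
    # main chain continues through C3'
    i_c3 = bld.nerf(slot, "C3'", i_prev2, i_prev1, i_c4, _R[("C4'", "C3'")], 115.5, gamma_built)
    i_o4 = bld.nerf(slot, "O4'", i_prev2, i_prev1, i_c4, _R[("C4'", "O4'")], 109.2,
                    gamma_built + _O4_OFFSET)
    i_o3 = bld.nerf(slot, "O3'", i_prev1, i_c4, i_c3, _R[("C3'", "O3'")], 110.6, _DELTA_BUILD)
    # sugar ring walks C3'->C2'->C1'; ring closes softly back onto O4'
    i_c2 = bld.nerf(slot, "C2'", i_prev1, i_c4, i_c3, _R[("C3'", "C2'")], 102.6,
                    _DELTA_BUILD + _C2_OFFSET)
    i_c1 = bld.nerf(slot, "C1'", i_c4, i_c3, i_c2, _R[("C2'", "C1'")], 101.5, _NU2)
    bld.nerf(slot, "O2'", i_c4, i_c3, i_c2, _R[("C2'", "O2'")], 113.0, _NU2 - 120.0)
    bld.closures.append((i_o4, i_c1))

    # rigid planar base: glycosidic N placed by NeRF, plane fixed by chi
    n_name = "N9" if base in ("A", "G") else "N1"
    base_atoms, base_bonds = _base_layout(base)
    i_n = bld.nerf(slot, n_name, i_c3, i_c2, i_c1, _R[("C1'", "N")], 112.0, chi)
    ex = bld.coords[i_n] - bld.coords[i_c1]
    ex /= np.linalg.norm(ex)
    ref = bld.coords[i_o4] - bld.coords[i_c1]
    ey = ref - (ref @ ex) * ex
    ey /= np.linalg.norm(ey)
    name_to_idx = {n_name: i_n}
    neighbours: dict[str, list[str]] = {}
    for a, b in base_bonds:
        neighbours.setdefault(a, []).append(b)
        neighbours.setdefault(b, []).append(a)
    from .nerf import rotation_about_axis

    spin_rot = rotation_about_axis(ex, base_spin) if base_spin else None
    for name, _elem, xy in base_atoms:
        if name == n_name:
            continue
        pos = bld.coords[i_n] + xy.real * ex + xy.imag * ey
        if spin_rot is not None:
            # glycosidic spin: rotate the base plane about the C1'-N axis
            pos = bld.coords[i_n] + spin_rot @ (pos - bld.coords[i_n])
        # tree parent = first already-placed chemical neighbour
        par = next(name_to_idx[nb] for nb in neighbours[name] if nb in name_to_idx)
        name_to_idx[name] = bld.add(slot, name, pos, parent=par)
    for a, b in base_bonds:
        ia, ib = name_to_idx[a], name_to_idx[b]
        if bld.parent[ib] != ia and bld.parent[ia] != ib:
            bld.closures.append((ia, ib))  # ring-closing chemical bonds
    return i_c3, i_o3


def build_template(sequence: str, chi: float = 240.0, base_spin: float = 150.0) -> DNTemplate:
    """Build the idealized template for one dinucleotide sequence.

    The initial conformation is A-form-like (the torsions are set per
    rotamer afterwards by the sampler).  ``chi`` is the glycosidic torsion
    used for both bases (anti region by default).
    """
    sequence = sequence.upper()
    if len(sequence) != 2 or any(b not in BASES for b in sequence):
        raise ValueError(f"sequence must be 2 letters over {BASES}, got {sequence!r}")
    bld = _Builder(sequence)

    # seed: 5'-terminal O5', C5', C4' of residue i-1
    i_o5a = bld.add(0, "O5'", np.zeros(3), parent=None)
    i_c5a = bld.add(0, "C5'", np.array([_R[("O5'", "C5'")], 0.0, 0.0]), parent=i_o5a)
    theta = math.radians(111.5)
    i_c4a = bld.add(
        0, "C4'",
        bld.coords[i_c5a] + _R[("C5'", "C4'")] * np.array([-math.cos(theta), math.sin(theta), 0.0]),
        parent=i_c5a,
    )
    i_c3a, i_o3a = _build_sugar_and_base(
        bld, 0, sequence[0], i_o5a, i_c5a, i_c4a, gamma_built=54.0, chi=chi, base_spin=base_spin
    )

    # phosphate bridge into residue i
    i_p = bld.nerf(1, "P", i_c4a, i_c3a, i_o3a, _R[("O3'", "P")], 119.7, 212.0)   # epsilon
    i_o5b = bld.nerf(1, "O5'", i_c3a, i_o3a, i_p, _R[("P", "O5'")], 104.0, 289.0)  # zeta
    i_op1 = bld.nerf(1, "OP1", i_c3a, i_o3a, i_p, _R[("P", "OP")], 108.1, 289.0 + 119.0)
    i_op2 = bld.nerf(1, "OP2", i_c3a, i_o3a, i_p, _R[("P", "OP")], 108.1, 289.0 - 119.0)
    i_c5b = bld.nerf(1, "C5'", i_o3a, i_p, i_o5b, _R[("O5'", "C5'")], 120.9, 295.0)  # alpha
    i_c4b = bld.nerf(1, "C4'", i_p, i_o5b, i_c5b, _R[("C5'", "C4'")], 111.5, 174.0)  # beta
    _build_sugar_and_base(
        bld, 1, sequence[1], i_o5b, i_c5b, i_c4b, gamma_built=54.0, chi=chi, base_spin=base_spin
    )

    rigid = [(p, i) for i, p in enumerate(bld.parent) if p is not None]
    tpl = DNTemplate(
        sequence=sequence,
        atom_names=bld.names,
        elements=bld.elements,
        slots=bld.slots,
        coords=np.vstack(bld.coords),
        parent=bld.parent,
        rigid_bonds=rigid,
        closure_bonds=bld.closures,
    )
    quads = {
        "d1": [(0, "C5'"), (0, "C4'"), (0, "C3'"), (0, "O3'")],
        "e1": [(0, "C4'"), (0, "C3'"), (0, "O3'"), (1, "P")],
        "z1": [(0, "C3'"), (0, "O3'"), (1, "P"), (1, "O5'")],
        "al": [(0, "O3'"), (1, "P"), (1, "O5'"), (1, "C5'")],
        "be": [(1, "P"), (1, "O5'"), (1, "C5'"), (1, "C4'")],
        "ga": [(1, "O5'"), (1, "C5'"), (1, "C4'"), (1, "C3'")],
        "d2": [(1, "C5'"), (1, "C4'"), (1, "C3'"), (1, "O3'")],
    }
    tpl.torsion_atoms = {
        name: tuple(tpl.index_of(slot, atom) for slot, atom in quad)
        for name, quad in quads.items()
    }
    for name in TORSION_NAMES:
        tpl.downstream_of(name)  # validates tree structure
    return tpl


def enumerate_templates(chi: float = 240.0, base_spin: float = 150.0) -> dict[str, DNTemplate]:
    """All 16 dinucleotide templates, keyed by sequence."""
    return {a + b: build_template(a + b, chi=chi, base_spin=base_spin)
            for a in BASES for b in BASES}
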