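"""Suite extraction from RNA 3D structures and nearest-rotamer assignment.

A *suite* is the sugar-to-sugar backbone unit spanning the seven torsions
(delta_{i-1}, epsilon_{i-1}, zeta_{i-1}, alpha_i, beta_i, gamma_i,
delta_i).  Given a PDB/mmCIF structure this module computes those torsions
for every bonded interior residue pair and assigns each suite to the
nearest catalog rotamer by circular Euclidean distance in torsion space.

Atom quadruples follow the standard nucleic-acid convention:

    alpha = O3'(i-1)-P-O5'-C5'      beta  = P-O5'-C5'-C4'
    gamma = O5'-C5'-C4'-C3'         delta = C5'-C4'-C3'-O3'
    eps   = C4'-C3'-O3'-P(i+1)      zeta  = C3'-O3'-P(i+1)-O5'(i+1)

Angles are reported on [0, 360).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

from .catalog import RotamerCatalog, TORSION_NAMES

__all__ = [
    "Suite",
    "UndefinedDihedralError",
    "dihedral",
    "wrap_degrees",
    "circular_distance",
    "assign_rotamer",
    "extract_suites",
    "read_structure",
    "read_shift_table",
    "write_suite_table",
    "suites_to_frame",
]

logger = logging.getLogger(__name__)

_RNA_RESIDUES = {"A", "C", "G", "U"}
#: C1'-C5' shift column names used in delimited tables.
SHIFT_NAMES = ("C1p", "C2p", "C3p", "C4p", "C5p")
#: Maximum O3'(i-1)-P(i) distance for two residues to count as bonded.
BOND_CUTOFF = 2.0


class UndefinedDihedralError(ValueError):
    """Dihedral undefined: collinear or coincident defining atoms."""


@dataclass
class Suite:
    """One suite: provenance, dinucleotide sequence, 7 torsions, options.

    ``torsions`` are degrees on [0, 360) in :data:`~rotasuite.catalog.TORSION_NAMES`
    order; ``shifts`` (when present) are the five ribose carbon shifts of
    residue i in ppm, ordered C1'-C5'.
    """

    structure_id: str
    chain: str
    residue_index_i: int
    sequence: str
    torsions: tuple[float, ...]
    shifts: tuple[float, ...] | None = None
    rotamer_id: str | None = None
    distance: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.torsions) != 7:
            raise ValueError("a suite has exactly 7 torsions")
        for t in self.torsions:
            if not math.isfinite(t) or not (0.0 <= t < 360.0):
                raise ValueError(f"torsion {t} outside [0, 360)")
        if self.shifts is not None:
            if len(self.shifts) != 5:
                raise ValueError("a suite carries exactly 5 shifts")
            for s in self.shifts:
                if not (0.0 <= s <= 120.0):
                    raise ValueError(f"shift {s} ppm outside plausibility window")


# ---------------------------------------------------------------------------
# dihedral geometry
# ---------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral of four 3D points, mapped to [0, 360) degrees.

    Raises :class:`UndefinedDihedralError` when either atom triple is
    collinear or consecutive points coincide.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if np.linalg.norm(b2) < 1e-12:
        raise UndefinedDihedralError("central atoms coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise UndefinedDihedralError("collinear defining atoms")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    # sign chosen to match the IUPAC convention (gemmi agrees)
    angle = -math.degrees(math.atan2(float(m @ n2), float(n1 @ n2)))
    return angle % 360.0


def wrap_degrees(delta: np.ndarray | float) -> np.ndarray | float:
    """Wrap an angular difference into (-180, 180]."""
    return -((-np.asarray(delta, dtype=float) + 180.0) % 360.0 - 180.0)


def circular_distance(
    a: Sequence[float], b: Sequence[float], scale: Sequence[float] | None = None
) -> float:
    """Circular Euclidean distance (degrees) between two torsion vectors.

    Each coordinate difference is wrapped into (-180, 180]; with ``scale``
    the wrapped differences are divided per-coordinate first (used for
    spread-scaled assignment).
    """
    d = wrap_degrees(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    if scale is not None:
        d = d / np.asarray(scale, dtype=float)
    return float(np.sqrt(np.sum(d * d)))


def assign_rotamer(
    torsions: Sequence[float],
    catalog: RotamerCatalog,
    scale_by_spread: bool = False,
) -> tuple[str, float]:
    """Nearest catalog rotamer for a 7-torsion vector.

    Returns ``(rotamer_id, distance)`` where distance is the circular
    Euclidean distance in degrees (in spread units when
    ``scale_by_spread``).  Ties break toward higher catalog frequency,
    then lexicographic id.
    """
    best: tuple[float, float, str] | None = None
    best_id = None
    for rot in catalog:
        scale = rot.spread_torsions if scale_by_spread else None
        d = circular_distance(torsions, rot.mean_torsions, scale)
        key = (d, -rot.frequency, rot.rotamer_id)
        if best is None or key < best:
            best = key
            best_id = rot.rotamer_id
    assert best_id is not None
    return best_id, best[0]


# ---------------------------------------------------------------------------
# structure parsing
# ---------------------------------------------------------------------------

def read_structure(path: str | Path) -> gemmi.Structure:
    """Read a PDB or mmCIF file (format sniffed from contents)."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def _atom_pos(residue: gemmi.Residue, name: str) -> np.ndarray | None:
    atom = residue.find_atom(name, "*")
    if atom is None:
        return None
    return np.array([atom.pos.x, atom.pos.y, atom.pos.z])


_SUITE_QUADS = {
    # torsion -> list of (residue slot 0 = i-1 / 1 = i, atom name)
    "d1": [(0, "C5'"), (0, "C4'"), (0, "C3'"), (0, "O3'")],
    "e1": [(0, "C4'"), (0, "C3'"), (0, "O3'"), (1, "P")],
    "z1": [(0, "C3'"), (0, "O3'"), (1, "P"), (1, "O5'")],
    "al": [(0, "O3'"), (1, "P"), (1, "O5'"), (1, "C5'")],
    "be": [(1, "P"), (1, "O5'"), (1, "C5'"), (1, "C4'")],
    "ga": [(1, "O5'"), (1, "C5'"), (1, "C4'"), (1, "C3'")],
    "d2": [(1, "C5'"), (1, "C4'"), (1, "C3'"), (1, "O3'")],
}


def extract_suites(
    structure: gemmi.Structure,
    model_index: int = 0,
    all_models: bool = False,
    catalog: RotamerCatalog | None = None,
    scale_by_spread: bool = False,
    max_distance: float | None = None,
) -> list[Suite]:
    """Assemble suites from a parsed structure.

    One suite per bonded interior residue pair (O3'(i-1)-P(i) within
    2.0 A) with all seven torsions computable; chain breaks and residues
    with missing backbone atoms yield no suite (logged, not fatal).
    Modified/HETATM nucleotides are skipped.  By default only the first
    model of an NMR ensemble is used; ``all_models`` extracts every model.
    When a ``catalog`` is given each suite is assigned its nearest rotamer
    (optionally flagged unassigned beyond ``max_distance``).
    """
    if len(structure) == 0:
        raise ValueError("structure contains no models")
    models = list(structure) if all_models else [structure[model_index]]
    suites: list[Suite] = []
    for model in models:
        for chain in model:
            residues = [
                r
                for r in chain
                if r.name.strip() in _RNA_RESIDUES and not r.het_flag == "H"
            ]
            for prev, curr in zip(residues, residues[1:]):
                o3 = _atom_pos(prev, "O3'")
                p = _atom_pos(curr, "P")
                if o3 is None or p is None:
                    logger.warning(
                        "%s %s %s-%s: missing O3'/P, suite skipped",
                        structure.name, chain.name, prev.seqid.num, curr.seqid.num,
                    )
                    continue
                if np.linalg.norm(o3 - p) > BOND_CUTOFF:
                    continue  # chain break
                pair = (prev, curr)
                torsions = []
                ok = True
                for name in TORSION_NAMES:
                    pts = []
                    for slot, atom in _SUITE_QUADS[name]:
                        pos = _atom_pos(pair[slot], atom)
                        if pos is None:
                            logger.warning(
                                "%s %s %s: missing atom %s, suite skipped",
                                structure.name, chain.name, curr.seqid.num, atom,
                            )
                            ok = False
                            break
                        pts.append(pos)
                    if not ok:
                        break
                    torsions.append(dihedral(*pts))
                if not ok:
                    continue
                suite = Suite(
                    structure_id=structure.name or "structure",
                    chain=chain.name,
                    residue_index_i=curr.seqid.num,
                    sequence=prev.name.strip() + curr.name.strip(),
                    torsions=tuple(torsions),
                )
                if catalog is not None:
                    rid, d = assign_rotamer(suite.torsions, catalog, scale_by_spread)
                    if max_distance is not None and d > max_distance:
                        suite.rotamer_id = None
                    else:
                        suite.rotamer_id = rid
                    suite.distance = d
                suites.append(suite)
    return suites


# ---------------------------------------------------------------------------
# shift tables and suite tables
# ---------------------------------------------------------------------------

def read_shift_table(path: str | Path) -> tuple[dict[tuple[str, str, int], tuple[float, ...]], int]:
    """Read per-suite ribose 13C' shifts from a delimited file.

    The file must have a header naming the five nuclei (``C1p``..``C5p``;
    primed spellings ``C1'`` are accepted) plus ``structure_id``, ``chain``
    and ``residue_i`` key columns.  Returns ``(records, n_dropped)`` where
    records maps ``(structure_id, chain, residue_i)`` to the 5 shifts and
    rows with any missing nucleus are dropped and counted.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed shift table {path}: {exc}") from exc
    df.columns = [str(c).replace("'", "p").replace("′", "p") for c in df.columns]
    missing_cols = [c for c in SHIFT_NAMES if c not in df.columns]
    if missing_cols:
        raise ValueError(f"shift table {path} missing columns {missing_cols}")
    for key in ("structure_id", "chain", "residue_i"):
        if key not in df.columns:
            raise ValueError(f"shift table {path} missing key column {key!r}")
    complete = df.dropna(subset=list(SHIFT_NAMES))
    n_dropped = len(df) - len(complete)
    records = {
        (str(row["structure_id"]), str(row["chain"]), int(row["residue_i"])): tuple(
            float(row[c]) for c in SHIFT_NAMES
        )
        for _, row in complete.iterrows()
    }
    return records, n_dropped


def suites_to_frame(suites: Sequence[Suite]) -> pd.DataFrame:
    """Tabulate suites (one row each) for writing as delimited text."""
    rows = []
    for s in suites:
        row = {
            "structure_id": s.structure_id,
            "chain": s.chain,
            "residue_i": s.residue_index_i,
            "sequence": s.sequence,
        }
        row.update(dict(zip(TORSION_NAMES, s.torsions)))
        if s.shifts is not None:
            row.update(dict(zip(SHIFT_NAMES, s.shifts)))
        row["rotamer_id"] = s.rotamer_id if s.rotamer_id is not None else ""
        row["distance"] = s.distance if s.distance is not None else ""
        rows.append(row)
    return pd.DataFrame(rows)


def write_suite_table(suites: Sequence[Suite], path: str | Path) -> None:
    suites_to_frame(suites).to_csv(path, sep="\t", index=False)
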