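"""Consensus catalog of the 46 RNA backbone suite rotamers.

The RNA backbone between consecutive ribose sugars (the *suite*, running
from ``delta`` of residue i-1 to ``delta`` of residue i) clusters into 46
consensus conformational classes ("rotamers"), each named by a two-character
label such as ``1a`` (the A-form helix class), ``2[`` or ``&a``.  This
module ships the catalog of per-rotamer mean torsions, circular spreads and
observed frequencies, together with the seven published family groupings
that coarsen the 46 classes down to as few as two labels.

The seven grouping schemes are keyed by which torsion peaks define them:

``dd_ag``
    delta(i-1), delta(i), alpha, gamma peaks -- 22 families.
``dd_a`` / ``dd_g``
    delta pair plus alpha (or gamma) -- 10 families each.
``ag``
    alpha/gamma peaks alone -- 7 families.
``dd``
    the two sugar puckers (C3'-endo vs C2'-endo) of the flanking riboses
    -- 4 families; the grouping chemical shifts resolve best.
``A_noA``
    rotamer 1a (A-form helix) versus everything else.
``Astar_noA``
    the A-form-related set {1a, 3d, 3b, 5d, 0a, 6d, 4b} versus the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "TORSION_NAMES",
    "SCHEME_IDS",
    "RotamerDef",
    "FamilyMap",
    "RotamerCatalog",
    "CatalogIntegrityError",
    "load_catalog",
]

#: Order of the seven suite torsions everywhere in this package.
TORSION_NAMES = ("d1", "e1", "z1", "al", "be", "ga", "d2")

#: The seven family grouping schemes, coarsest last.
SCHEME_IDS = ("dd_ag", "dd_a", "dd_g", "ag", "dd", "A_noA", "Astar_noA")

_DATA_PACKAGE = "rotasuite.data"


class CatalogIntegrityError(ValueError):
    """Raised when a rotamer table violates the catalog contract."""


@dataclass(frozen=True)
class RotamerDef:
    """One consensus rotamer: label, mean torsions, spreads, frequency.

    ``mean_torsions`` and ``spread_torsions`` are 7-tuples in degrees,
    ordered (delta_{i-1}, epsilon_{i-1}, zeta_{i-1}, alpha_i, beta_i,
    gamma_i, delta_i); means lie on [0, 360), spreads are circular
    standard deviations > 0.  ``frequency`` is a nonnegative observation
    weight used for tie-breaking and random baselines.
    """

    rotamer_id: str
    mean_torsions: tuple[float, ...]
    spread_torsions: tuple[float, ...]
    frequency: float

    def __post_init__(self) -> None:
        if len(self.mean_torsions) != 7 or len(self.spread_torsions) != 7:
            raise CatalogIntegrityError(
                f"rotamer {self.rotamer_id!r}: expected 7 means and 7 spreads"
            )
        for m in self.mean_torsions:
            if not (0.0 <= m < 360.0) or not math.isfinite(m):
                raise CatalogIntegrityError(
                    f"rotamer {self.rotamer_id!r}: mean {m} outside [0, 360)"
                )
        for s in self.spread_torsions:
            if not (s > 0.0) or not math.isfinite(s):
                raise CatalogIntegrityError(
                    f"rotamer {self.rotamer_id!r}: spread {s} must be > 0"
                )
        if self.frequency < 0:
            raise CatalogIntegrityError(
                f"rotamer {self.rotamer_id!r}: negative frequency"
            )


class FamilyMap:
    """rotamer_id -> single-character family label for one scheme."""

    def __init__(self, scheme_id: str, mapping: Mapping[str, str]):
        if scheme_id not in SCHEME_IDS:
            raise KeyError(f"unknown scheme {scheme_id!r}; valid: {SCHEME_IDS}")
        self.scheme_id = scheme_id
        self.mapping = dict(mapping)

    def __getitem__(self, rotamer_id: str) -> str:
        try:
            return self.mapping[rotamer_id]
        except KeyError:
            raise KeyError(
                f"rotamer {rotamer_id!r} not in scheme {self.scheme_id!r}"
            ) from None

    def labels(self) -> set[str]:
        return set(self.mapping.values())

    def n_families(self) -> int:
        return len(self.labels())


class RotamerCatalog:
    """The 46-rotamer catalog plus the seven family grouping schemes."""

    def __init__(self, rotamers: Sequence[RotamerDef], family_table: pd.DataFrame):
        ids = [r.rotamer_id for r in rotamers]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CatalogIntegrityError(f"duplicate rotamer ids: {dupes}")
        if len(ids) != 46:
            raise CatalogIntegrityError(
                f"catalog must contain exactly 46 rotamers, got {len(ids)}"
            )
        self._rotamers = {r.rotamer_id: r for r in rotamers}
        if sum(r.frequency for r in rotamers) <= 0:
            raise CatalogIntegrityError("frequencies must sum to a positive total")

        missing = set(ids) - set(family_table.index)
        if missing:
            raise CatalogIntegrityError(
                f"family map missing rotamers: {sorted(missing)}"
            )
        self._families = {
            scheme: FamilyMap(scheme, family_table[scheme].to_dict())
            for scheme in SCHEME_IDS
        }

    # -- lookup ----------------------------------------------------------

    def lookup(self, rotamer_id: str) -> RotamerDef:
        try:
            return self._rotamers[rotamer_id]
        except KeyError:
            raise KeyError(f"unknown rotamer {rotamer_id!r}") from None

    def __contains__(self, rotamer_id: str) -> bool:
        return rotamer_id in self._rotamers

    def __iter__(self) -> Iterator[RotamerDef]:
        return iter(self._rotamers.values())

    def __len__(self) -> int:
        return len(self._rotamers)

    @property
    def rotamer_ids(self) -> list[str]:
        return list(self._rotamers)

    def family_of(self, rotamer_id: str, scheme_id: str) -> str:
        """Family label of ``rotamer_id`` under one of the seven schemes."""
        if rotamer_id not in self._rotamers:
            raise KeyError(f"unknown rotamer {rotamer_id!r}")
        if scheme_id not in self._families:
            raise KeyError(f"unknown scheme {scheme_id!r}; valid: {SCHEME_IDS}")
        return self._families[scheme_id][rotamer_id]

    def family_map(self, scheme_id: str) -> FamilyMap:
        if scheme_id not in self._families:
            raise KeyError(f"unknown scheme {scheme_id!r}; valid: {SCHEME_IDS}")
        return self._families[scheme_id]

    def count_families(self, scheme_id: str) -> int:
        """Number of distinct family labels in a scheme's column."""
        return self.family_map(scheme_id).n_families()

    def frequencies(self) -> dict[str, float]:
        total = sum(r.frequency for r in self._rotamers.values())
        return {rid: r.frequency / total for rid, r in self._rotamers.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self:
            row = {"rotamer_id": r.rotamer_id}
            row.update(
                {f"{n}_mean": v for n, v in zip(TORSION_NAMES, r.mean_torsions)}
            )
            row.update(
                {f"{n}_sd": v for n, v in zip(TORSION_NAMES, r.spread_torsions)}
            )
            row["frequency"] = r.frequency
            rows.append(row)
        return pd.DataFrame(rows).set_index("rotamer_id")


def _packaged(name: str) -> Path:
    return Path(resources.files(_DATA_PACKAGE) / name)


def _strip_comments(path: Path):
    import io

    text = Path(path).read_text()
    kept = [ln for ln in text.splitlines() if not ln.startswith("# ")]
    return io.StringIO("\n".join(kept))


def load_catalog(
    rotamer_table: str | Path | None = None,
    family_table: str | Path | None = None,
) -> RotamerCatalog:
    """Load the packaged (or a user-supplied) rotamer catalog.

    Both tables are tab-separated with ``#`` comment headers; see the
    packaged assets under ``rotasuite/data`` for the column layout.
    """
    rot_path = Path(rotamer_table) if rotamer_table else _packaged("rotamer_table.tsv")
    fam_path = Path(family_table) if family_table else _packaged("family_map.tsv")
    # note: "#a" is a rotamer id, so only "# "-prefixed lines are comments
    rot = pd.read_csv(_strip_comments(rot_path), sep="\t", dtype={"rotamer_id": str})
    fam = pd.read_csv(_strip_comments(fam_path), sep="\t", dtype=str).set_index(
        "rotamer_id"
    )
    rotamers = [
        RotamerDef(
            rotamer_id=row["rotamer_id"],
            mean_torsions=tuple(float(row[f"{n}_mean"]) for n in TORSION_NAMES),
            spread_torsions=tuple(float(row[f"{n}_sd"]) for n in TORSION_NAMES),
            frequency=float(row["frequency"]),
        )
        for _, row in rot.iterrows()
    ]
    return RotamerCatalog(rotamers, fam)
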