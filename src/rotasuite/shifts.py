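"""Chemical-shift referencing and the synthetic shielding generator.

Quantum-chemical calculations yield isotropic shieldings (sigma, ppm);
comparison with experiment requires converting them to chemical shifts via
a reference shielding:  delta = sigma_ref - sigma.  The *simple* convention
uses a single scalar sigma_ref = 185.00 ppm (close to the theoretical
shielding of TMS); *effective* references refine this per nitrogenous-base
sequence, per ribose-pucker family, per carbon nucleus, or by linear
regression of experimental on computed values.

The synthetic generator replaces quantum-chemical data: it emits per-suite
5-vectors of ribose carbon shieldings (C1'-C5') whose dominant structure
follows the delta(i-1)/delta(i) sugar-pucker family of the generating
rotamer, with weaker alpha/gamma torsion dependence, sequence-dependent
offsets and Gaussian noise.  An "experimental-like" transform adds the
~1.47 ppm theory-vs-experiment discrepancy and mimics the sparsity of
experimentally observed rotamers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import RotamerCatalog

__all__ = [
    "NUCLEI",
    "SIMPLE_REFERENCE_PPM",
    "EXPERIMENTAL_NOISE_PPM",
    "ShiftRecord",
    "ReferenceScheme",
    "ReferenceResolutionError",
    "ShieldingParams",
    "reference_shift",
    "fit_effective_reference",
    "generate_theoretical",
    "generate_experimental_like",
    "records_to_frame",
    "frame_to_records",
]

#: The five ribose carbons, in column order.
NUCLEI = ("C1p", "C2p", "C3p", "C4p", "C5p")

#: Scalar reference shielding of the simple convention (ppm).
SIMPLE_REFERENCE_PPM = 185.00

#: Magnitude of the expected experiment-vs-theory discrepancy (ppm).
EXPERIMENTAL_NOISE_PPM = 1.47


class ReferenceResolutionError(KeyError):
    """A reference scheme cannot resolve the requested context."""


@dataclass
class ShiftRecord:
    """One suite's 5-vector of shieldings and/or shifts.

    ``sigma_comp`` holds computed shieldings for theoretical records (absent
    for experimental-like ones); ``delta`` the 5 shifts in ppm (C1'-C5').
    """

    rotamer_id: str
    sequence: str
    conformer: int
    origin: str  # "theoretical" | "experimental-like"
    delta: np.ndarray
    sigma_comp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.shape != (5,):
            raise ValueError("delta must hold 5 values (C1'-C5')")
        if self.sigma_comp is not None:
            self.sigma_comp = np.asarray(self.sigma_comp, dtype=float)
            if self.sigma_comp.shape != (5,):
                raise ValueError("sigma_comp must hold 5 values")


@dataclass
class ReferenceScheme:
    """A shielding-to-shift conversion rule.

    kinds: ``simple`` (scalar sigma_ref), ``by_sequence`` /
    ``by_pucker_family`` / ``by_nucleus`` (lookup sigma_ref per context
    cell), ``regression`` (delta = slope * sigma + intercept).
    """

    kind: str
    scalar: float = SIMPLE_REFERENCE_PPM
    table: dict[str, float] = field(default_factory=dict)
    slope: float = -1.0
    intercept: float = SIMPLE_REFERENCE_PPM
    fallback: float = SIMPLE_REFERENCE_PPM

    def __post_init__(self) -> None:
        valid = ("simple", "by_sequence", "by_pucker_family", "by_nucleus", "regression")
        if self.kind not in valid:
            raise ValueError(f"unknown reference kind {self.kind!r}; valid: {valid}")
        if self.kind == "regression" and (self.slope == 0 or not math.isfinite(self.slope)):
            raise ValueError("regression reference requires a finite nonzero slope")


def reference_shift(
    sigma_comp: float | np.ndarray,
    scheme: ReferenceScheme,
    context: str | None = None,
) -> float | np.ndarray:
    """Convert computed shielding(s) to shift(s): delta = sigma_ref - sigma.

    ``context`` names the lookup cell (nucleus, sequence or pucker-family
    label) for the tabulated kinds; the regression kind returns
    ``slope * sigma + intercept``.
    """
    sigma = np.asarray(sigma_comp, dtype=float)
    if scheme.kind == "simple":
        out = scheme.scalar - sigma
    elif scheme.kind == "regression":
        out = scheme.slope * sigma + scheme.intercept
    else:
        if context is None:
            raise ReferenceResolutionError(
                f"{scheme.kind} reference requires a context label"
            )
        if context not in scheme.table:
            raise ReferenceResolutionError(
                f"context {context!r} not in {scheme.kind} reference table"
            )
        out = scheme.table[context] - sigma
    return float(out) if np.isscalar(sigma_comp) or sigma.ndim == 0 else out


def _context_label(
    rec: ShiftRecord, nucleus: str, kind: str, catalog: RotamerCatalog | None
) -> str:
    if kind == "by_nucleus":
        return nucleus
    if kind == "by_sequence":
        return rec.sequence
    if kind == "by_pucker_family":
        if catalog is None:
            raise ValueError("by_pucker_family fitting needs a catalog")
        return catalog.family_of(rec.rotamer_id, "dd")
    raise ValueError(kind)


def fit_effective_reference(
    theoretical: list[ShiftRecord],
    experimental: list[ShiftRecord],
    kind: str,
    catalog: RotamerCatalog | None = None,
) -> ReferenceScheme:
    """Fit an effective reference from paired theoretical/experimental records.

    Records are paired by (rotamer_id, sequence, conformer).  Subtractive
    kinds use the moment-matching estimate sigma_ref(cell) =
    mean(sigma_comp + delta_exp) over the cell; the regression kind fits
    delta_exp on sigma_comp by least squares.  Cells with fewer than 2
    pairs (3 for regression) fall back to the simple scalar and are
    recorded in ``scheme.table`` only when estimable.
    """
    exp_by_key = {(r.rotamer_id, r.sequence, r.conformer): r for r in experimental}
    pairs: list[tuple[ShiftRecord, ShiftRecord]] = [
        (t, exp_by_key[(t.rotamer_id, t.sequence, t.conformer)])
        for t in theoretical
        if (t.rotamer_id, t.sequence, t.conformer) in exp_by_key
        and t.sigma_comp is not None
    ]
    if not pairs:
        raise ValueError("no paired records to fit a reference from")

    if kind == "simple":
        vals = np.concatenate([t.sigma_comp + e.delta for t, e in pairs])
        return ReferenceScheme(kind="simple", scalar=float(vals.mean()))
    if kind == "regression":
        x = np.concatenate([t.sigma_comp for t, _ in pairs])
        y = np.concatenate([e.delta for _, e in pairs])
        if len(x) < 3:
            raise ValueError("regression reference needs >= 3 pairs")
        slope, intercept = np.polyfit(x, y, 1)
        return ReferenceScheme(kind="regression", slope=float(slope), intercept=float(intercept))

    cells: dict[str, list[float]] = {}
    for t, e in pairs:
        for k, nucleus in enumerate(NUCLEI):
            label = _context_label(t, nucleus, kind, catalog)
            cells.setdefault(label, []).append(float(t.sigma_comp[k] + e.delta[k]))
    table = {
        label: float(np.mean(vals)) for label, vals in cells.items() if len(vals) >= 2
    }
    return ReferenceScheme(kind=kind, table=table)


# ---------------------------------------------------------------------------
# synthetic shielding generator
# ---------------------------------------------------------------------------

def _default_pucker_effects() -> dict[str, tuple[float, ...]]:
    # per dd-family shielding offsets (ppm) for C1'..C5'; family "a"
    # (C3'-endo/C3'-endo) is the baseline.  Chosen so the four pucker
    # families are separated by >> the experimental-scale noise while
    # staying within the few-ppm range pucker effects have in practice.
    return {
        "a": (0.0, 0.0, 0.0, 0.0, 0.0),
        "b": (1.2, -2.0, 3.5, 1.0, -0.8),
        "c": (2.5, 1.5, -4.0, -1.2, 0.6),
        "d": (3.7, -0.5, -0.5, -0.2, -0.2),
    }


@dataclass
class ShieldingParams:
    """Parameters of the synthetic shielding generator.

    ``base_sigma``: baseline shielding per nucleus (ppm), roughly 185 minus
    typical ribose shift values.  ``base_offsets``: additive offset per
    nitrogenous base identity of residue i (a weaker echo of residue i-1's
    base is added via ``prev_base_weight``).  ``pucker_effects``: offsets
    keyed by the delta(i-1)/delta(i) family of the generating rotamer — the
    dominant conformational signal.  ``alpha_amps`` / ``gamma_amps``:
    cosine-series (amplitude, phase) pairs giving a weak smooth dependence
    on the alpha and gamma torsions, scaled per nucleus by
    ``angle_weights``.  ``noise_sd``: Gaussian theoretical noise (ppm).
    """

    base_sigma: tuple[float, ...] = (93.0, 110.0, 112.0, 103.0, 122.0)
    base_offsets: dict[str, float] = field(
        default_factory=lambda: {"A": 0.0, "G": 0.4, "C": -0.3, "U": 0.5}
    )
    prev_base_weight: float = 0.3
    pucker_effects: dict[str, tuple[float, ...]] = field(
        default_factory=_default_pucker_effects
    )
    alpha_amps: tuple[tuple[float, float], ...] = ((0.25, 0.0), (0.15, 1.0))
    gamma_amps: tuple[tuple[float, float], ...] = ((0.30, 0.5), (0.10, 2.0))
    angle_weights: tuple[float, ...] = (1.0, 0.6, 0.8, 1.2, 0.9)
    noise_sd: float = 0.3

    def null_structure(self) -> "ShieldingParams":
        """Copy with all conformational and noise terms zeroed."""
        return replace(
            self,
            pucker_effects={k: (0.0,) * 5 for k in self.pucker_effects},
            alpha_amps=(),
            gamma_amps=(),
            noise_sd=0.0,
        )


def _cosine_term(angle_deg: float, amps) -> float:
    a = math.radians(angle_deg)
    return sum(
        amp * math.cos((k + 1) * a + phase) for k, (amp, phase) in enumerate(amps)
    )


def generate_theoretical(
    catalog: RotamerCatalog,
    sequences,
    n_per_rotamer: int,
    params: ShieldingParams | None = None,
    seed: int | np.random.Generator = 0,
    rotamer_ids=None,
    torsions_by_key: dict[tuple[str, str], np.ndarray] | None = None,
    reference: ReferenceScheme | None = None,
) -> list[ShiftRecord]:
    """Generate labelled theoretical shielding records.

    For each (rotamer, sequence) pair, ``n_per_rotamer`` suite torsion
    vectors are drawn from the catalog's wrapped normals (or taken from
    ``torsions_by_key``, e.g. clash-filtered sampler output) and converted
    to shieldings:

        sigma(nucleus) = base + base_offset(sequence)
                         + pucker_effect(dd family)
                         + weight * [cos-series(alpha) + cos-series(gamma)]
                         + N(0, noise_sd)

    ``delta`` is filled by referencing (simple scheme by default).
    Deterministic for a fixed integer seed.
    """
    params = params or ShieldingParams()
    reference = reference or ReferenceScheme(kind="simple")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rotamer_ids = list(rotamer_ids) if rotamer_ids is not None else catalog.rotamer_ids
    base = np.asarray(params.base_sigma)
    weights = np.asarray(params.angle_weights)
    records: list[ShiftRecord] = []
    for rid in rotamer_ids:
        rot = catalog.lookup(rid)
        family = catalog.family_of(rid, "dd")
        if family not in params.pucker_effects:
            raise KeyError(f"no pucker effect for dd family {family!r}")
        pucker = np.asarray(params.pucker_effects[family])
        for seq in sequences:
            seq = seq.upper()
            offset = params.base_offsets[seq[1]] + params.prev_base_weight * params.base_offsets[seq[0]]
            if torsions_by_key is not None:
                tors = np.asarray(torsions_by_key[(rid, seq)], dtype=float)[:n_per_rotamer]
            else:
                tors = rng.normal(
                    rot.mean_torsions, rot.spread_torsions, size=(n_per_rotamer, 7)
                ) % 360.0
            for c, tv in enumerate(tors):
                angle_term = _cosine_term(tv[3], params.alpha_amps) + _cosine_term(
                    tv[5], params.gamma_amps
                )
                sigma = (
                    base
                    + offset
                    + pucker
                    + weights * angle_term
                    + rng.normal(0.0, params.noise_sd, size=5)
                )
                delta = np.asarray(
                    [
                        reference_shift(s, reference, context=_reference_context(reference, rid, seq, nuc, catalog))
                        for s, nuc in zip(sigma, NUCLEI)
                    ]
                )
                records.append(
                    ShiftRecord(
                        rotamer_id=rid,
                        sequence=seq,
                        conformer=c,
                        origin="theoretical",
                        delta=delta,
                        sigma_comp=sigma,
                    )
                )
    return records


def _reference_context(
    scheme: ReferenceScheme, rotamer_id: str, sequence: str, nucleus: str,
    catalog: RotamerCatalog | None,
) -> str | None:
    if scheme.kind == "by_nucleus":
        return nucleus
    if scheme.kind == "by_sequence":
        return sequence
    if scheme.kind == "by_pucker_family":
        if catalog is None:
            raise ValueError("by_pucker_family referencing needs a catalog")
        return catalog.family_of(rotamer_id, "dd")
    return None


def generate_experimental_like(
    records: list[ShiftRecord],
    noise_sd: float = EXPERIMENTAL_NOISE_PPM,
    sparsity: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> list[ShiftRecord]:
    """Experimental-like copies of theoretical records.

    Adds i.i.d. Gaussian noise of sd ``noise_sd`` (ppm, default the 1.47
    theory-vs-experiment discrepancy) to each referenced shift, and
    subsamples records per ``sparsity`` (rotamer_id -> retention
    probability in [0, 1], or an integer count of records to keep).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sparsity:
        known = {r.rotamer_id for r in records}
        unknown = set(sparsity) - known
        if unknown:
            raise KeyError(f"sparsity profile names unknown rotamers: {sorted(unknown)}")
    out: list[ShiftRecord] = []
    by_rot: dict[str, list[ShiftRecord]] = {}
    for r in records:
        by_rot.setdefault(r.rotamer_id, []).append(r)
    for rid, recs in by_rot.items():
        keep = recs
        if sparsity is not None and rid in sparsity:
            level = sparsity[rid]
            if isinstance(level, (int, np.integer)) and level >= 1:
                idx = rng.choice(len(recs), size=min(int(level), len(recs)), replace=False)
                keep = [recs[i] for i in sorted(idx)]
            else:
                keep = [r for r in recs if rng.random() < float(level)]
        for r in keep:
            noisy = r.delta + rng.normal(0.0, noise_sd, size=5)
            out.append(
                ShiftRecord(
                    rotamer_id=r.rotamer_id,
                    sequence=r.sequence,
                    conformer=r.conformer,
                    origin="experimental-like",
                    delta=noisy,
                )
            )
    return out


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------

def records_to_frame(records: list[ShiftRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "rotamer_id": r.rotamer_id,
            "sequence": r.sequence,
            "conformer": r.conformer,
            "origin": r.origin,
        }
        row.update({n: v for n, v in zip(NUCLEI, r.delta)})
        if r.sigma_comp is not None:
            row.update({f"sigma_{n}": v for n, v in zip(NUCLEI, r.sigma_comp)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[ShiftRecord]:
    out = []
    has_sigma = all(f"sigma_{n}" in df.columns for n in NUCLEI)
    for _, row in df.iterrows():
        out.append(
            ShiftRecord(
                rotamer_id=str(row["rotamer_id"]),
                sequence=str(row["sequence"]),
                conformer=int(row["conformer"]),
                origin=str(row["origin"]),
                delta=np.array([row[n] for n in NUCLEI], dtype=float),
                sigma_comp=(
                    np.array([row[f"sigma_{n}"] for n in NUCLEI], dtype=float)
                    if has_sigma and not pd.isna(row.get(f"sigma_{NUCLEI[0]}"))
                    else None
                ),
            )
        )
    return out
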