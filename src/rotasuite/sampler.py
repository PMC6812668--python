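"""Rigid-geometry Monte-Carlo conformer sampling and entropy subsampling.

For each rotamer and dinucleotide template, suite torsions are drawn
independently from wrapped normal distributions (catalog mean and spread),
applied by rigid rotation about the torsion bond, and conformers with
steric clashes are rejected.  Shannon entropy of the retained torsion
distributions (5-degree histograms, summed over the seven torsions) is
used to pick how many conformers per rotamer are worth keeping: the
smallest subsample whose entropy reaches a cutoff fraction (default 80%)
of the full set's entropy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .catalog import TORSION_NAMES, RotamerDef
from .geometry import dihedral
from .nerf import rotation_about_axis
from .templates import DNTemplate

__all__ = [
    "ConformerSet",
    "set_torsion",
    "set_suite_torsions",
    "detect_clash",
    "sample_rotamer",
    "shannon_entropy",
    "entropy_curve",
    "select_sample_size",
]

logger = logging.getLogger(__name__)

#: Default fraction of van der Waals radius sum below which two atoms clash.
OVERLAP_FACTOR = 0.7
#: Attempts allowed per requested conformer before giving up.
ATTEMPT_FACTOR = 100
#: Histogram bin width (degrees) for torsion entropies.
BIN_WIDTH = 5.0


@dataclass
class ConformerSet:
    """Retained torsion vectors (and bookkeeping) for one rotamer/sequence."""

    rotamer_id: str
    sequence: str
    torsion_vectors: np.ndarray  # (n, 7) degrees
    n_generated: int
    n_clash_rejected: int
    partial: bool = False
    coordinates: list[np.ndarray] | None = field(default=None, repr=False)

    @property
    def n_retained(self) -> int:
        return len(self.torsion_vectors)


def set_torsion(
    template: DNTemplate, coords: np.ndarray, torsion: str, target: float
) -> np.ndarray:
    """Return coordinates with one suite torsion rotated to ``target`` degrees.

    The downstream rigid subtree rotates about the torsion's middle bond;
    all tree bond lengths and angles are untouched.
    """
    i, j, k, l = template.torsion_atoms[torsion]
    current = dihedral(coords[i], coords[j], coords[k], coords[l])
    delta = target - current
    if abs(((delta + 180.0) % 360.0) - 180.0) < 1e-12:
        return coords.copy()
    # a right-handed rotation of the downstream set about j->k increases
    # the measured torsion under the IUPAC sign convention
    axis = coords[k] - coords[j]
    rot = rotation_about_axis(axis, delta)
    moving = template.downstream_of(torsion)
    out = coords.copy()
    out[moving] = (out[moving] - coords[k]) @ rot.T + coords[k]
    return out


def set_suite_torsions(template: DNTemplate, targets) -> np.ndarray:
    """Apply all seven suite torsions (catalog order) to the template."""
    coords = template.coords.copy()
    for name, value in zip(TORSION_NAMES, targets):
        coords = set_torsion(template, coords, name, float(value))
    return coords


def detect_clash(
    coords: np.ndarray,
    graph_distances: np.ndarray,
    radii: np.ndarray,
    overlap_factor: float = OVERLAP_FACTOR,
    countable: np.ndarray | None = None,
) -> bool:
    """True iff some atom pair more than 3 bonds apart overlaps sterically.

    A pair clashes when its distance is below ``overlap_factor`` times the
    sum of the two van der Waals radii.  Pairs within 3 bonds (through the
    full bond graph, soft ring closures included) are never counted.  An
    optional boolean ``countable`` mask restricts scoring further (the
    sampler passes inter-residue pairs only; see
    :meth:`~rotasuite.templates.DNTemplate.countable_pairs`).
    """
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff * diff).sum(-1))
    cutoff = overlap_factor * (radii[:, None] + radii[None, :])
    mask = (graph_distances > 3) & (dist < cutoff)
    if countable is not None:
        mask &= countable
    return bool(np.triu(mask, 1).any())


def _wrapped_normal(rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray, n: int) -> np.ndarray:
    return (rng.normal(mean, sd, size=(n, len(mean)))) % 360.0


def sample_rotamer(
    template: DNTemplate,
    rotamer: RotamerDef,
    n_target: int,
    seed: int | np.random.Generator,
    overlap_factor: float = OVERLAP_FACTOR,
    keep_coordinates: bool = False,
    attempt_factor: int = ATTEMPT_FACTOR,
) -> ConformerSet:
    """Sample clash-free conformers of one rotamer on one DN template.

    Each torsion is drawn independently from a wrapped normal with the
    catalog mean and spread, applied by rigid rotation, and the conformer
    kept only if clash-free.  Stops at ``n_target`` retained or after
    ``attempt_factor * n_target`` attempts (then returns a partial set
    with ``partial=True``).  Deterministic for a fixed integer seed.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = np.asarray(rotamer.mean_torsions, dtype=float)
    sd = np.asarray(rotamer.spread_torsions, dtype=float)
    gdist = template.graph_distances()
    radii = template.vdw_radii()
    countable = template.countable_pairs()

    kept: list[np.ndarray] = []
    kept_coords: list[np.ndarray] = []
    n_generated = 0
    n_rejected = 0
    max_attempts = attempt_factor * n_target
    while len(kept) < n_target and n_generated < max_attempts:
        draw = _wrapped_normal(rng, mean, sd, 1)[0]
        n_generated += 1
        coords = set_suite_torsions(template, draw)
        if detect_clash(coords, gdist, radii, overlap_factor, countable):
            n_rejected += 1
            continue
        kept.append(draw)
        if keep_coordinates:
            kept_coords.append(coords)
    partial = len(kept) < n_target
    if partial:
        logger.warning(
            "rotamer %s/%s: only %d/%d conformers after %d attempts",
            rotamer.rotamer_id, template.sequence, len(kept), n_target, n_generated,
        )
    return ConformerSet(
        rotamer_id=rotamer.rotamer_id,
        sequence=template.sequence,
        torsion_vectors=np.array(kept) if kept else np.empty((0, 7)),
        n_generated=n_generated,
        n_clash_rejected=n_rejected,
        partial=partial,
        coordinates=kept_coords if keep_coordinates else None,
    )


# ---------------------------------------------------------------------------
# entropy-based subsample-size selection
# ---------------------------------------------------------------------------

def shannon_entropy(values, bin_width: float = BIN_WIDTH) -> float:
    """Shannon entropy S = -sum p_i ln p_i of an angle sample, in nats.

    Probabilities come from a normalized histogram over the fixed bins
    [0, w), [w, 2w), ..., [360-w, 360); empty bins contribute zero.
    """
    values = np.asarray(values, dtype=float) % 360.0
    if values.size == 0:
        raise ValueError("empty sample")
    edges = np.arange(0.0, 360.0 + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _total_entropy(torsion_vectors: np.ndarray, bin_width: float) -> float:
    # sum of the seven marginal per-torsion histogram entropies
    return sum(
        shannon_entropy(torsion_vectors[:, k], bin_width) for k in range(7)
    )


def entropy_curve(
    conformer_set: ConformerSet,
    sample_sizes,
    replicates: int = 50,
    seed: int | np.random.Generator = 0,
    bin_width: float = BIN_WIDTH,
) -> list[tuple[int, float, float, float]]:
    """Subsample entropy as a percentage of the full set's entropy.

    For each sample size n, draws ``replicates`` subsets without
    replacement and reports (n, mean %, min %, max %) of the total
    (seven-torsion) entropy relative to the full conformer set.
    """
    vectors = conformer_set.torsion_vectors
    full = _total_entropy(vectors, bin_width)
    if full <= 0:
        raise ValueError("full conformer set has zero entropy")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for n in sample_sizes:
        n = int(n)
        if n > len(vectors):
            raise ValueError(f"sample size {n} exceeds set size {len(vectors)}")
        if n == len(vectors):
            pct = [100.0] * replicates
        else:
            pct = []
            for _ in range(replicates):
                idx = rng.choice(len(vectors), size=n, replace=False)
                pct.append(100.0 * _total_entropy(vectors[idx], bin_width) / full)
        out.append((n, float(np.mean(pct)), float(np.min(pct)), float(np.max(pct))))
    return out


def select_sample_size(curve, cutoff_percent: float = 80.0) -> int:
    """Smallest sample size whose mean entropy fraction reaches the cutoff.

    Falls back to the largest size in the curve (with a warning) when no
    size reaches the cutoff.
    """
    if not curve:
        raise ValueError("empty entropy curve")
    for entry in sorted(curve, key=lambda e: e[0]):
        n, mean_pct = entry[0], entry[1]
        if mean_pct >= cutoff_percent:
            return int(n)
    largest = max(e[0] for e in curve)
    logger.warning(
        "no sample size reached %.1f%% of full entropy; using largest (%d)",
        cutoff_percent, largest,
    )
    return int(largest)
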