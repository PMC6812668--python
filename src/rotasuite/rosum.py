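"""ROSUM — the ROtamer SUbstitution Matrix — and weighted scoring.

Rotamer frequencies are highly uneven, and confusing two conformationally
adjacent rotamers is a lesser error than confusing two distant ones.
ROSUM, inspired by BLOSUM from protein alignment, weights each
(true, predicted) label pair by a Gaussian kernel of the circular
Euclidean distance between the rotamers' mean torsion vectors in the
seven-dimensional suite torsion space:

    W[a, b] = exp(-d(a, b)^2 / (2 * bandwidth^2))

so W is symmetric with unit diagonal and off-diagonal values in [0, 1).
The *weighted accuracy* of a prediction set is the mean of W[true, pred].
Rotamer frequencies enter through the random-choice baseline: the expected
weighted accuracy of a classifier that draws labels from the observed
frequency distribution, reported alongside every score.

One matrix exists per family scheme (family-to-family distances are
frequency-weighted means of member pairwise distances) plus one over the
46 rotamers themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from .catalog import RotamerCatalog
from .geometry import circular_distance

__all__ = [
    "RosumMatrix",
    "rotamer_distance",
    "build_rosum",
    "weighted_accuracy",
    "random_baseline",
    "standard_metrics",
]


def rotamer_distance(r1: str, r2: str, catalog: RotamerCatalog) -> float:
    """Circular Euclidean distance (degrees) between two rotamers' means."""
    a = catalog.lookup(r1).mean_torsions
    b = catalog.lookup(r2).mean_torsions
    return circular_distance(a, b)


@dataclass
class RosumMatrix:
    """Label-indexed substitution weights in [0, 1] with unit diagonal."""

    labels: list[str]
    weights: np.ndarray
    scheme_id: str | None  # None = the 46 rotamers themselves
    bandwidth: float
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square over labels")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("ROSUM must be symmetric")
        if not np.allclose(np.diag(self.weights), 1.0):
            raise ValueError("ROSUM diagonal must be exactly 1")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        try:
            return float(self.weights[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"label {exc} not in ROSUM") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.labels, columns=self.labels)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path, scheme_id: str | None = None, bandwidth: float = float("nan")) -> "RosumMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            labels=[str(c) for c in df.columns],
            weights=df.to_numpy(dtype=float),
            scheme_id=scheme_id,
            bandwidth=bandwidth,
        )


def _label_distances(catalog: RotamerCatalog, scheme_id: str | None) -> tuple[list[str], np.ndarray]:
    ids = catalog.rotamer_ids
    d46 = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if j > i:
                d46[i, j] = d46[j, i] = rotamer_distance(a, b, catalog)
    if scheme_id is None:
        return ids, d46
    fam = catalog.family_map(scheme_id)
    freqs = np.array([catalog.lookup(r).frequency for r in ids], dtype=float)
    labels = sorted(fam.labels())
    members = {lab: [i for i, r in enumerate(ids) if fam[r] == lab] for lab in labels}
    dist = np.zeros((len(labels), len(labels)))
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            if j <= i:
                continue
            # frequency-weighted mean pairwise distance between members
            ia, ib = members[la], members[lb]
            w = np.outer(freqs[ia], freqs[ib])
            dist[i, j] = dist[j, i] = float((w * d46[np.ix_(ia, ib)]).sum() / w.sum())
    return labels, dist


def build_rosum(
    catalog: RotamerCatalog,
    scheme_id: str | None = None,
    bandwidth: float | str = "auto",
) -> RosumMatrix:
    """Build the ROSUM for the 46 rotamers or for one family scheme.

    ``bandwidth="auto"`` uses the median off-diagonal label distance.
    The diagonal is exactly 1 regardless of bandwidth.
    """
    labels, dist = _label_distances(catalog, scheme_id)
    offdiag = dist[np.triu_indices(len(labels), k=1)]
    if bandwidth == "auto":
        bw = float(np.median(offdiag))
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ValueError("bandwidth must be > 0")
    weights = np.exp(-(dist**2) / (2.0 * bw**2))
    np.fill_diagonal(weights, 1.0)
    return RosumMatrix(labels=labels, weights=weights, scheme_id=scheme_id, bandwidth=bw)


def weighted_accuracy(y_true, y_pred, rosum: RosumMatrix) -> float:
    """Mean ROSUM weight over (true, predicted) label pairs, in [0, 1]."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label lists must have equal length")
    if not y_true:
        raise ValueError("empty label lists")
    return float(np.mean([rosum[t, p] for t, p in zip(y_true, y_pred)]))


def random_baseline(
    y_true,
    rosum: RosumMatrix,
    catalog: RotamerCatalog,
    scheme_id: str | None = None,
) -> float:
    """Expected weighted accuracy of frequency-weighted random prediction.

    The random-choice classifier draws each predicted label from the
    catalog frequency distribution (mapped through the family scheme);
    its expected score is sum_t p_test(t) sum_p q(p) W[t, p].
    """
    freqs = catalog.frequencies()
    q = np.zeros(len(rosum.labels))
    for rid, f in freqs.items():
        lab = rid if scheme_id is None else catalog.family_of(rid, scheme_id)
        q[rosum.labels.index(lab)] += f
    y_true = list(y_true)
    p_test = np.zeros(len(rosum.labels))
    for t in y_true:
        p_test[rosum.labels.index(t)] += 1.0 / len(y_true)
    return float(p_test @ rosum.weights @ q)


def standard_metrics(y_true, y_pred) -> tuple[float, float, float]:
    """Support-weighted (precision, recall, F1) over the label set.

    Per-label scores are averaged with weights equal to the true-label
    support; per-label F1 is the harmonic mean of precision and recall.
    Labels that are only predicted (never true) contribute zero precision
    by convention.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label lists must have equal length")
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="weighted", zero_division=0
    )
    return float(p), float(r), float(f1)
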