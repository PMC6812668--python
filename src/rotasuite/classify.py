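"""Classification of suites into rotamers/families and the three regimes.

Five classifier types (nearest-neighbour NN, decision tree DT, random
forest RF, multi-layer perceptron MLP, support-vector machine SVM) plus a
frequency-weighted random-choice baseline (RAND) are trained on 5-vectors
of ribose carbon shifts, optionally augmented with a one-hot dinucleotide
sequence encoding (16 indicators), and evaluated under three regimes:

``exp_vs_theo``
    train on the theoretical set, score the experimental-like set once;
``theo_vs_theo`` / ``exp_vs_exp``
    leave-one-out cross-validation within one dataset (a single suite is
    held out at every iteration).

Scores: ROSUM-weighted accuracy, support-weighted precision/recall/F1, and
the random baseline's expected weighted accuracy.

A statsmodels-flavoured front is provided: build a
:class:`SuiteShiftClassifier` from records or a DataFrame, call ``fit()``,
and read the scores off the returned :class:`ClassificationResults`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .catalog import RotamerCatalog
from .rosum import RosumMatrix, random_baseline, standard_metrics, weighted_accuracy
from .shifts import NUCLEI, EXPERIMENTAL_NOISE_PPM, ShiftRecord, generate_experimental_like

__all__ = [
    "CLASSIFIER_NAMES",
    "DEFAULT_GRIDS",
    "EvalReport",
    "RandomChoiceClassifier",
    "featurize",
    "make_classifier",
    "run_regime",
    "hyperparameter_sweep",
    "sparsity_experiment",
    "noise_experiment",
    "SuiteShiftClassifier",
    "ClassificationResults",
]

CLASSIFIER_NAMES = ("NN", "DT", "RF", "MLP", "SVM", "RAND")

_SEQUENCES = tuple(a + b for a in "ACGU" for b in "ACGU")

#: Small documented hyperparameter grids swept per classifier.
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "NN": [{"n_neighbors": k} for k in (1, 3, 5, 7)],
    "DT": [{"max_depth": d} for d in (3, 10, None)],
    "RF": [{"n_estimators": 100}],
    "MLP": [{"hidden_layer_sizes": (h,)} for h in (10, 50)],
    "SVM": [{"C": c} for c in (1.0, 10.0)],
    "RAND": [{}],
}


class RandomChoiceClassifier(BaseEstimator, ClassifierMixin):
    """Baseline: predict labels drawn from the training label frequencies."""

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        self.p_ = counts / counts.sum()
        return self

    def predict(self, X):
        rng = np.random.default_rng(self.random_state)
        return rng.choice(self.classes_, size=len(X), p=self.p_)


def make_classifier(name: str, seed: int = 0, **hyperparams):
    """A scaler+classifier pipeline for one of the six classifier names."""
    if name == "NN":
        clf = KNeighborsClassifier(**{"n_neighbors": 3, **hyperparams})
    elif name == "DT":
        clf = DecisionTreeClassifier(random_state=seed, **hyperparams)
    elif name == "RF":
        clf = RandomForestClassifier(
            random_state=seed, **{"n_estimators": 100, **hyperparams}
        )
    elif name == "MLP":
        clf = MLPClassifier(
            random_state=seed,
            max_iter=500,
            **{"hidden_layer_sizes": (10,), **hyperparams},
        )
    elif name == "SVM":
        clf = SVC(random_state=seed, **{"kernel": "rbf", "C": 1.0, **hyperparams})
    elif name == "RAND":
        clf = RandomChoiceClassifier(random_state=seed)
    else:
        raise ValueError(f"unknown classifier {name!r}; valid: {CLASSIFIER_NAMES}")
    # shifts are standardized with training-set statistics only (the
    # pipeline refits the scaler inside every fold)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def featurize(
    records: list[ShiftRecord],
    catalog: RotamerCatalog,
    scheme_id: str | None = None,
    use_sequence: bool = True,
) -> tuple[np.ndarray, list[str], int]:
    """Feature matrix and labels for a record list.

    Features: the 5 shifts, plus a 16-column one-hot dinucleotide encoding
    when ``use_sequence`` (dimension 21).  Labels are rotamer ids, mapped
    through ``scheme_id`` when given.  Records with missing shifts are
    dropped and counted; returns (X, y, n_dropped).
    """
    rows, labels = [], []
    n_dropped = 0
    for r in records:
        if r.delta is None or not np.all(np.isfinite(r.delta)):
            n_dropped += 1
            continue
        feat = list(r.delta)
        if use_sequence:
            feat.extend(1.0 if r.sequence == s else 0.0 for s in _SEQUENCES)
        rows.append(feat)
        labels.append(
            r.rotamer_id if scheme_id is None else catalog.family_of(r.rotamer_id, scheme_id)
        )
    return np.asarray(rows, dtype=float), labels, n_dropped


@dataclass
class EvalReport:
    """Scores of one classifier on one regime/scheme, JSON-serializable."""

    regime: str
    scheme_id: str | None
    classifier: str
    hyperparams: dict
    weighted_accuracy: float
    precision: float
    recall: float
    f1: float
    baseline_weighted_accuracy: float
    n_train: int
    n_test: int
    seed: int
    config_digest: str = ""

    def __post_init__(self) -> None:
        for name in ("weighted_accuracy", "precision", "recall", "f1",
                     "baseline_weighted_accuracy"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_test <= 0:
            raise ValueError("n_test must be positive")
        if not self.config_digest:
            payload = {
                k: v for k, v in asdict(self).items() if k != "config_digest"
            }
            blob = json.dumps(payload, sort_keys=True, default=str)
            self.config_digest = hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(**d)


def _loo_predictions(pipe: Pipeline, X: np.ndarray, y: list[str]) -> list[str]:
    # leave-one-out: a unique suite is held out at every iteration
    preds = []
    idx = np.arange(len(y))
    y_arr = np.asarray(y)
    for i in idx:
        mask = idx != i
        model = clone(pipe)
        model.fit(X[mask], y_arr[mask])
        preds.append(str(model.predict(X[i : i + 1])[0]))
    return preds


def run_regime(
    regime: str,
    train_records: list[ShiftRecord],
    test_records: list[ShiftRecord],
    scheme_id: str | None,
    classifier: str,
    rosum: RosumMatrix,
    catalog: RotamerCatalog,
    seed: int = 0,
    use_sequence: bool = True,
    hyperparams: dict | None = None,
) -> EvalReport:
    """Evaluate one classifier under one regime.

    ``exp_vs_theo`` fits once on the training set and scores the test set;
    the LOO regimes (``theo_vs_theo``, ``exp_vs_exp``) require
    ``train_records is test_records`` and cross-validate leave-one-out.
    """
    hyperparams = hyperparams or {}
    if regime not in ("exp_vs_theo", "theo_vs_theo", "exp_vs_exp"):
        raise ValueError(f"unknown regime {regime!r}")
    pipe = make_classifier(classifier, seed=seed, **hyperparams)
    X_tr, y_tr, _ = featurize(train_records, catalog, scheme_id, use_sequence)
    if regime == "exp_vs_theo":
        X_te, y_te, _ = featurize(test_records, catalog, scheme_id, use_sequence)
        pipe.fit(X_tr, y_tr)
        y_pred = [str(p) for p in pipe.predict(X_te)]
    else:
        if train_records is not test_records:
            raise ValueError(f"{regime} is leave-one-out: train and test must be the same set")
        X_te, y_te = X_tr, y_tr
        y_pred = _loo_predictions(pipe, X_tr, y_tr)
    missing = set(y_te) - set(rosum.labels)
    if missing:
        raise ValueError(f"test labels absent from ROSUM: {sorted(missing)}")
    wacc = weighted_accuracy(y_te, y_pred, rosum)
    prec, rec, f1 = standard_metrics(y_te, y_pred)
    base = random_baseline(y_te, rosum, catalog, scheme_id)
    return EvalReport(
        regime=regime,
        scheme_id=scheme_id,
        classifier=classifier,
        hyperparams=hyperparams,
        weighted_accuracy=wacc,
        precision=prec,
        recall=rec,
        f1=f1,
        baseline_weighted_accuracy=base,
        n_train=len(y_tr),
        n_test=len(y_te),
        seed=seed,
    )


def hyperparameter_sweep(
    regime: str,
    train_records: list[ShiftRecord],
    test_records: list[ShiftRecord],
    scheme_id: str | None,
    rosum: RosumMatrix,
    catalog: RotamerCatalog,
    grids: dict[str, list[dict]] | None = None,
    seed: int = 0,
    use_sequence: bool = True,
) -> tuple[list[EvalReport], dict[str, EvalReport]]:
    """One report per (classifier, grid point); best-per-classifier by F1."""
    grids = grids or DEFAULT_GRIDS
    reports: list[EvalReport] = []
    best: dict[str, EvalReport] = {}
    for name, grid in grids.items():
        for hp in grid:
            rep = run_regime(
                regime, train_records, test_records, scheme_id, name, rosum,
                catalog, seed=seed, use_sequence=use_sequence, hyperparams=hp,
            )
            reports.append(rep)
            if name not in best or rep.f1 > best[name].f1:
                best[name] = rep
    return reports, best


def sparsity_experiment(
    theoretical: list[ShiftRecord],
    sparsity: dict[str, float],
    scheme_id: str | None,
    rosum: RosumMatrix,
    catalog: RotamerCatalog,
    classifier: str = "NN",
    seed: int = 0,
) -> tuple[EvalReport, EvalReport]:
    """LOO on the full vs a sparsified theoretical set.

    The sparsity profile mimics the uneven rotamer coverage of
    experimental archives; returns (full_report, sparse_report) so the
    score delta attributable to sparsity alone can be read off.
    """
    sparse = generate_experimental_like(
        theoretical, noise_sd=0.0, sparsity=sparsity, seed=seed
    )
    full_rep = run_regime(
        "theo_vs_theo", theoretical, theoretical, scheme_id, classifier,
        rosum, catalog, seed=seed,
    )
    sparse_rep = run_regime(
        "theo_vs_theo", sparse, sparse, scheme_id, classifier, rosum,
        catalog, seed=seed,
    )
    return full_rep, sparse_rep


def noise_experiment(
    theoretical: list[ShiftRecord],
    noise_sd: float = EXPERIMENTAL_NOISE_PPM,
    scheme_id: str | None = None,
    rosum: RosumMatrix | None = None,
    catalog: RotamerCatalog | None = None,
    classifier: str = "NN",
    seed: int = 0,
) -> tuple[EvalReport, EvalReport]:
    """Train on clean theoretical records, test on noise-added copies.

    Returns (control_report, noisy_report) where the control tests on the
    unperturbed records; the gap shows how the theory-vs-experiment
    discrepancy alone (default 1.47 ppm) erodes classification.
    """
    noisy = generate_experimental_like(theoretical, noise_sd=noise_sd, seed=seed)
    clean = generate_experimental_like(theoretical, noise_sd=0.0, seed=seed)
    control = run_regime(
        "exp_vs_theo", theoretical, clean, scheme_id, classifier, rosum,
        catalog, seed=seed,
    )
    noisy_rep = run_regime(
        "exp_vs_theo", theoretical, noisy, scheme_id, classifier, rosum,
        catalog, seed=seed,
    )
    return control, noisy_rep


# ---------------------------------------------------------------------------
# model-object front
# ---------------------------------------------------------------------------

class SuiteShiftClassifier:
    """Model object: shift records -> rotamer/family classification.

    Parameters mirror :func:`run_regime`; ``fit`` evaluates the configured
    regime and returns a :class:`ClassificationResults`.
    """

    def __init__(
        self,
        train_records: list[ShiftRecord],
        catalog: RotamerCatalog,
        scheme_id: str | None = None,
        classifier: str = "NN",
        rosum: RosumMatrix | None = None,
        use_sequence: bool = True,
        seed: int = 0,
        **hyperparams,
    ):
        from .rosum import build_rosum

        self.train_records = train_records
        self.catalog = catalog
        self.scheme_id = scheme_id
        self.classifier = classifier
        self.rosum = rosum or build_rosum(catalog, scheme_id)
        self.use_sequence = use_sequence
        self.seed = seed
        self.hyperparams = hyperparams

    @classmethod
    def from_dataframe(cls, df, catalog: RotamerCatalog, **kwargs) -> "SuiteShiftClassifier":
        from .shifts import frame_to_records

        return cls(frame_to_records(df), catalog, **kwargs)

    def fit(
        self,
        regime: str = "theo_vs_theo",
        test_records: list[ShiftRecord] | None = None,
    ) -> "ClassificationResults":
        if regime == "exp_vs_theo":
            if test_records is None:
                raise ValueError("exp_vs_theo needs test_records")
            test = test_records
        else:
            test = self.train_records
        report = run_regime(
            regime, self.train_records, test, self.scheme_id, self.classifier,
            self.rosum, self.catalog, seed=self.seed,
            use_sequence=self.use_sequence, hyperparams=self.hyperparams,
        )
        return ClassificationResults(self, report)


@dataclass
class ClassificationResults:
    """Fitted-evaluation results wrapper with a printable summary."""

    model: SuiteShiftClassifier
    report: EvalReport

    @property
    def weighted_accuracy(self) -> float:
        return self.report.weighted_accuracy

    @property
    def f1(self) -> float:
        return self.report.f1

    def summary(self) -> str:
        r = self.report
        scheme = r.scheme_id or "46 rotamers"
        lines = [
            "Suite shift classification results",
            "=" * 44,
            f"{'regime:':<22}{r.regime}",
            f"{'grouping:':<22}{scheme}",
            f"{'classifier:':<22}{r.classifier} {r.hyperparams or ''}",
            f"{'n train / test:':<22}{r.n_train} / {r.n_test}",
            "-" * 44,
            f"{'weighted accuracy:':<22}{r.weighted_accuracy:.3f}",
            f"{'precision:':<22}{r.precision:.3f}",
            f"{'recall:':<22}{r.recall:.3f}",
            f"{'F1 score:':<22}{r.f1:.3f}",
            f"{'random baseline:':<22}{r.baseline_weighted_accuracy:.3f}",
            "-" * 44,
            f"seed={r.seed}  config={r.config_digest}",
        ]
        return "\n".join(lines)
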