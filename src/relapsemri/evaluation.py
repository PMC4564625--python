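"""Leave-one-patient-out evaluation of the classifier bank.

Each patient is held out in turn; classifiers train on the labeled
(at-or-after-decision) sessions of the remaining patients and predict
every session of the held-out patient independently.  Predictions are
scored against the patient's eventual clinical decision at every offset
— including pre-decision sessions, which is exactly the early-prediction
question — then pooled across folds into a per-offset balanced-error
series and summarised by the weighted BER.

Two dataset variants are supported: ``complete`` restricts training and
testing to fully observed sessions; ``imputed`` fills missing values
with the volume-conditioned imputer, fitted per fold on the training
patients' labeled sessions only (no leakage from the held-out patient).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cohort import Cohort, PatientRecord, modality_subset, select_complete
from .imputation import fit_imputer, impute_cohort, impute_point
from .metrics import BerSeries, balanced_error_rate, weighted_ber
from .schema import FeatureSchema, UNLABELED

logger = logging.getLogger(__name__)

FAMILIES = (
    "knn",
    "dlda",
    "svm",
    "classification_tree",
    "neural_net",
    "random_forest",
    "boosting",
)
SVM_VARIANTS = ("linear", "polynomial", "rbf", "sigmoid")
BOOST_VARIANTS = ("adaboost", "logitboost", "gentleboost", "robustboost")

#: families whose decision rules are scale-sensitive and get a z-scoring
#: step fit on the training fold; tree ensembles are scale-invariant
STANDARDIZED_FAMILIES = frozenset({"knn", "dlda", "svm", "neural_net"})


class EvaluationError(ValueError):
    pass


class PooledPinvLDA(BaseEstimator, ClassifierMixin):
    """Linear discriminant with the pseudoinverse of the pooled covariance.

    Discriminant scores use class means and the Moore-Penrose
    pseudoinverse of the pooled within-class covariance, which stays
    defined when the covariance is singular (more features than labeled
    sessions is the norm here).
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise EvaluationError("training labels contain a single class")
        means = []
        pooled = np.zeros((X.shape[1], X.shape[1]))
        for cls in self.classes_:
            Xc = X[y == cls]
            mu = Xc.mean(axis=0)
            means.append(mu)
            pooled += (Xc - mu).T @ (Xc - mu)
        pooled /= max(1, len(X) - len(self.classes_))
        self.means_ = np.array(means)
        self.pinv_cov_ = np.linalg.pinv(pooled)
        self.priors_ = np.array([np.mean(y == c) for c in self.classes_])
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        scores = []
        for mu, prior in zip(self.means_, self.priors_):
            w = self.pinv_cov_ @ mu
            scores.append(X @ w - 0.5 * mu @ w + np.log(prior))
        return self.classes_[np.argmax(np.column_stack(scores), axis=1)]


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family, subtype and its fixed hyperparameters.

    Defaults follow the study conditions: 3-NN with correlation
    distance, 100-tree forests and boosting ensembles, 10 hidden units.
    """

    family: str
    variant: str | None = None
    hyperparameters: dict = field(default_factory=dict)
    #: true when the family maps onto a neighbouring algorithm rather
    #: than an exact open implementation (e.g. robust boosting)
    substituted: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise EvaluationError(f"unknown classifier family {self.family!r}")
        if self.family == "svm" and self.variant not in SVM_VARIANTS:
            raise EvaluationError(f"unknown SVM kernel {self.variant!r}")
        if self.family == "boosting" and self.variant not in BOOST_VARIANTS:
            raise EvaluationError(f"unknown boosting variant {self.variant!r}")

    @property
    def name(self) -> str:
        return self.family if self.variant is None else f"{self.family}-{self.variant}"

    @property
    def standardize(self) -> bool:
        return self.family in STANDARDIZED_FAMILIES


def build_estimator(spec: ClassifierSpec, random_state: int):
    """Instantiate the sklearn estimator behind a spec (with scaling where due)."""
    hp = spec.hyperparameters
    if spec.family == "knn":
        est = KNeighborsClassifier(
            n_neighbors=hp.get("k", 3),
            metric=hp.get("distance", "correlation"),
            algorithm="brute",
        )
    elif spec.family == "dlda":
        est = PooledPinvLDA()
    elif spec.family == "svm":
        est = SVC(kernel=spec.variant, random_state=random_state)
    elif spec.family == "classification_tree":
        est = DecisionTreeClassifier(random_state=random_state)
    elif spec.family == "neural_net":
        est = MLPClassifier(
            hidden_layer_sizes=(hp.get("hidden_units", 10),),
            max_iter=1000,
            random_state=random_state,
        )
    elif spec.family == "random_forest":
        est = RandomForestClassifier(
            n_estimators=hp.get("n_trees", 100), random_state=random_state
        )
    elif spec.family == "boosting":
        n = hp.get("n_trees", 100)
        if spec.variant == "adaboost":
            est = AdaBoostClassifier(n_estimators=n, random_state=random_state)
        elif spec.variant == "logitboost":
            est = GradientBoostingClassifier(
                loss="log_loss", n_estimators=n, random_state=random_state
            )
        elif spec.variant == "gentleboost":
            est = GradientBoostingClassifier(
                loss="exponential", n_estimators=n, random_state=random_state
            )
        else:  # robust boosting stand-in
            est = HistGradientBoostingClassifier(
                max_iter=n, random_state=random_state
            )
    else:  # pragma: no cover - guarded by __post_init__
        raise EvaluationError(f"unknown family {spec.family!r}")
    if spec.standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


#: the study's six best-performing supervised classifiers
DEFAULT_BANK: tuple[ClassifierSpec, ...] = (
    ClassifierSpec("random_forest"),
    ClassifierSpec("dlda"),
    ClassifierSpec("svm", "linear"),
    ClassifierSpec("boosting", "logitboost"),
    ClassifierSpec("boosting", "robustboost", substituted=True),
    ClassifierSpec("svm", "sigmoid"),
)

FULL_BANK: tuple[ClassifierSpec, ...] = DEFAULT_BANK + (
    ClassifierSpec("knn"),
    ClassifierSpec("classification_tree"),
    ClassifierSpec("neural_net"),
    ClassifierSpec("svm", "polynomial"),
    ClassifierSpec("svm", "rbf"),
    ClassifierSpec("boosting", "adaboost"),
    ClassifierSpec("boosting", "gentleboost"),
)


@dataclass
class FoldResult:
    """Per-timepoint predictions for one held-out patient."""

    test_patient_id: str
    predictions: list[tuple[int, str, str]] = field(default_factory=list)
    """(offset, truth, predicted) triples; truth is the decision class."""


@dataclass
class EvaluationReport:
    classifier: str
    variant: str
    features: str
    series: BerSeries
    wber: float
    substituted: bool = False


def lopo_folds(cohort: Cohort) -> list[tuple[Cohort, PatientRecord]]:
    """One (train cohort, held-out patient) pair per patient."""
    if len(cohort.patients) < 2:
        raise EvaluationError("leave-one-patient-out needs at least 2 patients")
    folds = []
    for patient in cohort.patients:
        train = Cohort(
            cohort.schema,
            [p for p in cohort.patients if p.patient_id != patient.patient_id],
        )
        folds.append((train, patient))
    return folds


def _training_matrix(
    train: Cohort, indices: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    rows, labels = [], []
    for tp in train.iter_timepoints():
        if tp.label == UNLABELED or not tp.is_complete:
            continue
        rows.append(tp.features[list(indices)])
        labels.append(tp.label)
    if not rows:
        raise EvaluationError("no labeled complete training sessions")
    return np.array(rows), np.array(labels)


def train_and_predict(
    spec: ClassifierSpec,
    train: Cohort,
    test: PatientRecord,
    feature_indices: Sequence[int] | None = None,
    random_state: int = 0,
) -> FoldResult:
    """Fit on the training cohort's labeled sessions, predict the test patient.

    Every eligible (fully observed) test session is classified
    independently; the truth for every session is the patient's eventual
    decision class.  Raises if the training labels are single-class.
    """
    indices = (
        list(feature_indices)
        if feature_indices is not None
        else list(range(len(train.schema.names)))
    )
    X, y = _training_matrix(train, indices)
    if len(np.unique(y)) < 2:
        raise EvaluationError(
            f"fold {test.patient_id!r}: training labels contain a single class"
        )
    result = FoldResult(test_patient_id=test.patient_id)
    eligible = [tp for tp in test.timepoints if tp.is_complete]
    if not eligible:
        logger.info(
            "patient %s: no eligible session, empty fold", test.patient_id
        )
        return result
    est = build_estimator(spec, random_state)
    est.fit(X, y)
    X_test = np.array([tp.features[indices] for tp in eligible])
    predicted = est.predict(X_test)
    for tp, pred in zip(eligible, predicted):
        result.predictions.append((tp.offset, test.decision_class, str(pred)))
    return result


def pool_folds(folds: Iterable[FoldResult]) -> BerSeries:
    """Pool per-fold predictions into a per-offset BER series."""
    by_offset: dict[int, list[tuple[str, str]]] = {}
    for fold in folds:
        for offset, truth, pred in fold.predictions:
            by_offset.setdefault(offset, []).append((truth, pred))
    series = BerSeries()
    for offset, pairs in by_offset.items():
        truth = [t for t, _ in pairs]
        pred = [p for _, p in pairs]
        series.add(offset, balanced_error_rate(truth, pred), len(pairs))
    return series


def _prepare_fold(
    train: Cohort, test: PatientRecord, variant: str
) -> tuple[Cohort, PatientRecord]:
    if variant == "complete":
        return select_complete(train), test
    if variant != "imputed":
        raise EvaluationError(f"unknown variant {variant!r}")
    schema = train.schema
    assert isinstance(schema, FeatureSchema)
    labeled = [
        tp for tp in train.iter_timepoints() if tp.label != UNLABELED
    ]
    model = fit_imputer(labeled, schema)
    train_imp = impute_cohort(train, model)
    test_imp = PatientRecord(
        patient_id=test.patient_id,
        decision_class=test.decision_class,
        decision_session=test.decision_session,
        timepoints=[impute_point(tp, model, schema) for tp in test.timepoints],
    )
    return train_imp, test_imp


def evaluate(
    cohort: Cohort,
    spec: ClassifierSpec,
    features: str = "all",
    variant: str = "complete",
    seed: int = 0,
) -> EvaluationReport:
    """Full LOPO evaluation of one classifier on one dataset variant.

    The imputer (imputed variant) is refitted inside every fold on the
    training patients' labeled sessions.  Feature subsetting to a single
    modality happens after imputation, since the imputer conditions on
    the region volumes.  Deterministic given ``seed``.
    """
    root = np.random.SeedSequence(
        [seed, zlib.crc32(spec.name.encode()) % (2**31)]
    )
    fold_seeds = root.generate_state(len(cohort.patients))
    results = []
    for (train, test), fold_seed in zip(lopo_folds(cohort), fold_seeds):
        train_v, test_v = _prepare_fold(train, test, variant)
        if features != "all":
            train_v = modality_subset(train_v, features)
            sub_indices = train_v.schema.indices
        else:
            sub_indices = None
        if features != "all":
            test_v = PatientRecord(
                test_v.patient_id,
                test_v.decision_class,
                test_v.decision_session,
                [
                    _subset_timepoint(tp, sub_indices)
                    for tp in test_v.timepoints
                ],
            )
            sub_indices = None  # already applied
        results.append(
            train_and_predict(
                spec,
                train_v,
                test_v,
                feature_indices=sub_indices,
                random_state=int(fold_seed % (2**31)),
            )
        )
    series = pool_folds(results)
    return EvaluationReport(
        classifier=spec.name,
        variant=variant,
        features=features,
        series=series,
        wber=weighted_ber(series),
        substituted=spec.substituted,
    )


def _subset_timepoint(tp, indices):
    from dataclasses import replace

    idx = list(indices)
    return replace(
        tp,
        features=tp.features[idx].copy(),
        missing_mask=tp.missing_mask[idx].copy(),
    )


def compare_classifiers(
    cohort: Cohort,
    specs: Sequence[ClassifierSpec] = DEFAULT_BANK,
    seed: int = 0,
    features: str = "all",
    mark_best: int = 6,
) -> pd.DataFrame:
    """Weighted BER per classifier on complete and imputed data.

    Returns one row per classifier with columns ``complete``,
    ``imputed`` and their ``average``; the ``best`` column flags the
    ``mark_best`` lowest averages.
    """
    if not specs:
        raise EvaluationError("need at least one classifier spec")
    rows = []
    for spec in specs:
        complete = evaluate(cohort, spec, features, "complete", seed)
        imputed = evaluate(cohort, spec, features, "imputed", seed)
        rows.append(
            {
                "classifier": spec.name,
                "complete": complete.wber,
                "imputed": imputed.wber,
                "average": (complete.wber + imputed.wber) / 2,
            }
        )
    table = pd.DataFrame(rows).set_index("classifier")
    cutoff = table["average"].nsmallest(min(mark_best, len(table))).max()
    table["best"] = table["average"] <= cutoff
    return table
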