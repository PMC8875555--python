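"""Classifier training, model selection and library screening.

Actives and decoys become a labelled fingerprint matrix; seven classifier
families (KNN, Naive Bayes, Logistic Regression, Decision Tree, Random
Forest, MLP, XGBoost) are evaluated by repeated stratified k-fold
cross-validation; the model with the best mean MCC wins (ties go to the
simpler family); the final model is refit on everything and used to screen a
library, reporting for every hit its positive-class probability and its
nearest training active by Tanimoto similarity.  An external-validation
workflow removes training actives too similar to an annotated external set
(and their linked decoys), retrains, and tabulates true/false positives.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .decoys import DecoySet
from .library import MoleculeRecord
from .metrics import MetricSet, compute_metrics
from .similarity import fingerprints, tanimoto_matrix

logger = logging.getLogger(__name__)

ALGORITHMS = ("KNN", "NB", "Logit", "DT", "RF", "MLP", "XGBoost")

#: ascending effective-parameter count, used only to break exact MCC ties —
#: a simpler model raises fewer overfitting concerns
SIMPLICITY_ORDER = ("NB", "Logit", "KNN", "DT", "RF", "XGBoost", "MLP")


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family paired with a fingerprint kind and a seed."""

    algorithm: str = "Logit"
    fingerprint_kind: str = "ECFP4"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.fingerprint_kind not in ("ECFP4", "ECFP6", "MACCS"):
            raise ValueError(f"bad fingerprint kind {self.fingerprint_kind!r}")


def build_estimator(spec: ModelSpec):
    """Instantiate the sklearn/xgboost estimator for a ModelSpec.

    Framework defaults apply unless overridden in ``hyperparameters``; the
    only deviations from bare defaults are iteration caps raised enough to
    converge on fingerprint data.
    """
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.algorithm == "KNN":
        return KNeighborsClassifier(**hp)
    if spec.algorithm == "NB":
        return BernoulliNB(**hp)
    if spec.algorithm == "Logit":
        return LogisticRegression(max_iter=hp.pop("max_iter", 1000), **hp)
    if spec.algorithm == "DT":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if spec.algorithm == "RF":
        return RandomForestClassifier(random_state=seed, **hp)
    if spec.algorithm == "MLP":
        return MLPClassifier(random_state=seed, max_iter=hp.pop("max_iter", 400), **hp)
    if spec.algorithm == "XGBoost":
        return XGBClassifier(random_state=seed, eval_metric="logloss", **hp)
    raise ValueError(spec.algorithm)


class FingerprintFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: SMILES sequence -> fingerprint bit matrix."""

    def __init__(self, fingerprint_kind: str = "ECFP4"):
        self.fingerprint_kind = fingerprint_kind

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        fps = fingerprints(list(X), self.fingerprint_kind)
        return np.stack([fp.bits for fp in fps]).astype(np.uint8)


class FingerprintClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style classifier over molecular fingerprints.

    Accepts either a precomputed 0/1 fingerprint matrix or a sequence of
    SMILES strings (featurized internally with ``fingerprint_kind``).  The
    positive class is 1 (active); ``predict_proba`` exposes the screening
    probability p.
    """

    def __init__(
        self,
        algorithm: str = "Logit",
        fingerprint_kind: str = "ECFP4",
        hyperparameters: Mapping[str, object] | None = None,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.fingerprint_kind = fingerprint_kind
        self.hyperparameters = hyperparameters
        self.random_state = random_state

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(
            algorithm=self.algorithm,
            fingerprint_kind=self.fingerprint_kind,
            hyperparameters=self.hyperparameters or {},
            seed=self.random_state,
        )

    def _featurize(self, X) -> np.ndarray:
        if len(X) > 0 and isinstance(X[0], str):
            return FingerprintFeaturizer(self.fingerprint_kind).fit_transform(X)
        return np.asarray(X)

    def fit(self, X, y):
        X = self._featurize(X)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.estimator_ = build_estimator(self.spec)
        self.estimator_.fit(X, y)
        self.classes_ = np.asarray(self.estimator_.classes_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(self._featurize(X))

    def positive_probability(self, X) -> np.ndarray:
        """Probability of the active class."""
        proba = self.predict_proba(X)
        pos_col = int(np.flatnonzero(self.classes_ == 1)[0])
        return proba[:, pos_col]

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(self._featurize(X))


@dataclass
class Dataset:
    """Labelled fingerprint matrix with molecule ids, rows shuffled under seed."""

    X: np.ndarray
    y: np.ndarray
    ids: list[str]
    fingerprint_kind: str

    def data_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.X.tobytes())
        h.update(self.y.tobytes())
        h.update("\n".join(self.ids).encode())
        return h.hexdigest()


def assemble_dataset(
    actives: Sequence[MoleculeRecord],
    inactives: Sequence[MoleculeRecord],
    fingerprint_kind: str = "ECFP4",
    seed: int = 0,
) -> Dataset:
    """Fingerprint actives (label 1) and inactives (label 0) into one matrix."""
    if not actives or not inactives:
        raise ValueError("both classes must be non-empty")
    dup = {a.molecule_id for a in actives} & {i.molecule_id for i in inactives}
    if dup:
        raise ValueError(f"molecule ids present in both classes: {sorted(dup)[:5]}")
    records = list(actives) + list(inactives)
    fps = fingerprints([r.smiles for r in records], fingerprint_kind)
    X = np.stack([fp.bits for fp in fps]).astype(np.uint8)
    y = np.array([1] * len(actives) + [0] * len(inactives), dtype=int)
    ids = [r.molecule_id for r in records]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    return Dataset(
        X=X[perm], y=y[perm], ids=[ids[i] for i in perm],
        fingerprint_kind=fingerprint_kind,
    )


@dataclass
class CVReport:
    """Per-fold metrics plus aggregates for one classifier/fingerprint pair."""

    model_spec: ModelSpec
    folds: list[MetricSet]

    def _values(self, metric: str) -> np.ndarray:
        vals = [getattr(m, metric) for m in self.folds]
        return np.array([v for v in vals if v is not None], dtype=float)

    def mean(self, metric: str) -> float:
        return float(self._values(metric).mean())

    def sd(self, metric: str) -> float:
        return float(self._values(metric).std(ddof=1))

    def summary(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for metric in ("acc", "auc", "mcc"):
            out[f"{metric}_mean"] = self.mean(metric)
            out[f"{metric}_sd"] = self.sd(metric)
        return out


def cross_validate(
    dataset: Dataset,
    model_spec: ModelSpec,
    k: int = 5,
    runs: int = 5,
) -> CVReport:
    """Repeated stratified k-fold cross-validation (k folds x independent runs).

    Each run reshuffles the data into k stratified blocks; each fold trains on
    k-1 blocks and evaluates ACC/AUC/MCC on the held-out block.  Deterministic
    under the model spec's seed.
    """
    counts = np.bincount(dataset.y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs at least k={k} members for stratified folds, "
            f"got {counts.tolist()}"
        )
    folds: list[MetricSet] = []
    base = build_estimator(model_spec)
    for run in range(runs):
        splitter = StratifiedKFold(
            n_splits=k, shuffle=True,
            random_state=(model_spec.seed + 1_000_003 * run) % (2**31),
        )
        for train_idx, val_idx in splitter.split(dataset.X, dataset.y):
            est = clone(base)
            est.fit(dataset.X[train_idx], dataset.y[train_idx])
            proba = est.predict_proba(dataset.X[val_idx])
            pos_col = int(np.flatnonzero(np.asarray(est.classes_) == 1)[0])
            scores = proba[:, pos_col]
            pred = est.predict(dataset.X[val_idx])
            folds.append(compute_metrics(dataset.y[val_idx], pred, scores))
    return CVReport(model_spec=model_spec, folds=folds)


def select_model(reports: Sequence[CVReport]) -> ModelSpec:
    """Pick the spec with the highest mean MCC; exact ties go to the simpler
    algorithm (NB < Logit < KNN < DT < RF < XGBoost < MLP)."""
    if not reports:
        raise ValueError("no CV reports to select from")
    rank = {alg: i for i, alg in enumerate(SIMPLICITY_ORDER)}
    best = max(
        reports,
        key=lambda r: (r.mean("mcc"), -rank[r.model_spec.algorithm]),
    )
    return best.model_spec


@dataclass
class TrainedModel:
    """A final model fitted on all data, with a provenance manifest."""

    classifier: FingerprintClassifier
    training_actives: list[MoleculeRecord]
    manifest: dict

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        import joblib

        return joblib.load(path)


def train_final(
    dataset: Dataset,
    model_spec: ModelSpec,
    training_actives: Sequence[MoleculeRecord] = (),
) -> TrainedModel:
    """Fit the selected model on the full dataset and attach a manifest
    (spec, data hash) for provenance."""
    clf = FingerprintClassifier(
        algorithm=model_spec.algorithm,
        fingerprint_kind=model_spec.fingerprint_kind,
        hyperparameters=dict(model_spec.hyperparameters),
        random_state=model_spec.seed,
    )
    clf.fit(dataset.X, dataset.y)
    manifest = {
        "model_spec": {
            "algorithm": model_spec.algorithm,
            "fingerprint_kind": model_spec.fingerprint_kind,
            "hyperparameters": dict(model_spec.hyperparameters),
            "seed": model_spec.seed,
        },
        "n_samples": int(len(dataset.y)),
        "n_actives": int(dataset.y.sum()),
        "data_hash": dataset.data_hash(),
    }
    return TrainedModel(
        classifier=clf,
        training_actives=list(training_actives),
        manifest=manifest,
    )


@dataclass(frozen=True)
class ScreenResult:
    """One screened molecule above threshold: probability + nearest active."""

    molecule_id: str
    probability: float
    nearest_active_id: str
    nearest_active_tc: float


def screen_library(
    model: TrainedModel,
    library: Sequence[MoleculeRecord],
    p_threshold: float = 0.5,
) -> list[ScreenResult]:
    """Score a library and keep molecules with p >= threshold.

    Results are sorted by probability descending (ties by molecule_id) and
    each is annotated with the id and max TC of its nearest training active.
    """
    if not library:
        raise ValueError("empty screening library")
    kind = model.classifier.fingerprint_kind
    lib_smiles = [r.smiles for r in library]
    p = model.classifier.positive_probability(lib_smiles)
    hits_idx = np.flatnonzero(p >= p_threshold)
    if len(hits_idx) == 0:
        return []
    if model.training_actives:
        act_fps = fingerprints([a.smiles for a in model.training_actives], kind)
        act_ids = [a.molecule_id for a in model.training_actives]
        hit_fps = fingerprints([lib_smiles[i] for i in hits_idx], kind)
        tc = tanimoto_matrix(hit_fps, act_fps)
        # argmax with lexicographic tie-break on the active id
        order = sorted(range(len(act_ids)), key=lambda j: act_ids[j])
        tc = tc[:, order]
        sorted_ids = [act_ids[j] for j in order]
        nn_idx = tc.argmax(axis=1)
        nearest = [(sorted_ids[j], float(tc[i, j])) for i, j in enumerate(nn_idx)]
    else:
        nearest = [("", float("nan"))] * len(hits_idx)
    results = [
        ScreenResult(
            molecule_id=library[i].molecule_id,
            probability=float(p[i]),
            nearest_active_id=nearest[r][0],
            nearest_active_tc=nearest[r][1],
        )
        for r, i in enumerate(hits_idx)
    ]
    results.sort(key=lambda r: (-r.probability, r.molecule_id))
    return results


@dataclass
class ExternalValidation:
    """Outcome of the external-set validation workflow."""

    excluded_active_ids: list[str]
    excluded_decoy_ids: list[str]
    n_actives_retained: int
    n_inactives_retained: int
    tp: int
    fp: int
    calls: list[tuple[str, float, bool, bool]]  # (id, p, predicted, annotated)


def external_validation(
    actives: Sequence[MoleculeRecord],
    decoy_set: DecoySet,
    external_set: Sequence[MoleculeRecord],
    annotations: Mapping[str, bool],
    model_spec: ModelSpec = ModelSpec(),
    tc_exclusion: float = 0.6,
    p_threshold: float = 0.5,
) -> ExternalValidation:
    """Leakage-controlled validation against an annotated external set.

    Every training active with max TC >= ``tc_exclusion`` to any external
    molecule is excluded, together with exactly the decoys linked to it; the
    model is retrained on the remainder and the external set is called at
    p >= ``p_threshold``; TP/FP are tabulated against the annotations.
    """
    kind = model_spec.fingerprint_kind
    act_fps = fingerprints([a.smiles for a in actives], kind)
    ext_fps = fingerprints([e.smiles for e in external_set], kind)
    max_tc = tanimoto_matrix(act_fps, ext_fps).max(axis=1)
    excluded = [a.molecule_id for a, tc in zip(actives, max_tc) if tc >= tc_exclusion]
    excluded_set = set(excluded)
    retained_actives = [a for a in actives if a.molecule_id not in excluded_set]
    if not retained_actives:
        raise ValueError("similarity exclusion removed every training active")
    excluded_decoys = sorted(
        did for aid in excluded for did in decoy_set.decoy_ids_for(aid)
    )
    retained_inactives = [
        d
        for aid, decs in decoy_set.assignments.items()
        if aid not in excluded_set
        for d in decs
    ]
    logger.info(
        "external_validation: excluded %d actives and %d linked decoys",
        len(excluded), len(excluded_decoys),
    )
    dataset = assemble_dataset(
        retained_actives, retained_inactives, kind, seed=model_spec.seed
    )
    model = train_final(dataset, model_spec, training_actives=retained_actives)
    p = model.classifier.positive_probability([e.smiles for e in external_set])
    calls = []
    tp = fp = 0
    for rec, prob in zip(external_set, p):
        predicted = bool(prob >= p_threshold)
        annotated = bool(annotations.get(rec.molecule_id, False))
        if predicted and annotated:
            tp += 1
        elif predicted and not annotated:
            fp += 1
        calls.append((rec.molecule_id, float(prob), predicted, annotated))
    return ExternalValidation(
        excluded_active_ids=sorted(excluded),
        excluded_decoy_ids=excluded_decoys,
        n_actives_retained=len(retained_actives),
        n_inactives_retained=len(retained_inactives),
        tp=tp, fp=fp, calls=calls,
    )
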