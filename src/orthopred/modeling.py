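"""Per-target calibrated classifiers.

Three algorithm families are supported, each with the small
hyper-parameter grid used for benchmarking: random forests of 5, 50 or
500 trees (balanced class weights, √n_features per split), Bernoulli
naive Bayes with smoothing alpha 1.0 or 0.1, and linear SVMs with C of
1e−2, 1 or 1e2.  Classifier scores are turned into calibrated
p(activity) by Platt scaling: the training data are split into two
stratified halves, the classifier fitted on one half and a sigmoid on
the held-out half, both ways, and the two calibrated probabilities
averaged.  Class imbalance (inactives typically outnumber actives
100:1) is countered with balanced sample weights.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import joblib
import numpy as np
from scipy.optimize import minimize
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.svm import LinearSVC
from sklearn.utils.class_weight import compute_sample_weight

from orthopred.chemspace import DEFAULT_WIDTH, Fingerprint, fingerprint

logger = logging.getLogger(__name__)

ALGORITHMS = ("random-forest", "bernoulli-naive-bayes", "linear-svm")

RF_TREES_GRID = (5, 50, 500)
BNB_ALPHA_GRID = (1.0, 0.1)
SVM_C_GRID = (1e-2, 1.0, 1e2)


@dataclass(frozen=True)
class HyperParams:
    """One point of the benchmark hyper-parameter grid."""

    algorithm: str
    trees: int | None = None
    alpha: float | None = None
    C: float | None = None
    class_balancing: bool = True

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        needed = {"random-forest": "trees", "bernoulli-naive-bayes": "alpha",
                  "linear-svm": "C"}[self.algorithm]
        if getattr(self, needed) is None:
            raise ValueError(f"{self.algorithm} requires {needed!r}")
        for name in ("trees", "alpha", "C"):
            if name != needed and getattr(self, name) is not None:
                raise ValueError(f"{name!r} is not a {self.algorithm} parameter")

    @property
    def label(self) -> str:
        if self.algorithm == "random-forest":
            return f"RF(trees={self.trees})"
        if self.algorithm == "bernoulli-naive-bayes":
            return f"BNB(alpha={self.alpha:g})"
        return f"SVM(C={self.C:.0e})"


def default_grid() -> list[HyperParams]:
    """The eight benchmarked algorithm/hyper-parameter settings."""
    grid = [HyperParams("random-forest", trees=t) for t in RF_TREES_GRID]
    grid += [HyperParams("bernoulli-naive-bayes", alpha=a) for a in BNB_ALPHA_GRID]
    grid += [HyperParams("linear-svm", C=c) for c in SVM_C_GRID]
    return grid


def _base_estimator(hp: HyperParams, seed: int):
    if hp.algorithm == "random-forest":
        return RandomForestClassifier(
            n_estimators=hp.trees,
            max_features="sqrt",
            max_depth=None,
            class_weight="balanced" if hp.class_balancing else None,
            random_state=seed,
            n_jobs=1,
        )
    if hp.algorithm == "bernoulli-naive-bayes":
        return BernoulliNB(alpha=hp.alpha)
    return LinearSVC(C=hp.C, random_state=seed)


@dataclass
class CalibratedModel:
    """A fitted per-target classifier with Platt-scaled outputs."""

    target_accession: str
    hyperparams: HyperParams
    calibrated: CalibratedClassifierCV
    n_features: int
    digest: dict = field(default_factory=dict)

    @property
    def platt_parameters(self) -> list[tuple[float, float]]:
        """(A, B) of each calibration fold's sigmoid p = 1/(1+exp(A·s+B))."""
        out = []
        for cc in self.calibrated.calibrated_classifiers_:
            for cal in cc.calibrators:
                out.append((float(cal.a_), float(cal.b_)))
        return out

    def predict(self, fingerprints) -> np.ndarray:
        """Calibrated p(activity) in [0, 1] for each fingerprint."""
        X = _as_matrix(fingerprints)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"fingerprint width {X.shape[1]} does not match "
                f"training width {self.n_features}"
            )
        return self.calibrated.predict_proba(X)[:, 1]

    def save(self, directory) -> None:
        """Write a model bundle: JSON manifest + serialized estimator."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1,
            "target_accession": self.target_accession,
            "hyperparams": asdict(self.hyperparams),
            "n_features": self.n_features,
            "digest": self.digest,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        joblib.dump(self.calibrated, directory / "model.joblib")

    @classmethod
    def load(cls, directory) -> "CalibratedModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        return cls(
            target_accession=manifest["target_accession"],
            hyperparams=HyperParams(**manifest["hyperparams"]),
            calibrated=joblib.load(directory / "model.joblib"),
            n_features=manifest["n_features"],
            digest=manifest["digest"],
        )


def _as_matrix(fingerprints) -> np.ndarray:
    if isinstance(fingerprints, np.ndarray):
        return fingerprints.astype(np.uint8, copy=False)
    return np.stack([fp.bits for fp in fingerprints]).astype(np.uint8)


def train_matrix(
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: HyperParams,
    seed: int = 0,
    target_accession: str = "",
    ensemble: bool = True,
) -> CalibratedModel:
    """Fit a calibrated classifier on a fingerprint matrix.

    ``y`` is 1 for active, 0 for inactive.  With ``ensemble`` (the
    default) the two-fold calibration averages two (classifier, sigmoid)
    members; with ``ensemble=False`` one classifier is refit on all data
    and a single sigmoid fitted on out-of-fold scores, which keeps the
    calibrated ranking identical to the raw decision scores.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        missing = "inactive (0)" if 1 in classes else "active (1)"
        raise ValueError(f"training set has no {missing} examples")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 examples for 2-fold calibration")

    cv = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed)
    model = CalibratedClassifierCV(
        _base_estimator(hyperparams, seed), method="sigmoid", cv=cv,
        ensemble=ensemble,
    )
    sample_weight = (
        compute_sample_weight("balanced", y) if hyperparams.class_balancing else None
    )
    model.fit(X, y, sample_weight=sample_weight)
    digest = {
        "n_actives": int(counts[classes == 1][0]),
        "n_inactives": int(counts[classes == 0][0]),
        "seed": seed,
        "ensemble": ensemble,
    }
    return CalibratedModel(target_accession, hyperparams, model, X.shape[1], digest)


def train(
    training_set,
    hyperparams: HyperParams,
    seed: int = 0,
    fp_cache: dict[str, Fingerprint] | None = None,
    width: int = DEFAULT_WIDTH,
    ensemble: bool = True,
) -> CalibratedModel:
    """Fingerprint a :class:`~orthopred.orthomap.TrainingSet` and fit.

    Provenance composition (human / orthologue / sampled counts) is
    recorded in the model digest.
    """
    fp_cache = fp_cache if fp_cache is not None else {}

    def fp_bits(smiles: str) -> np.ndarray:
        if smiles not in fp_cache:
            fp_cache[smiles] = fingerprint(smiles, width=width)
        return fp_cache[smiles].bits

    act = training_set.actives
    inact = training_set.inactives
    if len(act) == 0 or len(inact) == 0:
        missing = "active" if len(act) == 0 else "inactive"
        raise ValueError(
            f"{training_set.target_accession}: no {missing} examples to train on"
        )
    X = np.stack([fp_bits(s) for s in act["smiles"]]
                 + [fp_bits(s) for s in inact["smiles"]])
    y = np.concatenate([np.ones(len(act), dtype=int), np.zeros(len(inact), dtype=int)])
    model = train_matrix(X, y, hyperparams, seed,
                         target_accession=training_set.target_accession,
                         ensemble=ensemble)
    model.digest["provenance"] = {
        "human": int((act["provenance"] == "human").sum()),
        "orthologue": int(act["provenance"].str.startswith("orthologue").sum()),
        "measured_inactive": int((inact["provenance"] == "measured").sum()),
        "sampled_inactive": int((inact["provenance"] == "sampled").sum()),
    }
    return model


def fit_platt(scores, labels) -> tuple[float, float]:
    """Fit Platt's sigmoid p(active|s) = 1 / (1 + exp(A·s + B)).

    Maximum-likelihood fit with Platt's smoothed targets
    t+ = (N+ + 1)/(N+ + 2) and t− = 1/(N− + 2), which regularize the
    fit when a calibration fold is small or separable.  For scores
    oriented so that larger means more active, the fitted A is ≤ 0.

    Raises on a single-class calibration fold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        missing = "positive" if n_pos == 0 else "negative"
        raise ValueError(f"calibration fold has no {missing} examples")
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(ab):
        a, b = ab
        z = a * s + b
        # log(1+e^z) computed stably
        log1pez = np.logaddexp(0.0, z)
        # p = 1/(1+e^z): log p = -log1pez ; log(1-p) = z - log1pez
        return float(-np.sum(t * (-log1pez) + (1.0 - t) * (z - log1pez)))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 5000})
    a, b = res.x
    return float(a), float(b)


def platt_predict(scores, a: float, b: float) -> np.ndarray:
    """Apply a fitted Platt sigmoid to raw scores."""
    z = np.asarray(scores, dtype=float) * a + b
    return 1.0 / (1.0 + np.exp(z))
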