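"""Interaction classifier: model and results objects.

:class:`InteractionModel` holds the design (fused pair features and labels)
plus the backend configuration; :meth:`InteractionModel.fit` returns an
:class:`InteractionResults` carrying the fitted estimator, its metadata and
prediction/evaluation/persistence methods.

Backends
--------
random_forest
    scikit-learn ``RandomForestClassifier`` with 100 trees by default and all
    other hyperparameters at their defaults; bootstrap and feature
    subsampling are seeded for reproducibility.
svm
    scikit-learn ``SVC`` with a polynomial kernel and C = 1 (backend-default
    degree, recorded in metadata); probabilities come from the backend's
    standard calibration and feed the threshold sweep only.

The classification threshold for the scalar measures is 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np

from .dataset import InteractionDataset
from .fingerprints import Drug
from .fusion import FusionModel, encode_pair, encode_pairs, models_code, parse_models
from .metrics import MetricsReport, evaluate_predictions

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class ClassifierConfig:
    """Backend choice and hyperparameters.

    n_trees applies to the random forest; svm_* to the support vector
    machine.  ``seed`` fixes every stochastic element of training.
    """

    backend: str = "random_forest"
    n_trees: int = 100
    svm_kernel: str = "poly"
    svm_C: float = 1.0
    svm_degree: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.backend not in ("random_forest", "svm"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.svm_C <= 0:
            raise ValueError("svm_C must be > 0")

    def make_estimator(self):
        if self.backend == "random_forest":
            from sklearn.ensemble import RandomForestClassifier

            return RandomForestClassifier(
                n_estimators=self.n_trees, random_state=self.seed, n_jobs=1
            )
        from sklearn.svm import SVC

        return SVC(
            kernel=self.svm_kernel,
            C=self.svm_C,
            degree=self.svm_degree,
            probability=True,
            random_state=self.seed,
        )


class InteractionModel:
    """A drug-pair interaction classifier specified by features and labels.

    Parameters
    ----------
    X : (n_samples, 1024 * n_models) feature matrix of fused pairs
    y : binary labels (1 = interacting)
    feature_models : the fusion-model combination the features were built with
    config : backend configuration
    """

    def __init__(
        self,
        X: np.ndarray,
        y: Sequence[int],
        feature_models: str | Sequence[FusionModel] = "AS",
        config: ClassifierConfig | None = None,
    ):
        self.X = np.asarray(X)
        self.y = np.asarray(y, dtype=np.int8)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"feature matrix {self.X.shape} does not match {self.y.shape[0]} labels"
            )
        if len(np.unique(self.y)) < 2:
            raise ValueError("training labels contain a single class")
        self.feature_models = parse_models(feature_models)
        self.config = config or ClassifierConfig()

    @classmethod
    def from_dataset(
        cls,
        dataset: InteractionDataset,
        feature_models: str | Sequence[FusionModel] = "AS",
        config: ClassifierConfig | None = None,
        indices: np.ndarray | None = None,
    ) -> "InteractionModel":
        """Build the design matrix from a dataset (optionally a sample subset)."""
        samples = dataset.samples
        if indices is not None:
            samples = [samples[i] for i in np.asarray(indices)]
        X = encode_pairs(dataset.drugs, [s.pair for s in samples], feature_models)
        y = np.array([s.label for s in samples], dtype=np.int8)
        return cls(X, y, feature_models=feature_models, config=config)

    def fit(self) -> "InteractionResults":
        estimator = self.config.make_estimator()
        estimator.fit(self.X, self.y)
        return InteractionResults(
            estimator=estimator,
            config=self.config,
            feature_models=self.feature_models,
            feature_length=self.X.shape[1],
            n_training_samples=self.X.shape[0],
        )


@dataclass
class InteractionResults:
    """A fitted interaction classifier with its training metadata."""

    estimator: object
    config: ClassifierConfig
    feature_models: tuple[FusionModel, ...]
    feature_length: int
    n_training_samples: int
    metadata: dict = field(default_factory=dict)

    # -- prediction -------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Interaction probability for each feature row."""
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.feature_length:
            raise ValueError(
                f"feature matrix with {X.shape[1] if X.ndim == 2 else '?'} columns "
                f"does not match model feature length {self.feature_length}"
            )
        if X.shape[0] == 0:
            return np.empty(0)
        proba = self.estimator.predict_proba(X)
        positive_col = list(self.estimator.classes_).index(1)
        return proba[:, positive_col]

    def predict(self, X: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(np.int8)

    def predict_pair(self, d1: Drug, d2: Drug) -> float:
        """Interaction probability of one drug pair (symmetric in order)."""
        feats = encode_pair(d1, d2, self.feature_models)
        if feats.vector.shape[0] != self.feature_length:
            raise ValueError(
                f"pair features of length {feats.vector.shape[0]} do not match "
                f"model feature length {self.feature_length}"
            )
        return float(self.predict_proba(feats.vector[None, :])[0])

    def evaluate(self, X: np.ndarray, y: Sequence[int],
                 threshold: float = DEFAULT_THRESHOLD) -> MetricsReport:
        """Full metrics report on held-out features/labels."""
        return evaluate_predictions(y, self.predict_proba(X), threshold=threshold)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        code = models_code(self.feature_models)
        lines = [
            "Interaction classifier results",
            "=" * 38,
            f"{'backend':<22}{self.config.backend}",
            f"{'fusion models':<22}{code} ({', '.join(m.value for m in self.feature_models)})",
            f"{'feature length':<22}{self.feature_length}",
            f"{'training samples':<22}{self.n_training_samples}",
            f"{'seed':<22}{self.config.seed}",
        ]
        if self.config.backend == "random_forest":
            lines.append(f"{'trees':<22}{self.config.n_trees}")
        else:
            lines.append(
                f"{'svm':<22}kernel={self.config.svm_kernel} "
                f"C={self.config.svm_C} degree={self.config.svm_degree}"
            )
        for k, v in self.metadata.items():
            lines.append(f"{k:<22}{v}")
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Persist to a binary artifact plus a JSON sidecar with config/metadata."""
        path = Path(path)
        joblib.dump(self.estimator, path)
        sidecar = {
            "config": asdict(self.config),
            "feature_models": models_code(self.feature_models),
            "feature_length": self.feature_length,
            "n_training_samples": self.n_training_samples,
            "metadata": self.metadata,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "InteractionResults":
        path = Path(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if not path.exists() or not sidecar_path.exists():
            raise FileNotFoundError(
                f"model artifact {path} and sidecar {sidecar_path} are both required"
            )
        sidecar = json.loads(sidecar_path.read_text())
        return cls(
            estimator=joblib.load(path),
            config=ClassifierConfig(**sidecar["config"]),
            feature_models=parse_models(sidecar["feature_models"]),
            feature_length=sidecar["feature_length"],
            n_training_samples=sidecar["n_training_samples"],
            metadata=sidecar.get("metadata", {}),
        )


def train(
    X: np.ndarray,
    y: Sequence[int],
    config: ClassifierConfig | None = None,
    feature_models: str | Sequence[FusionModel] = "AS",
) -> InteractionResults:
    """Functional shorthand for ``InteractionModel(X, y, ...).fit()``."""
    return InteractionModel(X, y, feature_models=feature_models, config=config).fit()
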