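"""Contrast-class training of the calibrated RBF support-vector classifier.

The multi-species occurrence dataset is reduced to a binary problem: the
invasive target species is the positive class, all native species pooled
form the negative class.  To mitigate the strongly unbalanced per-species
sample sizes, at most ``per_species_cap`` rows per species (default 1000)
enter training, drawn uniformly without replacement under a fixed seed.

The separator is a support-vector machine with a radial-basis-function
kernel and the reference hyper-parameters gamma = 0.0005, C = 1.0,
tolerance = 1e-10, applied to covariates in raw physical units (degC, mm)
— gamma is calibrated to those units, so no standardization is applied by
default.  Decision values are mapped to occurrence probabilities in [0, 1]
with a Platt sigmoid fitted by internal stratified 5-fold cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .geodata_io import INVASIVE, NATIVE, FeatureTable

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


class TrainingError(ValueError):
    """Configuration or degeneracy errors raised before/at fit time."""


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the calibrated separator (reference defaults)."""

    gamma: float = 0.0005
    C: float = 1.0
    tolerance: float = 1e-10
    kernel: str = "rbf"
    per_species_cap: int = 1000
    subsample_seed: int = 0
    calibration_folds: int = 5
    standardize: bool = False  # explicit opt-in; default is raw units

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.C <= 0 or self.tolerance <= 0:
            raise TrainingError("gamma, C and tolerance must be positive")
        if self.kernel != "rbf":
            raise TrainingError("only the radial basis function kernel is "
                                "supported")
        if self.per_species_cap < 1:
            raise TrainingError("per-species cap must be >= 1")
        if self.calibration_folds < 2:
            raise TrainingError("calibration needs >= 2 folds")


@dataclass
class CalibratedNicheModel:
    """Fitted separator + Platt sigmoid + the variable list it was trained on.

    ``estimator`` is the calibrated classifier (positive class = invasive,
    encoded 1).  ``sigmoid_a``/``sigmoid_b`` are the fitted Platt
    parameters: p = 1 / (1 + exp(a * decision + b)); a < 0 makes
    probability strictly increasing in the decision value.
    """

    estimator: CalibratedClassifierCV
    variables: list[str]
    config: TrainingConfig
    sigmoid_a: float
    sigmoid_b: float
    scale_mean: np.ndarray | None = None  # set when standardize=True
    scale_sd: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    # -- prediction ---------------------------------------------------------

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, FeatureTable):
            X = X.data[self._check_columns(X.variables)]
        if isinstance(X, pd.DataFrame):
            X = X[self._check_columns(list(X.columns))]
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.variables):
            raise ValueError(
                f"expected {len(self.variables)} covariates in order "
                f"{self.variables}, got {X.shape[1]}")
        if self.scale_mean is not None:
            X = (X - self.scale_mean) / self.scale_sd
        return X

    def _check_columns(self, cols: Sequence[str]) -> list[str]:
        missing = [v for v in self.variables if v not in cols]
        if missing:
            raise ValueError(f"input lacks model variables {missing}; "
                             f"expected {self.variables}")
        return list(self.variables)

    def decision_value(self, X) -> np.ndarray:
        """Signed distance to the separating hyperplane (invasive > 0 side)."""
        svc = self.estimator.calibrated_classifiers_[0].estimator
        return svc.decision_function(self._as_matrix(X))

    def predict_probability(self, X) -> np.ndarray:
        """Occurrence probability of the invasive class, in [0, 1]."""
        X = self._as_matrix(X)
        proba = self.estimator.predict_proba(X)
        pos = list(self.estimator.classes_).index(1)
        return proba[:, pos]

    def predict_class(self, X, threshold: float = 0.5,
                      mode: str = "probability") -> np.ndarray:
        """Binary labels ('invasive'/'native').

        ``probability`` mode: invasive iff calibrated probability >=
        threshold.  ``raw`` mode: invasive iff the uncalibrated decision
        value is > 0.
        """
        if mode == "probability":
            pos = self.predict_probability(X) >= threshold
        elif mode == "raw":
            pos = self.decision_value(X) > 0
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return np.where(pos, INVASIVE, NATIVE)


# ---------------------------------------------------------------------------


def build_training_set(table: FeatureTable, cap: int | None = None,
                       seed: int | None = None,
                       config: TrainingConfig | None = None) -> FeatureTable:
    """Cap each species at ``cap`` rows by seeded uniform subsampling.

    Species with at most ``cap`` rows pass through unchanged (original row
    order is preserved throughout).
    """
    config = config or TrainingConfig()
    cap = config.per_species_cap if cap is None else cap
    seed = config.subsample_seed if seed is None else seed
    labels = set(table.data["label"].unique())
    if labels != {INVASIVE, NATIVE}:
        raise TrainingError(
            "cannot train a binary separator: need both an invasive and a "
            f"native class, got {sorted(labels)}")
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(table.data), dtype=bool)
    # iterate species in first-appearance order for seeded determinism
    for species in dict.fromkeys(table.data["species"]):
        idx = np.flatnonzero((table.data["species"] == species).to_numpy())
        if len(idx) > cap:
            idx = np.sort(rng.choice(idx, size=cap, replace=False))
            logger.info("subsampled %s: %d -> %d rows", species,
                        (table.data["species"] == species).sum(), cap)
        keep[idx] = True
    return table.subset(keep)


def train(table: FeatureTable, config: TrainingConfig | None = None
          ) -> CalibratedNicheModel:
    """Fit the calibrated separator on a labelled feature table.

    The table is used as given (apply :func:`build_training_set` first for
    the per-species cap).  Training-set reclassification (resubstitution)
    counts are stored in the model metadata.
    """
    config = config or TrainingConfig()
    X = table.X
    y = table.y
    if np.isnan(X).any():
        raise TrainingError("training table contains missing covariates")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < 2 or n_neg < 2:
        raise TrainingError("need at least 2 rows per class "
                            f"(invasive={n_pos}, native={n_neg})")
    if np.all(X.std(axis=0) == 0):
        raise TrainingError("degenerate covariates: zero variance in every "
                            "variable")

    mu = sigma = None
    if config.standardize:
        mu = X.mean(axis=0)
        sigma = X.std(axis=0)
        sigma[sigma == 0] = 1.0
        X = (X - mu) / sigma

    svc = SVC(kernel=config.kernel, gamma=config.gamma, C=config.C,
              tol=config.tolerance)
    folds = min(config.calibration_folds, n_pos, n_neg)
    est = CalibratedClassifierCV(svc, method="sigmoid", cv=folds,
                                 ensemble=False)
    est.fit(X, y)
    calibrator = est.calibrated_classifiers_[0].calibrators[0]
    model = CalibratedNicheModel(
        estimator=est,
        variables=list(table.variables),
        config=config if folds == config.calibration_folds
        else replace(config, calibration_folds=folds),
        sigmoid_a=float(calibrator.a_),
        sigmoid_b=float(calibrator.b_),
        scale_mean=mu,
        scale_sd=sigma,
    )
    y_hat = model.predict_class(table.X)
    y_obs = np.where(y == 1, INVASIVE, NATIVE)
    model.metadata.update({
        "class_counts": {"invasive": n_pos, "native": n_neg},
        "species_counts": table.species_counts(),
        "resubstitution": {
            "TP": int(((y_obs == INVASIVE) & (y_hat == INVASIVE)).sum()),
            "FN": int(((y_obs == INVASIVE) & (y_hat == NATIVE)).sum()),
            "FP": int(((y_obs == NATIVE) & (y_hat == INVASIVE)).sum()),
            "TN": int(((y_obs == NATIVE) & (y_hat == NATIVE)).sum()),
        },
        "subsample_seed": config.subsample_seed,
    })
    return model


# ---------------------------------------------------------------------------
# Serialization: versioned self-describing bundle


def save_model(model: CalibratedNicheModel, path: str | Path) -> None:
    payload = {
        "format": "nichecontrast-model",
        "format_version": MODEL_FORMAT_VERSION,
        "estimator": model.estimator,
        "variables": model.variables,
        "config": model.config,
        "sigmoid_a": model.sigmoid_a,
        "sigmoid_b": model.sigmoid_b,
        "scale_mean": model.scale_mean,
        "scale_sd": model.scale_sd,
        "metadata": model.metadata,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> CalibratedNicheModel:
    payload = joblib.load(path)
    if payload.get("format") != "nichecontrast-model":
        raise ValueError(f"{path} is not a model bundle")
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version "
                         f"{payload.get('format_version')}")
    return CalibratedNicheModel(
        estimator=payload["estimator"],
        variables=list(payload["variables"]),
        config=payload["config"],
        sigmoid_a=payload["sigmoid_a"],
        sigmoid_b=payload["sigmoid_b"],
        scale_mean=payload.get("scale_mean"),
        scale_sd=payload.get("scale_sd"),
        metadata=payload["metadata"],
    )
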