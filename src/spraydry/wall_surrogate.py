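"""Machine-learned surrogate for the outer-wall temperature.

The outer-wall temperature Textwall closes the dryer balance but is not
instrumented on benchtop equipment.  It is therefore derived from each
experiment's measured outlet temperature by inverting the balance, and a
random-forest regressor is trained to map the five process features
(Tin, Text, RHext, FR, Gin) to those derived labels.  The fitted surrogate
then supplies Textwall for conditions where no measurement exists, which is
what makes the forward outlet-temperature prediction possible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import train_test_split

from .energy_balance import (
    BalanceOptions,
    DEFAULT_OPTIONS,
    DryerGeometry,
    FlaggedRecordError,
    ProcessConditions,
    derive_textwall_label,
)

__all__ = [
    "FEATURES",
    "ExperimentRecord",
    "EvaluationReport",
    "WallSurrogate",
    "build_training_set",
    "fit",
    "evaluate",
    "loo_predictions",
]

log = logging.getLogger(__name__)

#: Feature order of the surrogate, fixed across fitting and prediction.
FEATURES = ("Tin", "Text", "RHext", "FR", "Gin")


@dataclass
class ExperimentRecord:
    """One experiment: process conditions plus the measured outlet temperature.

    ``Gin`` is the instrument-indicated drying-gas flow (kg/h, as recorded);
    ``gin_effective`` optionally carries the flow actually used by the
    balance when the indicated value is known to be on a different basis.
    ``group_tag`` distinguishes empty runs (no feed) from atomizing runs.
    """

    Tin: float
    Gin: float
    Text: float
    RHext: float
    measured_Tout: float
    FR: float = 0.0
    cfeed: float = 0.0
    aspirator_pct: float | None = None
    gin_effective: float | None = None
    textwall_label: float | None = None
    group_tag: str = "empty"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.measured_Tout >= self.Tin:
            raise ValueError("measured_Tout must be below Tin")
        if self.group_tag not in ("empty", "atomizing", "synthetic"):
            raise ValueError("group_tag must be 'empty', 'atomizing' or 'synthetic'")

    @property
    def gin_model(self) -> float:
        """Drying-gas flow used by the balance and as the surrogate feature."""
        return self.gin_effective if self.gin_effective is not None else self.Gin

    @property
    def conditions(self) -> ProcessConditions:
        return ProcessConditions(
            Tin=self.Tin,
            Gin=self.gin_model,
            Text=self.Text,
            RHext=self.RHext,
            FR=self.FR,
            cfeed=self.cfeed,
        )


def feature_frame(records: Sequence[ExperimentRecord]) -> pd.DataFrame:
    """Stack records into the surrogate's feature matrix."""
    return pd.DataFrame(
        {
            "Tin": [r.Tin for r in records],
            "Text": [r.Text for r in records],
            "RHext": [r.RHext for r in records],
            "FR": [r.FR for r in records],
            "Gin": [r.gin_model for r in records],
        }
    )


@dataclass(frozen=True)
class EvaluationReport:
    """Held-out regression metrics."""

    rmse: float  # K
    r2: float  # –
    mae: float  # K
    n: int

    def __post_init__(self) -> None:
        if self.rmse < self.mae - 1e-12:
            raise ValueError("rmse cannot be below mae")


def evaluate(predictions, labels) -> EvaluationReport:
    """RMSE, R² and MAE of predictions against labels."""
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have the same length")
    if predictions.size < 2:
        raise ValueError("need at least 2 points to evaluate")
    return EvaluationReport(
        rmse=float(np.sqrt(mean_squared_error(labels, predictions))),
        r2=float(r2_score(labels, predictions)),
        mae=float(mean_absolute_error(labels, predictions)),
        n=int(predictions.size),
    )


def build_training_set(
    records: Iterable[ExperimentRecord],
    geom: DryerGeometry,
    opts: BalanceOptions = DEFAULT_OPTIONS,
) -> tuple[list[ExperimentRecord], list[tuple[ExperimentRecord, str]]]:
    """Derive a Textwall label for every record.

    Returns ``(labeled, flagged)`` where flagged records are those for which
    the balance admits no wall temperature in (Text, Tavg); each flagged
    entry carries the reason and is logged.
    """
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    labeled: list[ExperimentRecord] = []
    flagged: list[tuple[ExperimentRecord, str]] = []
    for rec in records:
        try:
            label = derive_textwall_label(rec.conditions, rec.measured_Tout, geom, opts)
        except FlaggedRecordError as err:
            log.warning("record flagged (%s %s K): %s", rec.group_tag, rec.Tin, err)
            flagged.append((rec, str(err)))
            continue
        labeled.append(replace(rec, textwall_label=label))
    return labeled, flagged


# hyperparameters fixed by design: forest of 500 unpruned trees with
# default feature subsampling; candidates, when given, are ranked by test RMSE
_BASE_PARAMS = {"n_estimators": 500, "max_depth": None}


@dataclass
class WallSurrogate:
    """Fitted (conditions -> Textwall) regressor with its split metadata."""

    model: RandomForestRegressor
    seed: int
    split_fraction: float
    metrics: EvaluationReport | None
    label_min: float
    label_max: float
    params: dict = field(default_factory=dict)

    def predict(self, records_or_frame) -> np.ndarray:
        """Predict Textwall (K); clipped per record to (Text, Tin)."""
        if isinstance(records_or_frame, pd.DataFrame):
            X = records_or_frame[list(FEATURES)]
        else:
            X = feature_frame(list(records_or_frame))
        pred = self.model.predict(X)
        return np.clip(pred, X["Text"].to_numpy(), X["Tin"].to_numpy())

    def predict_one(self, cond: ProcessConditions) -> float:
        X = pd.DataFrame(
            [[cond.Tin, cond.Text, cond.RHext, cond.FR, cond.Gin]], columns=list(FEATURES)
        )
        return float(self.predict(X)[0])

    def save(self, path: str | Path) -> None:
        """Persist the fitted model with a JSON metadata sidecar."""
        path = Path(path)
        joblib.dump(self.model, path)
        meta = {
            "seed": self.seed,
            "split_fraction": self.split_fraction,
            "label_min": self.label_min,
            "label_max": self.label_max,
            "params": self.params,
            "features": list(FEATURES),
            "metrics": None if self.metrics is None else vars(self.metrics),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "WallSurrogate":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        metrics = meta["metrics"]
        return cls(
            model=joblib.load(path),
            seed=meta["seed"],
            split_fraction=meta["split_fraction"],
            metrics=None if metrics is None else EvaluationReport(**metrics),
            label_min=meta["label_min"],
            label_max=meta["label_max"],
            params=meta["params"],
        )


def _require_labels(records: Sequence[ExperimentRecord]) -> np.ndarray:
    labels = [r.textwall_label for r in records]
    if any(label is None for label in labels):
        raise ValueError("all records must carry a textwall_label; run build_training_set first")
    return np.asarray(labels, dtype=float)


def fit(
    labeled: Sequence[ExperimentRecord],
    split_fraction: float = 0.8,
    seed: int = 0,
    candidates: Sequence[dict] | None = None,
) -> WallSurrogate:
    """Fit the wall surrogate on a seeded random 80/20 split.

    When several hyperparameter candidates are supplied, each is fit on the
    training portion and the one with the lowest held-out RMSE is kept.
    """
    labeled = list(labeled)
    if len(labeled) < 10:
        raise ValueError(
            "fewer than 10 labeled records: use loo_predictions (leave-one-out) instead"
        )
    y = _require_labels(labeled)
    X = feature_frame(labeled)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split_fraction, random_state=seed, shuffle=True
    )
    best: tuple[float, RandomForestRegressor, dict, EvaluationReport] | None = None
    for cand in candidates or [{}]:
        params = {**_BASE_PARAMS, **cand}
        model = RandomForestRegressor(random_state=seed, **params)
        model.fit(X_tr, y_tr)
        report = evaluate(model.predict(X_te), y_te)
        if best is None or report.rmse < best[0]:
            best = (report.rmse, model, params, report)
    assert best is not None
    _, model, params, report = best
    return WallSurrogate(
        model=model,
        seed=seed,
        split_fraction=split_fraction,
        metrics=report,
        label_min=float(y.min()),
        label_max=float(y.max()),
        params=params,
    )


def fit_full(labeled: Sequence[ExperimentRecord], seed: int = 0) -> WallSurrogate:
    """Fit on every labeled record (no held-out metrics); used for deployment."""
    labeled = list(labeled)
    y = _require_labels(labeled)
    model = RandomForestRegressor(random_state=seed, **_BASE_PARAMS)
    model.fit(feature_frame(labeled), y)
    return WallSurrogate(
        model=model,
        seed=seed,
        split_fraction=1.0,
        metrics=None,
        label_min=float(y.min()),
        label_max=float(y.max()),
        params=dict(_BASE_PARAMS),
    )


def loo_predictions(labeled: Sequence[ExperimentRecord], seed: int = 0) -> np.ndarray:
    """Leave-one-out Textwall predictions for a small labeled set.

    With only a few dozen records a 20% test split is a handful of points;
    leave-one-out keeps every record usable for both training and honest
    evaluation.
    """
    labeled = list(labeled)
    y = _require_labels(labeled)
    X = feature_frame(labeled)
    preds = np.empty(len(labeled))
    for i in range(len(labeled)):
        mask = np.ones(len(labeled), dtype=bool)
        mask[i] = False
        model = RandomForestRegressor(random_state=seed, **_BASE_PARAMS)
        model.fit(X[mask], y[mask])
        pred = float(model.predict(X[~mask])[0])
        preds[i] = np.clip(pred, labeled[i].Text, labeled[i].Tin)
    return preds
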