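"""Per-gait-phase stride-length regression with mean fusion.

Classical pedestrian dead-reckoning step-length models relate stride length
to simple statistics of the acceleration within a step: Weinberg's fourth
root of the vertical acceleration range, Kim's cube root of the mean
absolute acceleration, Ladetto's affine model in cadence and variance, and
Scarlett's normalized mean excursion.  Here those statistics are treated as
*features* (their multiplicative/additive constants are absorbed by the
regressor) computed per channel role -- sagittal, vertical, and the
per-sample 3-axis magnitude -- on each gait-phase segment.  One regressor
(RBF-kernel SVR, optionally AdaBoost-ensembled) is trained per dynamic
phase after feature standardization and random-forest importance selection,
and the per-phase predictions are fused by their arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.svm import SVR

from .core import ImuRecording

DYNAMIC_PHASES = ("push_off", "swing", "heel_strike")

#: default feature registry: 4 statistics x 3 channel roles = 12 features
FEATURE_CHANNELS = ("sagittal", "vertical", "magnitude")
FEATURE_STATS = ("weinberg", "kim", "variance", "range")


def _channel_series(segment: ImuRecording, role: str) -> np.ndarray:
    if role == "magnitude":
        return segment.accel_magnitude()
    return segment.channel("accel", role)


def compute_features(
    segment: ImuRecording,
    cadence_hz: float,
    include_cadence: bool = False,
    include_scarlett: bool = False,
) -> dict[str, float]:
    """Feature vector of one phase segment.

    Per channel role in (sagittal, vertical, magnitude):

    - ``weinberg`` = (a_max - a_min)**(1/4)
    - ``kim``      = (mean |a_i|)**(1/3)
    - ``variance`` = var(a)
    - ``range``    = a_max - a_min

    Optional shared features: ``cadence`` (strides/s of the enclosing walk)
    and ``scarlett`` = mean((|a_i| - a_min) / (a_max - a_min)) on the
    magnitude channel.  Flat channels (a_max == a_min) define the weinberg
    and scarlett terms as 0 rather than erroring.
    """
    if len(segment) < 2:
        raise ValueError("segment needs at least 2 samples")
    if cadence_hz <= 0:
        raise ValueError("cadence_hz must be positive")
    feats: dict[str, float] = {}
    for role in FEATURE_CHANNELS:
        a = _channel_series(segment, role)
        rng = float(a.max() - a.min())
        feats[f"{role}_weinberg"] = rng ** 0.25 if rng > 0 else 0.0
        feats[f"{role}_kim"] = float(np.mean(np.abs(a))) ** (1.0 / 3.0)
        feats[f"{role}_variance"] = float(np.var(a))
        feats[f"{role}_range"] = rng
    if include_cadence:
        feats["cadence"] = float(cadence_hz)
    if include_scarlett:
        a = np.abs(_channel_series(segment, "magnitude"))
        rng = float(a.max() - a.min())
        feats["scarlett"] = float(np.mean((a - a.min()) / rng)) if rng > 0 else 0.0
    if not all(np.isfinite(v) for v in feats.values()):
        raise ValueError("non-finite feature value")
    return feats


@dataclass
class ScalerParams:
    """Per-feature mean and unbiased SD fitted on training data."""

    names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        A = X[self.names].to_numpy(dtype=float)
        return (A - self.mean) / self.sd


def standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, ScalerParams]:
    """Column-wise standardization to mean 0, unbiased SD 1.

    Columns with zero variance are dropped and recorded in the returned
    :class:`ScalerParams`.
    """
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    params = ScalerParams(
        names=list(X.columns[keep]),
        mean=mean[keep].to_numpy(),
        sd=sd[keep].to_numpy(),
        dropped=list(X.columns[~keep]),
    )
    Xn = (X.loc[:, keep] - mean[keep]) / sd[keep]
    return Xn, params


def select_features(
    X: pd.DataFrame,
    y: Sequence[float],
    threshold: float = 0.05,
    seed: int = 0,
    n_estimators: int = 200,
) -> tuple[list[str], pd.Series]:
    """Impurity-based random-forest importance selection.

    Returns the names with importance strictly above ``threshold`` (at least
    the single top feature) plus the full importance table.
    """
    rf = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    rf.fit(X.to_numpy(dtype=float), np.asarray(y, dtype=float))
    imp = pd.Series(rf.feature_importances_, index=X.columns).sort_values(ascending=False)
    selected = list(imp.index[imp > threshold])
    if not selected:
        selected = [imp.index[0]]
    return selected, imp


def _make_regressor(model_type: str, cfg: Mapping, seed: int):
    svr = SVR(
        kernel="rbf",
        C=cfg.get("C", 10.0),
        gamma=cfg.get("gamma", "scale"),
        epsilon=cfg.get("epsilon", 0.01),
    )
    if model_type == "svr_rbf":
        return svr
    if model_type == "svr_adaboost":
        return AdaBoostRegressor(
            estimator=svr,
            n_estimators=cfg.get("n_estimators", 30),
            loss=cfg.get("loss", "linear"),
            random_state=seed,
        )
    raise ValueError(f"unknown model_type {model_type!r}")


class StrideLengthRegressor(BaseEstimator, RegressorMixin):
    """Importance-select -> standardize -> SVR pipeline for one phase.

    Parameters
    ----------
    model_type:
        ``"svr_rbf"`` or ``"svr_adaboost"`` (RBF-SVR base estimators).
    importance_threshold:
        Keep features whose random-forest importance exceeds this value.
    random_state:
        Seeds both the selector forest and the AdaBoost ensemble.
    """

    def __init__(
        self,
        model_type: str = "svr_rbf",
        importance_threshold: float = 0.05,
        C: float = 10.0,
        gamma="scale",
        epsilon: float = 0.01,
        n_estimators: int = 30,
        random_state: int = 0,
    ):
        self.model_type = model_type
        self.importance_threshold = importance_threshold
        self.C = C
        self.gamma = gamma
        self.epsilon = epsilon
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "StrideLengthRegressor":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        selected, importances = select_features(
            X, y, threshold=self.importance_threshold, seed=self.random_state
        )
        Xn, scaler = standardize(X[selected])
        # selection may retain a constant column in a degenerate matrix
        self.selected_features_ = scaler.names
        self.importances_ = importances
        self.scaler_ = scaler
        self.regressor_ = _make_regressor(
            self.model_type,
            {"C": self.C, "gamma": self.gamma, "epsilon": self.epsilon,
             "n_estimators": self.n_estimators},
            self.random_state,
        )
        self.regressor_.fit(Xn.to_numpy(dtype=float), y)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        return self.regressor_.predict(self.scaler_.transform(X))


@dataclass
class FusedPrediction:
    value: float
    per_phase: dict
    partial: bool  # True when a phase was missing and fusion used a subset


class FusedStrideLengthEstimator(BaseEstimator, RegressorMixin):
    """Per-phase stride-length models fused by the arithmetic mean.

    ``fit`` takes a mapping ``{phase: feature DataFrame}`` covering the three
    dynamic phases (rows aligned across phases, one row per stride) plus the
    per-stride reference lengths.  A whole-stride comparison model is trained
    on ``X["whole"]`` when provided.
    """

    def __init__(
        self,
        model_type: str = "svr_rbf",
        importance_threshold: float = 0.05,
        min_train_strides: int = 20,
        random_state: int = 0,
        **svr_params,
    ):
        self.model_type = model_type
        self.importance_threshold = importance_threshold
        self.min_train_strides = min_train_strides
        self.random_state = random_state
        self.svr_params = svr_params

    def fit(self, X: Mapping[str, pd.DataFrame], y) -> "FusedStrideLengthEstimator":
        y = np.asarray(y, dtype=float)
        missing = [ph for ph in DYNAMIC_PHASES if ph not in X]
        if missing:
            raise ValueError(f"missing phase feature tables: {missing}")
        n = len(y)
        if n < self.min_train_strides:
            raise ValueError(
                f"need at least {self.min_train_strides} training strides, got {n}"
            )
        self.models_ = {}
        for ph in DYNAMIC_PHASES:
            Xp = pd.DataFrame(X[ph])
            if len(Xp) != n:
                raise ValueError(f"phase {ph!r}: {len(Xp)} rows but {n} targets")
            self.models_[ph] = StrideLengthRegressor(
                model_type=self.model_type,
                importance_threshold=self.importance_threshold,
                random_state=self.random_state,
                **self.svr_params,
            ).fit(Xp, y)
        self.whole_model_ = None
        if "whole" in X:
            self.whole_model_ = StrideLengthRegressor(
                model_type=self.model_type,
                importance_threshold=self.importance_threshold,
                random_state=self.random_state,
                **self.svr_params,
            ).fit(pd.DataFrame(X["whole"]), y)
        return self

    def predict(self, X: Mapping[str, pd.DataFrame]) -> np.ndarray:
        preds = [
            self.models_[ph].predict(pd.DataFrame(X[ph]))
            for ph in DYNAMIC_PHASES
            if ph in X
        ]
        if not preds:
            raise ValueError("no phase feature tables supplied")
        return np.mean(np.vstack(preds), axis=0)

    def predict_whole(self, X_whole: pd.DataFrame) -> np.ndarray:
        if self.whole_model_ is None:
            raise RuntimeError("no whole-stride model was trained")
        return self.whole_model_.predict(pd.DataFrame(X_whole))

    def predict_one(self, phase_features: Mapping[str, Mapping[str, float]]) -> FusedPrediction:
        """Predict a single stride from per-phase feature dicts; phases
        missing due to segmentation failure are skipped (partial fusion)."""
        per_phase = {}
        for ph in DYNAMIC_PHASES:
            if ph in phase_features and phase_features[ph] is not None:
                row = pd.DataFrame([phase_features[ph]])
                per_phase[ph] = float(self.models_[ph].predict(row)[0])
        if not per_phase:
            raise ValueError("no phase features available for this stride")
        return FusedPrediction(
            value=float(np.mean(list(per_phase.values()))),
            per_phase=per_phase,
            partial=len(per_phase) < len(DYNAMIC_PHASES),
        )


def train(
    phase_features: Mapping[str, pd.DataFrame],
    reference_lengths: Sequence[float],
    model_type: str = "svr_rbf",
    cfg: Mapping | None = None,
    seed: int = 0,
) -> FusedStrideLengthEstimator:
    """Functional wrapper over :class:`FusedStrideLengthEstimator.fit`."""
    cfg = dict(cfg or {})
    est = FusedStrideLengthEstimator(
        model_type=model_type,
        importance_threshold=cfg.pop("importance_threshold", 0.05),
        min_train_strides=cfg.pop("min_train_strides", 20),
        random_state=seed,
        **cfg,
    )
    return est.fit(phase_features, reference_lengths)


def predict(model: FusedStrideLengthEstimator, phase_features) -> FusedPrediction | np.ndarray:
    """Predict stride length(s); accepts one stride's per-phase feature dicts
    or a mapping of per-phase feature tables."""
    if isinstance(phase_features, Mapping) and any(
        isinstance(v, pd.DataFrame) for v in phase_features.values()
    ):
        return model.predict(phase_features)
    return model.predict_one(phase_features)


def phase_feature_tables(
    rec: ImuRecording,
    labels,
    strides,
    cadence_hz: float | None = None,
    include_whole: bool = True,
):
    """Assemble per-phase feature tables for a set of segmented strides.

    Returns ``(tables, used)`` where ``tables`` maps each dynamic phase (and
    optionally ``"whole"``) to a DataFrame with one row per stride that has
    all three dynamic phases, and ``used`` lists the indices of those
    strides.  ``cadence_hz`` defaults to the stride rate of the walk.
    """
    from .core import slice_recording

    strides = list(strides)
    if cadence_hz is None:
        total_s = sum(len(s) for s in strides) / rec.sample_rate_hz
        cadence_hz = len(strides) / total_s if total_s > 0 else 1.0
    rows: dict[str, list] = {ph: [] for ph in DYNAMIC_PHASES}
    whole_rows: list = []
    used: list[int] = []
    for k, stride in enumerate(strides):
        mine = {l.phase: l.interval for l in labels if stride.contains(l.interval)}
        if not all(ph in mine and len(mine[ph]) >= 2 for ph in DYNAMIC_PHASES):
            continue
        for ph in DYNAMIC_PHASES:
            rows[ph].append(compute_features(slice_recording(rec, mine[ph]), cadence_hz))
        if include_whole:
            whole_rows.append(compute_features(slice_recording(rec, stride), cadence_hz))
        used.append(k)
    tables = {ph: pd.DataFrame(rows[ph]) for ph in DYNAMIC_PHASES}
    if include_whole:
        tables["whole"] = pd.DataFrame(whole_rows)
    return tables, used


def save_model(model: FusedStrideLengthEstimator, path) -> None:
    joblib.dump({"format_version": 1, "model": model}, path)


def load_model(path) -> FusedStrideLengthEstimator:
    payload = joblib.load(path)
    return payload["model"]
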