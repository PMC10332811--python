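"""PVALB vs non-PVALB classification from intrinsic membrane properties.

Pipeline: (1) cross-protocol feature harmonization — drop any feature for
which the recording protocol explains more than 5% of variance in a one-way
ANOVA; (2) robust standardisation (median / IQR); (3) nearest-neighbour
imputation of missing features; (4) two-class linear discriminant analysis;
(5) monotone probability calibration on the full reference set.  Calibrated
PVALB probabilities inside the configurable uncertain band (default
[0.4, 0.6], inclusive) yield the label "uncertain".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.impute import KNNImputer
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import RobustScaler

from .stats import RegressionResult, linear_regression

POSITIVE_CLASS = "PVALB"
UNCERTAIN_BAND = (0.4, 0.6)


@dataclass
class HarmonizationResult:
    retained: list[str]
    eta_squared: dict[str, float]
    threshold: float


def protocol_eta_squared(values: np.ndarray, protocol: np.ndarray) -> float:
    """Fraction of variance explained by protocol (one-way ANOVA eta²)."""
    ok = np.isfinite(values)
    values, protocol = values[ok], protocol[ok]
    groups = [values[protocol == p] for p in np.unique(protocol)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        return np.nan
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_total = ((values - grand) ** 2).sum()
    return float(ss_between / ss_total) if ss_total > 0 else np.nan


def harmonize_features(
    table: pd.DataFrame,
    feature_names: list[str] | None = None,
    threshold: float = 0.05,
) -> HarmonizationResult:
    """Exclude features whose protocol eta² strictly exceeds ``threshold``.

    Features with fewer than two non-missing values in either protocol are
    excluded with a warning (eta² undefined).
    """
    if "protocol" not in table.columns:
        raise ValueError("table needs a 'protocol' column")
    if feature_names is None:
        feature_names = [
            c for c in table.columns if c not in ("protocol", "subclass")
        ]
    protocol = table["protocol"].to_numpy()
    if np.unique(protocol).size < 2:
        raise ValueError("both protocols must be represented")
    eta2: dict[str, float] = {}
    retained: list[str] = []
    for name in feature_names:
        e = protocol_eta_squared(table[name].to_numpy(float), protocol)
        eta2[name] = e
        if np.isnan(e):
            warnings.warn(f"feature {name!r}: too few values per protocol; excluded",
                          stacklevel=2)
        elif e <= threshold:  # strict '>' excludes, boundary retained
            retained.append(name)
    return HarmonizationResult(retained, eta2, threshold)


@dataclass
class SubclassPrediction:
    pvalb_probability: float
    label: str  # {PVALB, non-PVALB, uncertain}


@dataclass
class CVReport:
    accuracy: float
    false_positive_rate: float  # non-PVALB predicted PVALB
    false_negative_rate: float  # PVALB predicted non-PVALB
    n_folds: int
    seed: int
    confusion: np.ndarray = field(default=None, repr=False)  # [[TN, FP], [FN, TP]]


class SubclassClassifier:
    """Robust-scaled, kNN-imputed linear discriminant with calibration."""

    def __init__(
        self,
        features: list[str],
        n_neighbors: int = 5,
        calibration: str = "isotonic",
        uncertain_band: tuple[float, float] = UNCERTAIN_BAND,
    ):
        if calibration not in ("isotonic", "sigmoid"):
            raise ValueError("calibration must be 'isotonic' or 'sigmoid'")
        self.features = list(features)
        self.n_neighbors = n_neighbors
        self.calibration = calibration
        self.uncertain_band = uncertain_band
        self.scaler_: RobustScaler | None = None
        self.imputer_: KNNImputer | None = None
        self.lda_: LinearDiscriminantAnalysis | None = None
        self.calibrator_ = None
        self.used_features_: list[str] | None = None

    # -- fitting ---------------------------------------------------------
    def fit(self, reference: pd.DataFrame) -> "SubclassClassifier":
        """Fit scaler, imputer and discriminant on the labelled reference."""
        y = reference["subclass"].to_numpy()
        if np.unique(y).size < 2:
            raise ValueError("reference must contain both classes")
        X = reference[self.features].to_numpy(float)
        q75, q25 = np.nanpercentile(X, [75, 25], axis=0)
        iqr = q75 - q25
        keep = iqr > 0
        if not keep.all():
            dropped = [f for f, k in zip(self.features, keep) if not k]
            warnings.warn(f"dropping zero-IQR features: {dropped}", stacklevel=2)
        self.used_features_ = [f for f, k in zip(self.features, keep) if k]
        if not self.used_features_:
            raise ValueError("no usable features")
        X = reference[self.used_features_].to_numpy(float)
        self.scaler_ = RobustScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.imputer_ = KNNImputer(n_neighbors=self.n_neighbors).fit(Xs)
        Xi = self.imputer_.transform(Xs)
        self.lda_ = LinearDiscriminantAnalysis().fit(Xi, y)
        return self

    def _raw_probability(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.used_features_].to_numpy(float)
        if np.all(np.isnan(X), axis=1).any():
            raise ValueError("some cells have all features missing")
        Xi = self.imputer_.transform(self.scaler_.transform(X))
        idx = list(self.lda_.classes_).index(POSITIVE_CLASS)
        return self.lda_.predict_proba(Xi)[:, idx]

    def calibrate(self, reference: pd.DataFrame) -> "SubclassClassifier":
        """Learn a monotone probability mapping on the full reference set."""
        p_raw = self._raw_probability(reference)
        y = (reference["subclass"].to_numpy() == POSITIVE_CLASS).astype(float)
        if self.calibration == "isotonic":
            self.calibrator_ = IsotonicRegression(
                y_min=0.0, y_max=1.0, out_of_bounds="clip"
            ).fit(p_raw, y)
        else:
            lr = LogisticRegression(C=1e6)
            lr.fit(p_raw.reshape(-1, 1), y.astype(int))
            self.calibrator_ = lr
        return self

    # -- prediction ------------------------------------------------------
    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Calibrated PVALB probability per cell."""
        p = self._raw_probability(table)
        if self.calibrator_ is None:
            return p
        if self.calibration == "isotonic":
            return self.calibrator_.predict(p)
        return self.calibrator_.predict_proba(p.reshape(-1, 1))[:, 1]

    def predict(self, table: pd.DataFrame) -> list[SubclassPrediction]:
        lo, hi = self.uncertain_band
        out = []
        for p in self.predict_proba(table):
            if lo <= p <= hi:
                label = "uncertain"
            elif p > hi:
                label = POSITIVE_CLASS
            else:
                label = "non-PVALB"
            out.append(SubclassPrediction(float(p), label))
        return out

    # -- serialization (all learned parameters explicit, no pickles) -----
    def to_json(self) -> str:
        d = {
            "features": self.features,
            "used_features": self.used_features_,
            "n_neighbors": self.n_neighbors,
            "calibration": self.calibration,
            "uncertain_band": list(self.uncertain_band),
            "scaler_center": self.scaler_.center_.tolist(),
            "scaler_scale": self.scaler_.scale_.tolist(),
            "imputer_train": np.asarray(self.imputer_._fit_X).tolist(),
            "lda_classes": self.lda_.classes_.tolist(),
            "lda_coef": self.lda_.coef_.tolist(),
            "lda_intercept": self.lda_.intercept_.tolist(),
        }
        if self.calibrator_ is not None and self.calibration == "isotonic":
            d["calibrator_x"] = self.calibrator_.X_thresholds_.tolist()
            d["calibrator_y"] = self.calibrator_.y_thresholds_.tolist()
        elif self.calibrator_ is not None:
            d["calibrator_coef"] = [float(self.calibrator_.coef_[0, 0]),
                                    float(self.calibrator_.intercept_[0])]
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SubclassClassifier":
        d = json.loads(text)
        self = cls(d["features"], d["n_neighbors"], d["calibration"],
                   tuple(d["uncertain_band"]))
        self.used_features_ = d["used_features"]
        p = len(self.used_features_)
        self.scaler_ = RobustScaler()
        self.scaler_.center_ = np.array(d["scaler_center"])
        self.scaler_.scale_ = np.array(d["scaler_scale"])
        self.scaler_.n_features_in_ = p
        train = np.array(d["imputer_train"])
        self.imputer_ = KNNImputer(n_neighbors=self.n_neighbors).fit(train)
        self.lda_ = LinearDiscriminantAnalysis()
        self.lda_.classes_ = np.array(d["lda_classes"])
        self.lda_.coef_ = np.array(d["lda_coef"])
        self.lda_.intercept_ = np.array(d["lda_intercept"])
        if "calibrator_x" in d:
            iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
            iso.fit(np.array(d["calibrator_x"]), np.array(d["calibrator_y"]))
            self.calibrator_ = iso
        elif "calibrator_coef" in d:
            lr = LogisticRegression()
            coef, intercept = d["calibrator_coef"]
            lr.classes_ = np.array([0, 1])
            lr.coef_ = np.array([[coef]])
            lr.intercept_ = np.array([intercept])
            self.calibrator_ = lr
        return self


def fit_classifier(
    reference: pd.DataFrame,
    retained: list[str],
    n_neighbors: int = 5,
    calibration: str = "isotonic",
) -> SubclassClassifier:
    """Fit + calibrate on the full reference in one call."""
    clf = SubclassClassifier(retained, n_neighbors, calibration)
    clf.fit(reference)
    clf.calibrate(reference)
    return clf


def cross_validate(
    reference: pd.DataFrame,
    retained: list[str],
    n_folds: int = 5,
    seed: int = 0,
    n_neighbors: int = 5,
) -> CVReport:
    """Stratified k-fold CV of the scaling → imputation → LDA pipeline.

    Harmonization is decided once, on the full table, before this call
    (matching the original pre-alignment order; a known source of mild
    optimism).  PVALB is the positive class for FPR/FNR.
    """
    y = reference["subclass"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need both classes for cross-validation")
    min_count = counts.min()
    if min_count < n_folds:
        warnings.warn(
            f"reducing folds from {n_folds} to {min_count} (smallest class)",
            stacklevel=2,
        )
        n_folds = int(min_count)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    tn = fp = fn = tp = 0
    for train_idx, test_idx in skf.split(reference, y):
        train = reference.iloc[train_idx]
        test = reference.iloc[test_idx]
        clf = SubclassClassifier(retained, n_neighbors).fit(train)
        p = clf._raw_probability(test)
        pred_pos = p > 0.5
        true_pos = test["subclass"].to_numpy() == POSITIVE_CLASS
        tp += int(np.sum(pred_pos & true_pos))
        tn += int(np.sum(~pred_pos & ~true_pos))
        fp += int(np.sum(pred_pos & ~true_pos))
        fn += int(np.sum(~pred_pos & true_pos))
    total = tn + fp + fn + tp
    return CVReport(
        accuracy=(tp + tn) / total,
        false_positive_rate=fp / (fp + tn) if fp + tn else np.nan,
        false_negative_rate=fn / (fn + tp) if fn + tp else np.nan,
        n_folds=n_folds,
        seed=seed,
        confusion=np.array([[tn, fp], [fn, tp]]),
    )


def embed(
    table: pd.DataFrame,
    retained: list[str],
    seed: int = 0,
    n_neighbors: int = 15,
) -> np.ndarray:
    """2-D UMAP embedding of scaled, imputed features (visualisation only)."""
    if len(table) < 4:
        raise ValueError("need at least 4 cells to embed")
    import umap  # deferred: heavy import

    X = table[retained].to_numpy(float)
    scaler = RobustScaler().fit(X)
    Xs = KNNImputer(n_neighbors=5).fit_transform(scaler.transform(X))
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, len(table) - 1),
        random_state=seed,
    )
    return reducer.fit_transform(Xs)


def probability_correlations(
    probabilities: pd.Series,
    ppr: pd.Series,
    amplitudes: pd.Series,
) -> dict[str, RegressionResult]:
    """OLS of PPR and EPSP amplitude on PVALB probability (matched by index)."""
    out = {}
    for name, response in (("ppr", ppr), ("amplitude", amplitudes)):
        joined = pd.concat([probabilities, response], axis=1, join="inner").dropna()
        if len(joined) < 3:
            raise ValueError(f"fewer than 3 matched pairs for {name}")
        x = joined.iloc[:, 0].to_numpy()
        y = joined.iloc[:, 1].to_numpy()
        out[name] = linear_regression(x, y)
    return out
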