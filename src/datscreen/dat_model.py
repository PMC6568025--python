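"""Training and application of the 0-100 DAT screening classifiers.

Two models over the eight recording-level features: an L2-penalized
logistic regression (linear) and a bagged ensemble of Gaussian-RBF
support-vector classifiers (nonlinear).  Each SVC base is fit on a
bootstrap resample and its decision values are mapped to probabilities by
a Platt-style sigmoid fit on the base's out-of-bag rows; the ensemble
score is 100 x the mean base probability.  Scores fall in [0, 100] and
carry a risk band: low (< 20), intermediate (20-60), high (>= 60).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import expit
from scipy.stats import mannwhitneyu
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .epoch_features import MODEL_FEATURES, FEATURE_COLUMNS, PKGSummary

__all__ = [
    "LABELS",
    "ModelConfig",
    "DEFAULT_GRID",
    "DATModel",
    "DATScore",
    "SplitResult",
    "validate_cohort",
    "split_cohort",
    "Standardizer",
    "train_linear",
    "train_nonlinear",
    "tune_hyperparameters",
    "predict_score",
    "score_cohort",
    "risk_band",
]

LABELS = ("CP", "CN", "CONTROL")
SCHEMA_VERSION = 1

#: Default hyperparameter grid (standardized features): kernel width gamma
#: and inverse regularization strength C.
DEFAULT_GRID = tuple(
    (C, gamma) for C in (0.1, 1.0, 10.0) for gamma in (0.01, 0.1, 1.0)
)


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort table has the required columns and finite features."""
    missing = [c for c in ("subject_id", "label", *FEATURE_COLUMNS) if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {', '.join(missing)}")
    bad = set(table["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"unknown label(s): {sorted(bad)}")
    feats = table[list(FEATURE_COLUMNS)].to_numpy(float)
    if not np.isfinite(feats).all():
        raise ValueError("non-finite feature values in cohort table")
    return table


def _binary_labels(labels) -> np.ndarray:
    """CP -> 1, CN -> 0; controls are not part of supervised fitting."""
    labels = np.asarray(labels)
    if not set(np.unique(labels)) <= {"CP", "CN"}:
        raise ValueError("supervised operations accept CP/CN rows only")
    y = (labels == "CP").astype(int)
    if np.unique(y).size < 2:
        raise ValueError("degenerate labels")
    return y


# ---------------------------------------------------------------------------
# Cohort splitting

@dataclass
class SplitResult:
    construction: pd.DataFrame
    test: pd.DataFrame
    n_redraws: int
    min_p: float
    similarity_ok: bool


def _largest_remainder(total: int, sizes: dict, n: int) -> dict:
    exact = {c: total * sizes[c] / n for c in sizes}
    counts = {c: int(np.floor(exact[c])) for c in sizes}
    leftover = total - sum(counts.values())
    order = sorted(sizes, key=lambda c: exact[c] - np.floor(exact[c]), reverse=True)
    for c in order[:leftover]:
        counts[c] += 1
    return counts


def _stratified_draw(table: pd.DataFrame, n_construction: int, n_test: int, rng: np.random.Generator):
    """Class-stratified random assignment with largest-remainder rounding."""
    n = len(table)
    classes = table["label"].to_numpy()
    uniq = sorted(set(classes))
    sizes = {c: int((classes == c).sum()) for c in uniq}
    counts_c = _largest_remainder(n_construction, sizes, n)
    counts_t = _largest_remainder(n_test, sizes, n)
    cons_idx, test_idx = [], []
    for c in uniq:
        idx = np.flatnonzero(classes == c)
        rng.shuffle(idx)
        cons_idx.extend(idx[: counts_c[c]])
        test_idx.extend(idx[counts_c[c]: counts_c[c] + counts_t[c]])
    cons_idx = np.sort(np.asarray(cons_idx))
    test_idx = np.sort(np.asarray(test_idx))
    return table.iloc[cons_idx].reset_index(drop=True), table.iloc[test_idx].reset_index(drop=True)


def _split_similarity_p(construction: pd.DataFrame, test: pd.DataFrame, feature_cols) -> float:
    """Smallest Mann-Whitney p over features x classes between the two sets."""
    pmin = 1.0
    for c in sorted(set(construction["label"])):
        a = construction[construction["label"] == c]
        b = test[test["label"] == c]
        if a.empty or b.empty:
            return 0.0
        for f in feature_cols:
            x = a[f].to_numpy(float)
            y = b[f].to_numpy(float)
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                continue  # identical constants: trivially similar
            p = mannwhitneyu(x, y, alternative="two-sided").pvalue
            pmin = min(pmin, float(p))
    return pmin


def split_cohort(
    cohort: pd.DataFrame,
    n_construction: int,
    n_test: int,
    seed: int,
    feature_cols=FEATURE_COLUMNS,
    p_threshold: float = 0.05,
    max_redraws: int = 100,
) -> SplitResult:
    """Class-stratified construction/test split with a similarity check.

    After each seeded draw, every feature is compared between matched
    classes of the two sets with a two-sided Mann-Whitney test; if any
    p <= ``p_threshold`` the split is redrawn with an incremented seed.
    After ``max_redraws`` failures the most similar split seen is returned
    with a warning.
    """
    validate_cohort(cohort)
    if n_construction + n_test > len(cohort):
        raise ValueError("n_construction + n_test exceeds cohort size")
    if n_construction < 2 or n_test < 2:
        raise ValueError("both sets need at least 2 rows")
    classes = set(cohort["label"])
    if len(classes - {"CONTROL"}) < 2:
        raise ValueError("both CP and CN must be present")
    best = None
    best_p = -1.0
    for attempt in range(max_redraws + 1):
        rng = np.random.default_rng(seed + attempt)
        cons, test = _stratified_draw(cohort, n_construction, n_test, rng)
        if not (set(cons["label"]) >= classes and set(test["label"]) >= classes):
            continue
        pmin = _split_similarity_p(cons, test, feature_cols)
        if pmin > best_p:
            best, best_p = (cons, test), pmin
        if pmin > p_threshold:
            return SplitResult(cons, test, attempt, pmin, True)
    if best is None:
        raise ValueError("could not draw a split containing every class on both sides")
    warnings.warn(
        f"no split passed the similarity check after {max_redraws} redraws; "
        f"returning the most similar one (min p = {best_p:.4f})"
    )
    return SplitResult(best[0], best[1], max_redraws, best_p, False)


# ---------------------------------------------------------------------------
# Standardization

class Standardizer:
    """Per-feature z-scoring with statistics estimated on training rows."""

    def __init__(self) -> None:
        self.center: np.ndarray | None = None
        self.scale: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("cannot standardize an empty training set")
        self.center = X.mean(axis=0)
        scale = X.std(axis=0)  # population scale
        zero = scale == 0
        if zero.any():
            warnings.warn("zero-variance feature(s); scale set to 1")
            scale = np.where(zero, 1.0, scale)
        self.scale = scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.center is None:
            raise ValueError("standardizer not fitted")
        return (np.asarray(X, dtype=float) - self.center) / self.scale


def standardize_fit_apply(train: np.ndarray, other: np.ndarray | None = None):
    """Fit z-scoring on ``train`` and apply it to both arrays."""
    std = Standardizer().fit(train)
    train_t = std.transform(train)
    other_t = std.transform(other) if other is not None else None
    return train_t, other_t, std


# ---------------------------------------------------------------------------
# Models

@dataclass(frozen=True)
class ModelConfig:
    features: tuple[str, ...] = MODEL_FEATURES
    C: float = 1.0
    gamma: float = 0.1
    n_estimators: int = 100
    bootstrap: bool = True


@dataclass
class RBFBase:
    """One trained RBF max-margin base with its sigmoid calibration."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    platt_a: float
    platt_b: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        K = np.exp(-self.gamma * cdist(X, self.support_vectors, "sqeuclidean"))
        return K @ self.dual_coef + self.intercept

    def probability(self, X: np.ndarray) -> np.ndarray:
        return expit(self.platt_a * self.decision(X) + self.platt_b)


@dataclass
class DATScore:
    value: float
    band: str


@dataclass
class DATModel:
    """A fitted linear or bagged-nonlinear screening classifier."""

    kind: str  # "linear" | "nonlinear"
    features: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    weights: np.ndarray | None = None  # linear
    bias: float | None = None
    bases: list[RBFBase] = field(default_factory=list)  # nonlinear
    config: ModelConfig | None = None
    seed: int | None = None
    schema_version: int = SCHEMA_VERSION

    # -- scoring ----------------------------------------------------------
    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.features if f not in X.columns]
            if missing:
                raise KeyError(f"missing feature(s): {', '.join(missing)}")
            X = X[list(self.features)].to_numpy(float)
        elif isinstance(X, (dict, pd.Series, PKGSummary)):
            d = X.as_dict() if isinstance(X, PKGSummary) else dict(X)
            missing = [f for f in self.features if f not in d]
            if missing:
                raise KeyError(f"missing feature(s): {', '.join(missing)}")
            X = np.array([[float(d[f]) for f in self.features]])
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")
        return (X - self.center) / self.scale

    def scores(self, X) -> np.ndarray:
        """0-100 scores for one or more feature rows."""
        Z = self._matrix(X)
        if self.kind == "linear":
            return 100.0 * expit(Z @ self.weights + self.bias)
        probs = np.mean([b.probability(Z) for b in self.bases], axis=0)
        return 100.0 * probs

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "schema_version": self.schema_version,
            "kind": self.kind,
            "features": list(self.features),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "seed": self.seed,
            "config": asdict(self.config) | {"features": list(self.config.features)}
            if self.config else None,
        }
        if self.kind == "linear":
            doc["weights"] = self.weights.tolist()
            doc["bias"] = self.bias
        else:
            doc["bases"] = [
                {
                    "support_vectors": b.support_vectors.tolist(),
                    "dual_coef": b.dual_coef.tolist(),
                    "intercept": b.intercept,
                    "gamma": b.gamma,
                    "platt_a": b.platt_a,
                    "platt_b": b.platt_b,
                }
                for b in self.bases
            ]
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DATModel":
        doc = json.loads(text)
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        cfg = doc.get("config")
        config = ModelConfig(**{**cfg, "features": tuple(cfg["features"])}) if cfg else None
        model = cls(
            kind=doc["kind"],
            features=tuple(doc["features"]),
            center=np.asarray(doc["center"], float),
            scale=np.asarray(doc["scale"], float),
            config=config,
            seed=doc.get("seed"),
        )
        if model.kind == "linear":
            model.weights = np.asarray(doc["weights"], float)
            model.bias = float(doc["bias"])
        else:
            model.bases = [
                RBFBase(
                    support_vectors=np.asarray(b["support_vectors"], float),
                    dual_coef=np.asarray(b["dual_coef"], float),
                    intercept=float(b["intercept"]),
                    gamma=float(b["gamma"]),
                    platt_a=float(b["platt_a"]),
                    platt_b=float(b["platt_b"]),
                )
                for b in doc["bases"]
            ]
        return model


def _design(table: pd.DataFrame, features) -> tuple[np.ndarray, np.ndarray]:
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise KeyError(f"missing feature(s): {', '.join(missing)}")
    X = table[list(features)].to_numpy(float)
    y = _binary_labels(table["label"].to_numpy())
    return X, y


def train_linear(construction: pd.DataFrame, config: ModelConfig = ModelConfig()) -> DATModel:
    """L2-penalized logistic regression; score = 100 * sigmoid(w.z + b)."""
    X, y = _design(construction, config.features)
    Z, _, std = standardize_fit_apply(X)
    clf = LogisticRegression(C=config.C, solver="lbfgs", max_iter=5000)  # L2 penalty (default)
    clf.fit(Z, y)
    return DATModel(
        kind="linear",
        features=tuple(config.features),
        center=std.center,
        scale=std.scale,
        weights=clf.coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        config=config,
    )


def _fit_platt(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=500)
    lr.fit(decision.reshape(-1, 1), y)
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def train_nonlinear(
    construction: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
    return_oob: bool = False,
):
    """Bagged Gaussian-RBF SVC ensemble with per-base Platt calibration.

    Each base is fit on a size-n bootstrap resample (redrawn if single
    class); its sigmoid is fit on the base's out-of-bag rows, falling back
    to the full construction set when those are single-class.

    With ``return_oob=True`` also returns out-of-bag 0-100 scores for the
    construction rows (each row scored only by bases whose resample missed
    it).  Resubstitution scores of a bagged ensemble are optimistically
    separated, so operating thresholds should be chosen on these instead.
    """
    if config.n_estimators < 1:
        raise ValueError("ensemble size must be >= 1")
    X, y = _design(construction, config.features)
    Z, _, std = standardize_fit_apply(X)
    n = len(y)
    bases: list[RBFBase] = []
    oob_prob_sum = np.zeros(n)
    oob_count = np.zeros(n)
    root = np.random.SeedSequence(seed)
    children = root.spawn(config.n_estimators)
    for child in children:
        rng = np.random.default_rng(child)
        if config.bootstrap:
            for _ in range(1000):
                idx = rng.integers(0, n, n)
                if np.unique(y[idx]).size == 2:
                    break
            else:
                raise ValueError("could not draw a two-class bootstrap resample")
        else:
            idx = np.arange(n)
        svc = SVC(C=config.C, kernel="rbf", gamma=config.gamma)
        svc.fit(Z[idx], y[idx])
        oob = np.setdiff1d(np.arange(n), np.unique(idx))
        if oob.size >= 2 and np.unique(y[oob]).size == 2:
            cal_idx = oob
        else:
            cal_idx = np.arange(n)
        base = RBFBase(
            support_vectors=svc.support_vectors_.copy(),
            dual_coef=svc.dual_coef_[0].copy(),
            intercept=float(svc.intercept_[0]),
            gamma=float(svc._gamma),
            platt_a=0.0,
            platt_b=0.0,
        )
        base.platt_a, base.platt_b = _fit_platt(base.decision(Z[cal_idx]), y[cal_idx])
        if oob.size:
            oob_prob_sum[oob] += base.probability(Z[oob])
            oob_count[oob] += 1
        bases.append(base)
    model = DATModel(
        kind="nonlinear",
        features=tuple(config.features),
        center=std.center,
        scale=std.scale,
        bases=bases,
        config=config,
        seed=seed,
    )
    if not return_oob:
        return model
    oob_scores = np.where(
        oob_count > 0,
        100.0 * oob_prob_sum / np.maximum(oob_count, 1),
        model.scores(construction),  # never-left-out rows: fall back
    )
    return model, oob_scores


def tune_hyperparameters(
    construction: pd.DataFrame,
    grid=DEFAULT_GRID,
    k: int = 5,
    seed: int = 0,
    features=MODEL_FEATURES,
) -> ModelConfig:
    """Stratified k-fold grid search maximizing mean out-of-fold ROC AUC.

    A single (un-bagged) RBF base is fit per fold; its decision values are
    a monotone proxy for the calibrated ensemble score, so AUC is
    unchanged, and tuning stays cheap.  Ties prefer stronger
    regularization (smaller C), then smaller gamma.
    """
    grid = list(dict.fromkeys(grid))
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if k < 2:
        raise ValueError("k must be >= 2")
    X, y = _design(construction, features)
    if np.bincount(y).min() < k:
        raise ValueError("too few rows of one class for the requested folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    results = []
    for C, gamma in grid:
        aucs = []
        for tr, va in folds:
            Ztr, Zva, _ = standardize_fit_apply(X[tr], X[va])
            svc = SVC(C=C, kernel="rbf", gamma=gamma)
            svc.fit(Ztr, y[tr])
            aucs.append(roc_auc_score(y[va], svc.decision_function(Zva)))
        results.append((np.mean(aucs), C, gamma))
    best = max(results, key=lambda r: (r[0], -r[1], -r[2]))
    return ModelConfig(features=tuple(features), C=best[1], gamma=best[2])


def risk_band(value: float) -> str:
    """Risk band for a 0-100 score: low < 20 <= intermediate < 60 <= high."""
    if not 0.0 <= value <= 100.0:
        raise ValueError("score must be in [0, 100]")
    if value < 20.0:
        return "low"
    if value < 60.0:
        return "intermediate"
    return "high"


def predict_score(model: DATModel, x) -> DATScore:
    """Score one recording summary and attach its risk band."""
    value = float(model.scores(x)[0])
    value = min(max(value, 0.0), 100.0)
    return DATScore(value=value, band=risk_band(value))


def score_cohort(model: DATModel, table: pd.DataFrame) -> np.ndarray:
    """0-100 scores for every row of a cohort table."""
    return model.scores(table)
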