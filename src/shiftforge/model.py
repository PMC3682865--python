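"""Per-super-class regression of chemical shifts.

One random forest is trained per atom super class (500 trees by default;
the number of split candidates ``mtry`` is tuned by a doubling/halving
sweep around p/3 on out-of-bag error).  The estimator follows the sklearn
protocol — ``fit(X, y)`` / ``predict(X)`` on a DataFrame carrying a
``super_class`` column next to the feature columns — so it composes with
sklearn model selection; the module-level ``split_dataset`` /
``train_models`` / ``evaluate`` functions are thin wrappers.

Evaluation reports, per class, the root-mean-square error

    rmse = sqrt( sum_i (d_exp_i - d_pred_i)^2 / n )

and the sample-normalized Pearson correlation

    corr = 1/(n-1) * sum_i [(d_exp_i - mean_exp)/s_exp]
                         * [(d_pred_i - mean_pred)/s_pred]

with s the (n-1)-denominator sample standard deviations.  corr is
undefined (reported as None) for n < 2 or zero-variance vectors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor

from .records import MISSING, Dataset, TEST, TRAIN, UNASSIGNED
from .superclass import SuperClassScheme, default_scheme

DEFAULT_TRAIN_FRACTION = 0.6
DEFAULT_MIN_CLASS_SIZE = 50


# ---------------------------------------------------------------------------
# metrics


def rmse(exp, pred) -> float:
    """Root mean square error between experimental and predicted shifts."""
    exp = np.asarray(exp, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if exp.shape != pred.shape or exp.ndim != 1:
        raise ValueError("rmse needs two equal-length 1-d vectors")
    if exp.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((exp - pred) ** 2)))


def pearson_corr(exp, pred) -> float | None:
    """Sample-normalized Pearson correlation; None when undefined."""
    exp = np.asarray(exp, dtype=float)
    pred = np.asarray(pred, dtype=float)
    n = exp.size
    if n < 2:
        return None
    s_exp = exp.std(ddof=1)
    s_pred = pred.std(ddof=1)
    if s_exp == 0.0 or s_pred == 0.0:
        return None
    z = ((exp - exp.mean()) / s_exp) * ((pred - pred.mean()) / s_pred)
    return float(z.sum() / (n - 1))


@dataclass
class EvaluationResult:
    """Per-class test metrics with the moment intermediates."""

    super_class: str
    n: int
    rmse: float | None
    corr: float | None
    mean_exp: float | None = None
    mean_pred: float | None = None
    sd_exp: float | None = None
    sd_pred: float | None = None

    def __post_init__(self) -> None:
        if self.corr is not None and not -1.0 - 1e-12 <= self.corr <= 1.0 + 1e-12:
            raise ValueError(f"corr out of [-1,1]: {self.corr}")
        if self.rmse is not None and self.rmse < 0:
            raise ValueError("rmse must be >= 0")


# ---------------------------------------------------------------------------
# dataset split


def split_dataset(dataset: Dataset, train_fraction: float = DEFAULT_TRAIN_FRACTION,
                  seed: int = 0) -> Dataset:
    """Partition a dataset into train/test at the structure level.

    All atoms of one pdb_id land on the same side, preventing leakage of
    intra-protein correlation across the split.  The number of training
    structures is round-half-up of (structure count x fraction);
    deterministic per seed.
    """
    if not dataset.records:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train fraction must be in (0,1): {train_fraction}")
    already = {dataset.partition[r.key] for r in dataset.records}
    if already - {UNASSIGNED}:
        raise ValueError("dataset is already partitioned")
    structures = sorted({r.pdb_id for r in dataset.records})
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(structures))
    n_train = math.floor(len(structures) * train_fraction + 0.5)
    train_ids = set(order[:n_train])
    for r in dataset.records:
        dataset.partition[r.key] = TRAIN if r.pdb_id in train_ids else TEST
    dataset.provenance["split"] = {
        "train_fraction": train_fraction, "seed": seed,
        "n_structures": len(structures), "n_train_structures": n_train,
    }
    return dataset


# ---------------------------------------------------------------------------
# model backends

MODEL_BACKENDS: dict[str, object] = {}


class UnknownBackendError(ValueError):
    pass


def register_backend(name: str, factory, replace: bool = False) -> None:
    if name in MODEL_BACKENDS and not replace:
        raise ValueError(f"backend already registered: {name!r}")
    MODEL_BACKENDS[name] = factory


def _rf_factory(n_estimators, max_features, random_state, oob=False):
    return RandomForestRegressor(
        n_estimators=n_estimators,
        max_features=max_features,
        oob_score=oob,
        bootstrap=True,
        random_state=random_state,
        n_jobs=1,
    )


register_backend("rf", _rf_factory)


# ---------------------------------------------------------------------------
# the estimator


class SuperClassRandomForest(BaseEstimator, RegressorMixin):
    """One regression model per atom super class.

    Parameters
    ----------
    n_estimators : trees per forest (default 500).
    min_class_size : classes with fewer training rows are skipped with a
        warning rather than fitted (default 50).
    tune_mtry : when True, the per-split candidate count is chosen by a
        doubling/halving sweep around p/3 minimizing out-of-bag error
        (100-tree forests for the sweep, full size for the final fit).
    backend : name of a registered model backend ("rf").
    class_column : column of X holding the super-class label.
    random_state : seed for every stochastic component.

    Fitted attributes (per sklearn convention, trailing underscore):
    ``models_`` (class -> fitted regressor), ``encodings_`` (class ->
    encoding metadata), ``classes_``, ``skipped_classes_``,
    ``feature_names_in_``, ``feature_kinds_``.
    """

    def __init__(self, n_estimators: int = 500,
                 min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
                 tune_mtry: bool = True, backend: str = "rf",
                 class_column: str = "super_class",
                 random_state: int | None = None):
        self.n_estimators = n_estimators
        self.min_class_size = min_class_size
        self.tune_mtry = tune_mtry
        self.backend = backend
        self.class_column = class_column
        self.random_state = random_state

    # -- encoding ---------------------------------------------------------

    @staticmethod
    def _feature_kinds(X: pd.DataFrame, feature_cols: list[str]
                       ) -> dict[str, str]:
        kinds = {}
        for c in feature_cols:
            col = X[c].mask(X[c] == MISSING)
            numeric = pd.to_numeric(col, errors="coerce")
            kinds[c] = ("numeric"
                        if numeric.notna().sum() >= col.notna().sum()
                        else "categorical")
        return kinds

    def _encode(self, X: pd.DataFrame, enc: dict, fit: bool) -> np.ndarray:
        cols = []
        names = []
        for c in enc["feature_names"]:
            kind = enc["kinds"][c]
            col = X[c].mask(X[c] == MISSING)
            if kind == "numeric":
                v = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
                miss = np.isnan(v)
                if fit:
                    med = float(np.nanmedian(v)) if (~miss).any() else 0.0
                    enc["medians"][c] = med
                v = np.where(miss, enc["medians"][c], v)
                cols.append(v)
                names.append(c)
                cols.append(miss.astype(float))
                names.append(f"{c}__missing")
            else:
                vals = col.fillna(MISSING).astype(str)
                if fit:
                    enc["categories"][c] = sorted(vals.unique())
                for cat in enc["categories"][c]:
                    cols.append((vals == cat).to_numpy(dtype=float))
                    names.append(f"{c}={cat}")
        enc["encoded_names"] = names
        return np.column_stack(cols) if cols else np.empty((len(X), 0))

    # -- sklearn API ------------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "SuperClassRandomForest":
        if self.backend not in MODEL_BACKENDS:
            raise UnknownBackendError(
                f"unknown model backend {self.backend!r}; "
                f"registered: {sorted(MODEL_BACKENDS)}"
            )
        factory = MODEL_BACKENDS[self.backend]
        if self.class_column not in X.columns:
            raise ValueError(f"X lacks class column {self.class_column!r}")
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        feature_cols = [c for c in X.columns if c != self.class_column]
        self.feature_names_in_ = list(feature_cols)
        self.feature_kinds_ = self._feature_kinds(X, feature_cols)
        self.models_ = {}
        self.encodings_ = {}
        self.skipped_classes_ = []
        self.train_meta_ = {}
        labels = X[self.class_column].astype(str)
        for label in sorted(labels[labels != "None"].unique()):
            mask = (labels == label).to_numpy()
            n_rows = int(mask.sum())
            if n_rows < self.min_class_size:
                self.skipped_classes_.append(label)
                import logging

                logging.getLogger("shiftforge").warning(
                    "super class %s has %d rows < min_class_size %d; "
                    "skipped", label, n_rows, self.min_class_size,
                )
                continue
            enc = {"feature_names": feature_cols,
                   "kinds": self.feature_kinds_,
                   "medians": {}, "categories": {}}
            Xc = self._encode(X.loc[mask], enc, fit=True)
            yc = y[mask]
            p = Xc.shape[1]
            mtry = self._tune_mtry(factory, Xc, yc, p) if self.tune_mtry \
                else max(1, round(p / 3))
            model = factory(self.n_estimators, mtry, self.random_state)
            model.fit(Xc, yc)
            self.models_[label] = model
            self.encodings_[label] = enc
            self.train_meta_[label] = {
                "n": n_rows, "mtry": mtry, "p_encoded": p,
                "n_estimators": self.n_estimators,
                "random_state": self.random_state,
            }
        if not self.models_:
            raise ValueError(
                "no trainable super class (all below min_class_size)")
        self.classes_ = sorted(self.models_)
        return self

    def _tune_mtry(self, factory, Xc, yc, p: int) -> int:
        """Doubling/halving sweep around p/3 on out-of-bag error.

        Starting from p/3, mtry is doubled while the OOB error keeps
        improving, then halved from the start likewise (the classic
        random-forest tuning walk); 100-tree forests keep the sweep cheap.
        """
        def oob_error(c: int) -> float:
            m = factory(100, c, self.random_state, oob=True)
            m.fit(Xc, yc)
            return 1.0 - float(m.oob_score_)  # oob_score_ is R^2

        base = max(1, round(p / 3))
        errors = {base: oob_error(base)}
        best = (errors[base], base)
        c = base
        while c < p:
            c = min(p, c * 2)
            errors[c] = oob_error(c)
            if errors[c] < best[0] - 1e-12:
                best = (errors[c], c)
            else:
                break
        c = base
        while c > 1:
            c = max(1, c // 2)
            errors[c] = oob_error(c)
            if errors[c] < best[0] - 1e-12:
                best = (errors[c], c)
            else:
                break
        return best[1]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "models_"):
            raise ValueError("estimator is not fitted")
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        if missing:
            raise ValueError(f"X lacks feature columns {missing}")
        out = np.full(len(X), np.nan)
        labels = X[self.class_column].astype(str)
        for label, model in self.models_.items():
            mask = (labels == label).to_numpy()
            if not mask.any():
                continue
            Xc = self._encode(X.loc[mask], self.encodings_[label], fit=False)
            out[mask] = model.predict(Xc)
        return out

    # -- introspection ----------------------------------------------------

    def feature_importance(self) -> dict[str, list[tuple[str, float]]]:
        """Per class, (feature, importance) descending, aggregated back to
        the original feature names (one-hot/indicator columns summed)."""
        out = {}
        for label, model in self.models_.items():
            if not hasattr(model, "feature_importances_"):
                import logging

                logging.getLogger("shiftforge").warning(
                    "backend for class %s exposes no importances", label)
                out[label] = []
                continue
            enc = self.encodings_[label]
            agg: dict[str, float] = {}
            for name, imp in zip(enc["encoded_names"],
                                 model.feature_importances_):
                src = name.split("=", 1)[0].split("__missing", 1)[0]
                agg[src] = agg.get(src, 0.0) + float(imp)
            out[label] = sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))
        return out

    def importance_above_noise(self) -> dict[str, int]:
        """Features per class with importance above the uniform share
        1/p_features (the backend's noise floor for impurity importance)."""
        out = {}
        for label, ranked in self.feature_importance().items():
            floor = 1.0 / max(1, len(ranked))
            out[label] = sum(1 for _, imp in ranked if imp > floor)
        return out


# ---------------------------------------------------------------------------
# record-level wrappers


def records_to_frame(records, scheme: SuperClassScheme | None = None,
                     feature_names: list[str] | None = None
                     ) -> tuple[pd.DataFrame, np.ndarray]:
    """DataFrame (super_class + features) and target vector from records."""
    scheme = scheme or default_scheme()
    rows = []
    y = []
    for r in records:
        label = r.super_class or scheme.assign(r.atom_name, r.residue_type)
        row = {"super_class": str(label)}
        row.update(r.features)
        rows.append(row)
        y.append(r.experimental_shift)
    frame = pd.DataFrame(rows)
    if feature_names is not None:
        frame = frame[["super_class"] + list(feature_names)]
    return frame, np.asarray(y, dtype=float)


def train_models(dataset: Dataset, scheme: SuperClassScheme | None = None,
                 backend: str = "rf", n_estimators: int = 500,
                 min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
                 tune_mtry: bool = True, seed: int = 0
                 ) -> SuperClassRandomForest:
    """Fit one model per super class on the training partition."""
    train = dataset.train_records
    if not train:
        raise ValueError("dataset has no training partition")
    X, y = records_to_frame(train, scheme)
    est = SuperClassRandomForest(
        n_estimators=n_estimators, min_class_size=min_class_size,
        tune_mtry=tune_mtry, backend=backend, random_state=seed,
    )
    return est.fit(X, y)


def evaluate(model: SuperClassRandomForest, dataset: Dataset,
             scheme: SuperClassScheme | None = None
             ) -> dict[str, EvaluationResult]:
    """Per-class rmse and corr of the model on the test partition."""
    test = dataset.test_records
    results: dict[str, EvaluationResult] = {}
    if not test:
        return results
    X, y = records_to_frame(test, scheme,
                            feature_names=model.feature_names_in_)
    pred = model.predict(X)
    labels = X["super_class"].to_numpy()
    for label in model.classes_:
        mask = labels == label
        n = int(mask.sum())
        if n == 0:
            results[label] = EvaluationResult(label, 0, None, None)
            continue
        e, p = y[mask], pred[mask]
        corr = pearson_corr(e, p)
        results[label] = EvaluationResult(
            super_class=label, n=n, rmse=rmse(e, p), corr=corr,
            mean_exp=float(e.mean()), mean_pred=float(p.mean()),
            sd_exp=float(e.std(ddof=1)) if n > 1 else None,
            sd_pred=float(p.std(ddof=1)) if n > 1 else None,
        )
    return results


def pooled_metrics(model: SuperClassRandomForest, dataset: Dataset,
                   scheme: SuperClassScheme | None = None
                   ) -> tuple[float, float | None, int]:
    """(rmse, corr, n) over all covered test atoms of every class."""
    test = dataset.test_records
    X, y = records_to_frame(test, scheme,
                            feature_names=model.feature_names_in_)
    pred = model.predict(X)
    ok = ~np.isnan(pred)
    if not ok.any():
        raise ValueError("no test atom is covered by the model")
    return rmse(y[ok], pred[ok]), pearson_corr(y[ok], pred[ok]), int(ok.sum())


def permute_shifts_within_class(dataset: Dataset, seed: int = 0,
                                scheme: SuperClassScheme | None = None
                                ) -> Dataset:
    """Negative control: shuffle training shifts within each super class.

    Destroys any feature-shift association while preserving each class's
    shift distribution; a sound pipeline trained on the permuted data
    should show no residual test correlation beyond class-mean structure.
    """
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(seed)
    train = dataset.train_records
    labels = np.array([
        str(r.super_class or scheme.assign(r.atom_name, r.residue_type))
        for r in train
    ])
    shifts = np.array([r.experimental_shift for r in train])
    for label in np.unique(labels):
        idx = np.where(labels == label)[0]
        shifts[idx] = shifts[rng.permutation(idx)]
    for r, v in zip(train, shifts):
        r.experimental_shift = float(v)
    return dataset


# ---------------------------------------------------------------------------
# persistence: one binary artifact per class + JSON sidecar


def save_models(model: SuperClassRandomForest, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "format_version": 1,
        "backend": model.backend,
        "feature_names": model.feature_names_in_,
        "feature_kinds": model.feature_kinds_,
        "classes": model.classes_,
        "skipped_classes": model.skipped_classes_,
        "train_meta": model.train_meta_,
        "encodings": {
            label: {k: v for k, v in enc.items() if k != "feature_names"}
            for label, enc in model.encodings_.items()
        },
        "params": model.get_params(),
    }
    (directory / "models.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True))
    for label, m in model.models_.items():
        joblib.dump(m, directory / f"model_{label}.joblib")


def load_models(directory: str | Path) -> SuperClassRandomForest:
    directory = Path(directory)
    sidecar = json.loads((directory / "models.json").read_text())
    est = SuperClassRandomForest(**sidecar["params"])
    est.feature_names_in_ = sidecar["feature_names"]
    est.feature_kinds_ = sidecar["feature_kinds"]
    est.classes_ = sidecar["classes"]
    est.skipped_classes_ = sidecar["skipped_classes"]
    est.train_meta_ = sidecar["train_meta"]
    est.models_ = {}
    est.encodings_ = {}
    for label in est.classes_:
        est.models_[label] = joblib.load(directory / f"model_{label}.joblib")
        enc = sidecar["encodings"][label]
        enc["feature_names"] = est.feature_names_in_
        est.encodings_[label] = enc
    return est
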