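"""Per-target pIC50 regression on fingerprints with applicability-domain filtering.

Activity is modelled as pIC50 = −log10(IC50[nM] × 1e−9), regressed on binary
circular fingerprints with a random forest. The applicability domain of a
fitted model is defined by a residual-percentile rule: training-set records
whose absolute residual exceeds the q-quantile (default 95th percentile) of
the absolute residuals are excluded from further prediction, after a potency
pre-filter (pIC50 ≥ 5 by default) has removed weak binders.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .chem import (
    DEFAULT_N_BITS,
    DEFAULT_RADIUS,
    CompoundRecord,
    SchemaError,
    SmilesParseError,
    fingerprint_matrix,
    parse_and_canonicalize,
)

logger = logging.getLogger(__name__)

DEFAULT_PIC50_MIN = 5.0
DEFAULT_RESIDUAL_Q = 0.95


def ic50_to_pic50(ic50_nm) -> float:
    """pIC50 = −log10(IC50 × 1e−9) for IC50 given in nM.

    Strictly decreasing in IC50; raises for non-positive or non-finite input.
    Accepts scalars or arrays.
    """
    arr = np.asarray(ic50_nm, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"IC50 must be positive and finite, got {ic50_nm!r}")
    out = -np.log10(arr * 1e-9)
    return float(out) if np.isscalar(ic50_nm) or arr.ndim == 0 else out


def pic50_to_ic50(pic50) -> float:
    """Inverse transform: IC50[nM] = 10^(9 − pIC50)."""
    arr = np.asarray(pic50, dtype=float)
    out = np.power(10.0, 9.0 - arr)
    return float(out) if np.isscalar(pic50) or arr.ndim == 0 else out


@dataclass(frozen=True)
class ActivityRecord:
    """One training observation: a compound's IC50 against a named target."""

    compound: CompoundRecord
    target: str
    ic50_nm: float
    pic50: float

    @classmethod
    def from_ic50(cls, compound: CompoundRecord, target: str, ic50_nm: float):
        return cls(compound, target, float(ic50_nm), ic50_to_pic50(ic50_nm))


def read_activity_table(path) -> tuple[list[ActivityRecord], int]:
    """Read an activity CSV (columns: id, smiles, target, ic50_nm).

    Rows with unparseable SMILES or non-positive IC50 are logged and skipped.
    """
    df = pd.read_csv(path, dtype={"id": str})
    required = ("id", "smiles", "target", "ic50_nm")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"activity table {path} is missing column {col!r}")
    if df.empty:
        logger.warning("activity table %s is empty", path)
        return [], 0
    records: list[ActivityRecord] = []
    n_skipped = 0
    for idx, row in df.iterrows():
        try:
            canonical = parse_and_canonicalize(row["smiles"], row_index=int(idx))
            compound = CompoundRecord(
                id=str(row["id"]), smiles=str(row["smiles"]), canonical_smiles=canonical
            )
            records.append(
                ActivityRecord.from_ic50(compound, str(row["target"]), float(row["ic50_nm"]))
            )
        except (SmilesParseError, ValueError) as exc:
            logger.warning("skipping activity row %d: %s", idx, exc)
            n_skipped += 1
    return records, n_skipped


@dataclass
class QSARConfig:
    """Hyperparameters of the fingerprint random-forest regressor."""

    n_estimators: int = 500
    max_depth: int | None = None
    k_folds: int = 5
    n_bits: int = DEFAULT_N_BITS
    radius: int = DEFAULT_RADIUS
    seed: int = 0


@dataclass
class QSARModel:
    """A fitted per-target regressor with its metrics and domain cutoff."""

    target: str
    regressor: RandomForestRegressor
    feature_params: dict
    seed: int
    train_metrics: dict = field(default_factory=dict)
    test_metrics: dict = field(default_factory=dict)
    cv_metrics: list[dict] = field(default_factory=list)
    residual_cutoff: float | None = None

    def featurize(self, records) -> np.ndarray:
        compounds = [r.compound if isinstance(r, ActivityRecord) else r for r in records]
        return fingerprint_matrix(
            compounds,
            n_bits=self.feature_params["n_bits"],
            radius=self.feature_params["radius"],
        )

    def predict(self, records) -> np.ndarray:
        """Predicted pIC50 for compound or activity records."""
        return self.regressor.predict(self.featurize(records).astype(float))

    def save(self, out_dir) -> None:
        """Serialize to a directory bundle: params JSON + regressor pickle."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "target": self.target,
            "feature_params": self.feature_params,
            "seed": self.seed,
            "train_metrics": self.train_metrics,
            "test_metrics": self.test_metrics,
            "cv_metrics": self.cv_metrics,
            "residual_cutoff": self.residual_cutoff,
            "format_version": 1,
        }
        (out / "model.json").write_text(json.dumps(meta, indent=2))
        with open(out / "regressor.pkl", "wb") as fh:
            pickle.dump(self.regressor, fh)

    @classmethod
    def load(cls, in_dir) -> "QSARModel":
        path = Path(in_dir)
        meta = json.loads((path / "model.json").read_text())
        with open(path / "regressor.pkl", "rb") as fh:
            regressor = pickle.load(fh)
        return cls(
            target=meta["target"],
            regressor=regressor,
            feature_params=meta["feature_params"],
            seed=meta["seed"],
            train_metrics=meta["train_metrics"],
            test_metrics=meta["test_metrics"],
            cv_metrics=meta["cv_metrics"],
            residual_cutoff=meta["residual_cutoff"],
        )


def split_dataset(records: list, train_fraction: float = 0.8, seed: int = 0):
    """Random disjoint train/test partition; train size = round(n × fraction)."""
    n = len(records)
    if n < 2:
        raise ValueError(f"need at least 2 records to split, got {n}")
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)  # both sides non-empty
    train_idx, test_idx = order[:n_train], order[n_train:]
    return [records[i] for i in train_idx], [records[i] for i in test_idx]


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """MSE, R², MAE, RMSE for a prediction vector (rmse == sqrt(mse) exactly)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise ValueError("cannot evaluate on empty data")
    err = y_true - y_pred
    mse = float(np.mean(err**2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else (1.0 if mse == 0 else 0.0)
    return {
        "mse": mse,
        "r2": r2,
        "mae": float(np.mean(np.abs(err))),
        "rmse": float(np.sqrt(mse)),
    }


def train_qsar(train: list[ActivityRecord], config: QSARConfig | None = None) -> QSARModel:
    """Fit a random-forest pIC50 regressor on one target's training records.

    K-fold cross-validation metrics are computed during training and retained
    on the model. Deterministic under a fixed config seed.
    """
    config = config or QSARConfig()
    if not train:
        raise ValueError("empty training set")
    targets = {r.target for r in train}
    if len(targets) > 1:
        raise ValueError(f"training set mixes targets: {sorted(targets)}")
    if len(train) < config.k_folds:
        raise ValueError(
            f"{len(train)} records is fewer than k_folds={config.k_folds}"
        )
    y = np.array([r.pic50 for r in train], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite pIC50 in training set")
    feature_params = {"n_bits": config.n_bits, "radius": config.radius}
    X = fingerprint_matrix(
        [r.compound for r in train], n_bits=config.n_bits, radius=config.radius
    ).astype(float)

    cv_metrics = []
    kf = KFold(n_splits=config.k_folds, shuffle=True, random_state=config.seed)
    for fold, (tr, va) in enumerate(kf.split(X)):
        rf = RandomForestRegressor(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            random_state=config.seed,
            n_jobs=1,
        )
        rf.fit(X[tr], y[tr])
        m = evaluate_predictions(y[va], rf.predict(X[va]))
        m["fold"] = fold
        cv_metrics.append(m)

    regressor = RandomForestRegressor(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        random_state=config.seed,
        n_jobs=1,
    )
    regressor.fit(X, y)
    model = QSARModel(
        target=next(iter(targets)),
        regressor=regressor,
        feature_params=feature_params,
        seed=config.seed,
        cv_metrics=cv_metrics,
    )
    model.train_metrics = evaluate_predictions(y, regressor.predict(X))
    return model


def evaluate_model(model: QSARModel, data: list[ActivityRecord]) -> dict:
    """Evaluate a fitted model on activity records; returns mse/r2/mae/rmse."""
    if not data:
        raise ValueError("cannot evaluate on empty data")
    y = np.array([r.pic50 for r in data], dtype=float)
    return evaluate_predictions(y, model.predict(data))


def residual_cutoff(residuals, q: float = DEFAULT_RESIDUAL_Q) -> float:
    """q-quantile of absolute residuals under linear interpolation.

    Records with residual strictly above the cutoff fall outside the
    applicability domain.
    """
    res = np.asarray(residuals, dtype=float)
    if res.size == 0:
        raise ValueError("empty residual vector")
    if np.any(res < 0):
        raise ValueError("residuals must be absolute (non-negative)")
    if not 0 < q < 1:
        raise ValueError(f"quantile q must be in (0, 1), got {q}")
    return float(np.quantile(res, q, method="linear"))


@dataclass
class FilterReport:
    """Stage counts of the two-stage applicability-domain filter."""

    n_input: int
    n_after_potency: int
    n_after_residual: int
    pic50_min: float
    residual_q: float
    cutoff: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def filter_applicability(
    records: list[ActivityRecord],
    model: QSARModel,
    q: float = DEFAULT_RESIDUAL_Q,
    pic50_min: float = DEFAULT_PIC50_MIN,
) -> tuple[list[ActivityRecord], FilterReport]:
    """Two-stage domain filter on activity records.

    Stage 1 keeps records with pIC50 ≥ ``pic50_min``; stage 2 drops records
    whose absolute prediction residual exceeds the q-quantile of the stage-1
    absolute residuals. The fitted cutoff is stored on the model.
    """
    if not 0 < q < 1:
        raise ValueError(f"quantile q must be in (0, 1), got {q}")
    stage1 = [r for r in records if r.pic50 >= pic50_min]
    if not stage1:
        report = FilterReport(len(records), 0, 0, pic50_min, q, float("nan"))
        return [], report
    preds = model.predict(stage1)
    abs_res = np.abs(np.array([r.pic50 for r in stage1]) - preds)
    cutoff = residual_cutoff(abs_res, q)
    retained = [r for r, e in zip(stage1, abs_res) if e <= cutoff]
    model.residual_cutoff = cutoff
    report = FilterReport(
        n_input=len(records),
        n_after_potency=len(stage1),
        n_after_residual=len(retained),
        pic50_min=pic50_min,
        residual_q=q,
        cutoff=cutoff,
    )
    return retained, report


def pca_projection(fingerprints: np.ndarray, n_components: int = 2):
    """Centered PCA of a fingerprint matrix.

    Returns (coordinates, explained-variance fractions); fractions are
    non-increasing and sum to at most 1.
    """
    X = np.asarray(fingerprints, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if X.shape[0] < n_components:
        raise ValueError(
            f"n_components={n_components} exceeds number of rows {X.shape[0]}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_
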