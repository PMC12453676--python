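"""Feature tables, train/test splitting, classifiers and evaluation reports.

The ``|V| x d`` matrix of each frame is flattened row-major (node-major,
dimension-minor) into one row of an ``n_frames x (|V| * d)`` table; a state
label column can be attached, the table split 70/30 (stratified), and any
of seven classifier families trained and evaluated with per-class recall
("class-specific accuracy"), precision, F1, confusion matrix and overall
accuracy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trajembed.embeddings import EmbeddingSeries
from trajembed.errors import AlignmentError, ArgumentError, IntegrityError, TrainingError
from trajembed.labeling import StateLabelSeries

LABEL_COLUMN = "label"

MODEL_NAMES = (
    "logistic_regression",
    "random_forest",
    "gradient_boosting_xgb_style",
    "gradient_boosting_lgbm_style",
    "neural_network",
    "cnn_1d",
    "support_vector",
)

_SCALED_MODELS = {"logistic_regression", "neural_network", "cnn_1d", "support_vector"}


# ---------------------------------------------------------------------------
# types


@dataclass
class FeatureTable:
    """Per-frame flattened embedding features, optionally labeled."""

    df: pd.DataFrame
    n_nodes: int
    dimension: int
    provenance: str = ""

    def __post_init__(self):
        feats = self.feature_columns()
        if len(feats) != self.n_nodes * self.dimension:
            raise IntegrityError(
                f"expected {self.n_nodes * self.dimension} feature columns, got {len(feats)}"
            )
        if self.df[feats].isna().any().any():
            raise IntegrityError("feature table contains missing values")

    def feature_columns(self) -> list[str]:
        return [c for c in self.df.columns if c != LABEL_COLUMN]

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def is_labeled(self) -> bool:
        return LABEL_COLUMN in self.df.columns

    def features(self) -> np.ndarray:
        return self.df[self.feature_columns()].to_numpy(dtype=np.float64)

    def labels(self) -> np.ndarray:
        if not self.is_labeled:
            raise IntegrityError("feature table has no label column")
        return self.df[LABEL_COLUMN].to_numpy(dtype=object)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# trajembed features v1\tn_nodes={self.n_nodes}"
                     f"\tdimension={self.dimension}\tprovenance={self.provenance}\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            meta = dict(tok.split("=", 1) for tok in header.split("\t")[1:])
            df = pd.read_csv(fh, sep="\t")
        return cls(df=df, n_nodes=int(meta["n_nodes"]),
                   dimension=int(meta["dimension"]), provenance=meta.get("provenance", ""))


@dataclass
class SplitSpec:
    """Single stratified random split; default 70/30."""

    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ArgumentError(f"train_fraction must be in (0, 1), got {self.train_fraction}")


@dataclass
class ClassifierSpec:
    model: str = "logistic_regression"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODEL_NAMES:
            raise ArgumentError(f"unknown model {self.model!r}; choose from {MODEL_NAMES}")


@dataclass
class EvaluationReport:
    """Per-class recall/precision/F1, confusion matrix and overall accuracy.

    ``recall`` (the per-class "class-specific accuracy") is ``None`` for a
    class absent from the test set, never 0.
    """

    class_names: list[str]
    confusion: np.ndarray
    recall: dict[str, float | None]
    precision: dict[str, float | None]
    f1: dict[str, float | None]
    support: dict[str, int]
    accuracy: float
    model: str = ""
    split_seed: int | None = None

    def __post_init__(self):
        self.confusion = np.asarray(self.confusion, dtype=np.int64)
        total = self.confusion.sum()
        if total > 0:
            expected = float(np.trace(self.confusion)) / float(total)
            if abs(expected - self.accuracy) > 1e-12:
                raise IntegrityError("accuracy must equal trace(confusion)/sum(confusion)")

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "confusion": self.confusion.tolist(),
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "support": self.support,
            "accuracy": self.accuracy,
            "model": self.model,
            "split_seed": self.split_seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# table construction


def flatten(series: EmbeddingSeries) -> FeatureTable:
    """Row t = frame t's |V| x d matrix flattened row-major."""
    n_nodes, dim = series.n_nodes, series.dimension
    matrix = np.stack([fe.matrix.reshape(-1) for fe in series])
    names = [f"node{i}_dim{j}" for i in range(n_nodes) for j in range(dim)]
    prov = hashlib.sha256(
        json.dumps(series.config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
    return FeatureTable(
        df=pd.DataFrame(matrix, columns=names),
        n_nodes=n_nodes, dimension=dim, provenance=prov,
    )


def unflatten(table: FeatureTable) -> np.ndarray:
    """Inverse of :func:`flatten`: (n_frames, |V|, d) array."""
    return table.features().reshape(table.n_rows, table.n_nodes, table.dimension)


def attach_labels(table: FeatureTable, labels: StateLabelSeries) -> FeatureTable:
    if len(labels) != table.n_rows:
        raise AlignmentError(
            f"{table.n_rows} feature rows but {len(labels)} labels"
        )
    df = table.df.copy()
    df[LABEL_COLUMN] = np.asarray(labels.labels, dtype=object)
    return FeatureTable(df=df, n_nodes=table.n_nodes,
                        dimension=table.dimension, provenance=table.provenance)


def split(table: FeatureTable, spec: SplitSpec) -> tuple[FeatureTable, FeatureTable]:
    """Disjoint, exhaustive train/test split; train size = round(f * n)."""
    from sklearn.model_selection import train_test_split

    if not table.is_labeled:
        raise IntegrityError("split requires a labeled table")
    n = table.n_rows
    n_train = int(round(spec.train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ArgumentError(f"split of {n} rows at {spec.train_fraction} leaves an empty side")
    y = table.labels()
    stratify = None
    if spec.stratified:
        _, counts = np.unique(y.astype(str), return_counts=True)
        if counts.min() < 2:
            raise ArgumentError(
                "stratified split impossible: some class has fewer than 2 members"
            )
        stratify = y.astype(str)
    idx_train, idx_test = train_test_split(
        np.arange(n), train_size=n_train, stratify=stratify,
        random_state=spec.seed, shuffle=True,
    )

    def _sub(idx):
        return FeatureTable(
            df=table.df.iloc[np.sort(idx)].reset_index(drop=True),
            n_nodes=table.n_nodes, dimension=table.dimension, provenance=table.provenance,
        )

    return _sub(idx_train), _sub(idx_test)


# ---------------------------------------------------------------------------
# classifiers


class _CNN1D:
    """Minimal 1-D convolutional classifier over the node axis.

    Input rows are reshaped to |V| x d; a single convolution over nodes
    (d input channels) feeds a relu, global average pooling, and a softmax
    layer. Trained with Adam on cross-entropy; fully seed-deterministic.
    """

    def __init__(self, n_nodes: int, dim: int, n_filters: int = 16, kernel: int = 5,
                 epochs: int = 40, batch_size: int = 64, lr: float = 1e-3, seed: int = 0):
        self.n_nodes, self.dim = n_nodes, dim
        self.kernel = min(kernel, n_nodes)
        self.n_filters, self.epochs, self.batch_size, self.lr = n_filters, epochs, batch_size, lr
        self.seed = seed

    def fit(self, x: np.ndarray, y: np.ndarray):
        rng = np.random.default_rng(self.seed)
        self.classes_, y_idx = np.unique(y.astype(str), return_inverse=True)
        n_classes = len(self.classes_)
        kd = self.kernel * self.dim
        self.wc = rng.normal(0, np.sqrt(2.0 / kd), size=(kd, self.n_filters))
        self.bc = np.zeros(self.n_filters)
        self.wd = rng.normal(0, np.sqrt(2.0 / self.n_filters), size=(self.n_filters, n_classes))
        self.bd = np.zeros(n_classes)
        params = [self.wc, self.bc, self.wd, self.bd]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        t = 0
        n = x.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                xb, yb = x[idx], y_idx[idx]
                cols, h, pooled, probs = self._forward(xb)
                b = xb.shape[0]
                dlogits = probs.copy()
                dlogits[np.arange(b), yb] -= 1.0
                dlogits /= b
                g_wd = pooled.T @ dlogits
                g_bd = dlogits.sum(axis=0)
                dpooled = dlogits @ self.wd.T                      # (b, F)
                n_windows = h.shape[1]
                dh = (dpooled[:, None, :] / n_windows) * (h > 0)   # (b, L, F)
                g_wc = np.einsum("blk,blf->kf", cols, dh)
                g_bc = dh.sum(axis=(0, 1))
                grads = [g_wc, g_bc, g_wd, g_bd]
                t += 1
                for p, gr, mm, vv in zip(params, grads, m, v):
                    mm *= 0.9
                    mm += 0.1 * gr
                    vv *= 0.999
                    vv += 0.001 * gr * gr
                    p -= self.lr * (mm / (1 - 0.9 ** t)) / (np.sqrt(vv / (1 - 0.999 ** t)) + 1e-8)
        return self

    def _forward(self, x: np.ndarray):
        b = x.shape[0]
        imgs = x.reshape(b, self.n_nodes, self.dim)
        win = np.lib.stride_tricks.sliding_window_view(imgs, self.kernel, axis=1)
        # win: (b, L, d, kernel) -> (b, L, kernel * d) matching wc layout
        cols = win.transpose(0, 1, 3, 2).reshape(b, -1, self.kernel * self.dim)
        pre = cols @ self.wc + self.bc
        h = np.maximum(pre, 0.0)
        pooled = h.mean(axis=1)
        logits = pooled @ self.wd + self.bd
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return cols, h, pooled, probs

    def predict(self, x: np.ndarray) -> np.ndarray:
        *_, probs = self._forward(x)
        return self.classes_[np.argmax(probs, axis=1)]


def _make_estimator(spec: ClassifierSpec, n_nodes: int, dimension: int):
    hp = dict(spec.hyperparameters)
    if spec.model == "logistic_regression":
        from sklearn.linear_model import LogisticRegression
        return LogisticRegression(max_iter=hp.pop("max_iter", 2000), **hp)
    if spec.model == "random_forest":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100), random_state=spec.seed, **hp)
    if spec.model == "gradient_boosting_xgb_style":
        from sklearn.ensemble import GradientBoostingClassifier
        return GradientBoostingClassifier(random_state=spec.seed, **hp)
    if spec.model == "gradient_boosting_lgbm_style":
        from sklearn.ensemble import HistGradientBoostingClassifier
        return HistGradientBoostingClassifier(random_state=spec.seed, **hp)
    if spec.model == "neural_network":
        from sklearn.neural_network import MLPClassifier
        return MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (128,)),
            max_iter=hp.pop("max_iter", 300), random_state=spec.seed, **hp)
    if spec.model == "cnn_1d":
        return _CNN1D(n_nodes=n_nodes, dim=dimension, seed=spec.seed, **hp)
    if spec.model == "support_vector":
        from sklearn.svm import SVC
        return SVC(random_state=spec.seed, **hp)
    raise ArgumentError(f"unknown model {spec.model!r}")


@dataclass
class FittedModel:
    """A trained classifier plus the (optional) train-set standardizer."""

    estimator: object
    scaler: object | None
    spec: ClassifierSpec
    classes: list[str]

    def predict(self, features: np.ndarray | FeatureTable) -> np.ndarray:
        x = features.features() if isinstance(features, FeatureTable) else np.asarray(features)
        if self.scaler is not None:
            x = self.scaler.transform(x)
        return np.asarray(self.estimator.predict(x)).astype(str)


def train(train_table: FeatureTable, spec: ClassifierSpec) -> FittedModel:
    """Fit one classifier; features standardized for the scale-sensitive models."""
    from sklearn.preprocessing import StandardScaler

    if not train_table.is_labeled:
        raise IntegrityError("training requires a labeled table")
    y = train_table.labels().astype(str)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise TrainingError(f"training requires >= 2 classes, got {classes}")
    x = train_table.features()
    scaler = None
    if spec.model in _SCALED_MODELS:
        scaler = StandardScaler().fit(x)
        x = scaler.transform(x)
    est = _make_estimator(spec, train_table.n_nodes, train_table.dimension)
    est.fit(x, y)
    return FittedModel(estimator=est, scaler=scaler, spec=spec, classes=classes)


def evaluate(model: FittedModel, test_table: FeatureTable,
             split_seed: int | None = None) -> EvaluationReport:
    """Confusion-matrix report on a labeled test table."""
    from sklearn.metrics import confusion_matrix

    if not test_table.is_labeled:
        raise IntegrityError("evaluation requires a labeled table")
    y_true = test_table.labels().astype(str)
    y_pred = model.predict(test_table)
    class_names = sorted(set(model.classes) | set(y_true))
    cm = confusion_matrix(y_true, y_pred, labels=class_names)
    return report_from_confusion(cm, class_names, model=model.spec.model,
                                 split_seed=split_seed)


def report_from_confusion(cm: np.ndarray, class_names: list[str], model: str = "",
                          split_seed: int | None = None) -> EvaluationReport:
    cm = np.asarray(cm, dtype=np.int64)
    recall: dict[str, float | None] = {}
    precision: dict[str, float | None] = {}
    f1: dict[str, float | None] = {}
    support: dict[str, int] = {}
    for k, name in enumerate(class_names):
        row = cm[k].sum()
        col = cm[:, k].sum()
        support[name] = int(row)
        recall[name] = float(cm[k, k] / row) if row > 0 else None
        precision[name] = float(cm[k, k] / col) if col > 0 else None
        if recall[name] and precision[name]:
            f1[name] = 2 * recall[name] * precision[name] / (recall[name] + precision[name])
        elif recall[name] == 0.0 or precision[name] == 0.0:
            f1[name] = 0.0
        else:
            f1[name] = None
    accuracy = float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0
    return EvaluationReport(
        class_names=list(class_names), confusion=cm, recall=recall,
        precision=precision, f1=f1, support=support, accuracy=accuracy,
        model=model, split_seed=split_seed,
    )


# ---------------------------------------------------------------------------
# benchmarking


def benchmark(
    labeled_tables: dict[str, FeatureTable],
    classifier_specs: list[ClassifierSpec],
    split_spec: SplitSpec | None = None,
) -> pd.DataFrame:
    """Full factorial sweep over (table, model); one report row per cell.

    The output mirrors a per-class comparison table: one row per
    (dataset, model) with per-class recall columns and overall accuracy.
    Failures are recorded in an ``error`` column and the sweep continues.
    """
    if not labeled_tables or not classifier_specs:
        raise ArgumentError("benchmark needs at least one table and one classifier spec")
    split_spec = split_spec or SplitSpec()
    rows = []
    for table_name, table in labeled_tables.items():
        try:
            tr, te = split(table, split_spec)
        except Exception as exc:
            for spec in classifier_specs:
                rows.append({"dataset": table_name, "model": spec.model,
                             "accuracy": None, "error": str(exc)})
            continue
        for spec in classifier_specs:
            row = {"dataset": table_name, "model": spec.model, "error": ""}
            try:
                report = evaluate(train(tr, spec), te, split_seed=split_spec.seed)
                for cls in report.class_names:
                    row[f"recall_{cls}"] = report.recall[cls]
                row["accuracy"] = report.accuracy
            except Exception as exc:
                row["accuracy"] = None
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
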