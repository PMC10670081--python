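"""Training protocol, classification metrics, repeated-run averaging, and
the three classical baselines (SVM with Gaussian kernel, ReLU MLP, random
forest).

Metric conventions: the confusion matrix is indexed ``[predicted, true]``.
Accuracy is trace/total; precision and sensitivity are computed one-vs-rest
per class and macro-averaged for multiclass problems (micro averaging
available by flag); all three are reported as percentages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import engine
from .engine import Adam, cross_entropy
from .network import ArchitectureSpec, Model
from .preprocess import SpectraDataset

log = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "ConfusionMatrix",
    "EvalReport",
    "split_dataset",
    "train_model",
    "evaluate_model",
    "compute_metrics",
    "per_class_metrics",
    "repeated_runs",
    "fit_baselines",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    dropout_rate: float = 0.3
    batch_size: int = 16
    epochs: int = 200
    train_fraction: float = 0.9
    n_runs: int = 5                      # protocol default is 30; desk default 5
    seed: int = 0
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    stratify: bool = True
    precision: str = "float32"           # training dtype; float64 for exactness

    _PRECISIONS = ("float32", "float64")

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam" or self.loss != "cross_entropy":
            raise ValueError("only adam + cross_entropy are supported")
        if self.precision not in self._PRECISIONS:
            raise ValueError(f"precision must be one of {self._PRECISIONS}")


@dataclass
class ConfusionMatrix:
    """C x C count matrix; rows are predicted labels, columns true labels."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("confusion matrix entries must be nonnegative integers")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if not self.class_names:
            self.class_names = [f"class{i}" for i in range(self.counts.shape[0])]

    @classmethod
    def from_predictions(cls, y_pred, y_true, n_classes: int | None = None,
                         class_names: list[str] | None = None) -> "ConfusionMatrix":
        y_pred = np.asarray(y_pred, dtype=int)
        y_true = np.asarray(y_true, dtype=int)
        if y_pred.shape != y_true.shape:
            raise ValueError("prediction/label length mismatch")
        c = n_classes or int(max(y_pred.max(), y_true.max())) + 1
        counts = np.zeros((c, c), dtype=np.int64)
        np.add.at(counts, (y_pred, y_true), 1)
        return cls(counts, class_names or [])

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts, list(self.class_names))


def per_class_metrics(cm: ConfusionMatrix) -> list[dict]:
    """One-vs-rest TP/FP/FN/TN and precision/sensitivity (in %) per class."""
    m = cm.counts
    total = cm.total
    out = []
    for c in range(cm.n_classes):
        tp = int(m[c, c])
        fp = int(m[c, :].sum() - tp)     # predicted c, truly something else
        fn = int(m[:, c].sum() - tp)     # truly c, predicted something else
        tn = total - tp - fp - fn
        if tp + fp == 0:
            log.warning("class %s: no predicted positives; precision set to 0",
                        cm.class_names[c])
            prec = 0.0
        else:
            prec = 100.0 * tp / (tp + fp)
        sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        out.append({"class": cm.class_names[c], "tp": tp, "fp": fp, "fn": fn, "tn": tn,
                    "precision": prec, "sensitivity": sens})
    return out


def compute_metrics(cm: ConfusionMatrix, average: str = "auto",
                    positive: int = 0) -> tuple[float, float, float]:
    """(accuracy, precision, sensitivity) in percent.

    ``average='binary'`` (the default resolution of 'auto' for 2 classes)
    scores the ``positive`` class directly from TP/FP/TN/FN; multiclass
    problems default to macro one-vs-rest averaging; ``'micro'`` pools counts.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if average == "auto":
        average = "binary" if cm.n_classes == 2 else "macro"
    acc = 100.0 * np.trace(cm.counts) / cm.total
    pc = per_class_metrics(cm)
    if average == "binary":
        if cm.n_classes != 2:
            raise ValueError("binary averaging requires a 2x2 matrix")
        return acc, pc[positive]["precision"], pc[positive]["sensitivity"]
    if average == "macro":
        return (acc, float(np.mean([d["precision"] for d in pc])),
                float(np.mean([d["sensitivity"] for d in pc])))
    if average == "micro":
        tp = sum(d["tp"] for d in pc)
        fp = sum(d["fp"] for d in pc)
        fn = sum(d["fn"] for d in pc)
        prec = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        return acc, prec, sens
    raise ValueError(f"unknown averaging {average!r}")


@dataclass
class EvalReport:
    """Mean +/- SD metrics over repeated runs, plus per-class breakdown."""

    model_name: str
    n_runs: int
    run_accuracy: np.ndarray
    run_precision: np.ndarray
    run_sensitivity: np.ndarray
    confusion: ConfusionMatrix
    per_class: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> tuple[float, float]:
        return float(np.mean(self.run_accuracy)), float(np.std(self.run_accuracy))

    @property
    def precision(self) -> tuple[float, float]:
        return float(np.mean(self.run_precision)), float(np.std(self.run_precision))

    @property
    def sensitivity(self) -> tuple[float, float]:
        return float(np.mean(self.run_sensitivity)), float(np.std(self.run_sensitivity))

    @staticmethod
    def _fmt(pair: tuple[float, float]) -> str:
        return f"{pair[0]:.2f} ± {pair[1]:.2f}"

    def summary(self) -> dict:
        return {
            "model": self.model_name,
            "n_runs": self.n_runs,
            "accuracy": self._fmt(self.accuracy),
            "precision": self._fmt(self.precision),
            "sensitivity": self._fmt(self.sensitivity),
        }


# ---------------------------------------------------------------------------
# protocol operations
# ---------------------------------------------------------------------------

def split_dataset(ds: SpectraDataset, train_fraction: float = 0.9, seed: int = 0,
                  stratify: bool = True) -> tuple[SpectraDataset, SpectraDataset]:
    """Random disjoint, exhaustive train/test split, reproducible from seed.

    Stratified per class by default (train gets floor(fraction * n_c) + the
    fair share of remainders); with stratification off, a plain shuffle.
    """
    n = len(ds)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    if stratify:
        train_idx, test_idx = [], []
        for c in range(ds.n_classes):
            idx = np.flatnonzero(ds.y == c)
            rng.shuffle(idx)
            k = int(round(train_fraction * idx.size))
            k = min(max(k, 0), idx.size)
            train_idx.append(idx[:k])
            test_idx.append(idx[k:])
        train_idx = np.concatenate(train_idx)
        test_idx = np.concatenate(test_idx)
    else:
        perm = rng.permutation(n)
        k = int(round(train_fraction * n))
        train_idx, test_idx = perm[:k], perm[k:]
        missing = set(range(ds.n_classes)) - set(ds.y[train_idx].tolist())
        if missing:
            log.warning("classes %s absent from the training split", sorted(missing))
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(test_idx))


def train_model(spec: ArchitectureSpec, train_ds: SpectraDataset,
                cfg: TrainConfig) -> tuple[dict, dict]:
    """Minimize mean cross-entropy with Adam; returns (params, history).

    History records per-epoch mean loss and training accuracy.  Fully
    deterministic given the seed (single-threaded numpy backend).
    """
    if len(train_ds) == 0:
        raise ValueError("empty training set")
    if train_ds.X.shape[1] != spec.input_bands:
        raise ValueError(f"spectra have {train_ds.X.shape[1]} bands, architecture "
                         f"expects {spec.input_bands}")
    spec = replace(spec, dropout_rate=cfg.dropout_rate)
    with engine.use_dtype(np.dtype(cfg.precision)):
        model = Model(spec, seed=cfg.seed)
        opt = Adam(model.trainable(), lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed)
        X = train_ds.X.astype(np.dtype(cfg.precision))
        y = train_ds.y
        n = X.shape[0]
        history: dict[str, list[float]] = {"loss": [], "train_accuracy": []}
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            loss_sum = 0.0
            correct = 0
            for s in range(0, n, cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                logits = model.forward(X[idx], training=True, rng=rng)
                loss = cross_entropy(logits, y[idx])
                val = float(loss.data)
                if not np.isfinite(val):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}, "
                        f"batch {s // cfg.batch_size} (lr={cfg.learning_rate}, "
                        f"batch_size={cfg.batch_size})")
                opt.zero_grad()
                loss.backward()
                opt.step()
                loss_sum += val * idx.size
                correct += int((np.argmax(logits.data, axis=1) == y[idx]).sum())
            history["loss"].append(loss_sum / n)
            history["train_accuracy"].append(100.0 * correct / n)
    return model.export_params(), history


def evaluate_model(spec: ArchitectureSpec, params: dict,
                   ds: SpectraDataset) -> ConfusionMatrix:
    """Predict a dataset and tally the confusion matrix (rows = predicted)."""
    model = Model(spec, params=params)
    preds = model.predict(ds.X)
    return ConfusionMatrix.from_predictions(preds, ds.y, ds.n_classes,
                                            list(ds.class_names))


def repeated_runs(spec: ArchitectureSpec, ds: SpectraDataset, cfg: TrainConfig,
                  model_name: str = "1DCNN",
                  skip_failed: bool = False) -> EvalReport:
    """Re-split / re-initialize / re-train ``cfg.n_runs`` times; average.

    Run r uses seed ``cfg.seed + r`` for both the split and the training.
    A failed run aborts the report unless ``skip_failed`` is set.
    """
    if cfg.n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    accs, precs, senss = [], [], []
    confusion: ConfusionMatrix | None = None
    for r in range(cfg.n_runs):
        run_seed = cfg.seed + r
        try:
            train, test = split_dataset(ds, cfg.train_fraction, run_seed, cfg.stratify)
            run_cfg = replace(cfg, seed=run_seed)
            params, _ = train_model(spec, train, run_cfg)
            cm = evaluate_model(spec, params, test)
        except Exception:
            if skip_failed:
                log.exception("run %d failed; excluded from the report", r)
                continue
            raise
        a, p, s = compute_metrics(cm)
        accs.append(a)
        precs.append(p)
        senss.append(s)
        confusion = cm if confusion is None else confusion + cm
    if confusion is None:
        raise RuntimeError("all runs failed")
    return EvalReport(model_name, len(accs), np.array(accs), np.array(precs),
                      np.array(senss), confusion, per_class_metrics(confusion),
                      config={"seed": cfg.seed, "epochs": cfg.epochs,
                              "learning_rate": cfg.learning_rate,
                              "batch_size": cfg.batch_size,
                              "train_fraction": cfg.train_fraction})


# ---------------------------------------------------------------------------
# classical baselines
# ---------------------------------------------------------------------------

BASELINES = ("svm", "mlp", "rf")


def _make_baseline(which: str, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    if which == "svm":
        # Gaussian (RBF) kernel; C and gamma left at the library heuristics
        return SVC(kernel="rbf", random_state=seed)
    if which == "mlp":
        return MLPClassifier(activation="relu", max_iter=200,
                             learning_rate_init=1e-4, random_state=seed)
    if which == "rf":
        return RandomForestClassifier(n_estimators=200, max_depth=40,
                                      random_state=seed)
    raise ValueError(f"unknown baseline {which!r}; choose from {BASELINES}")


def fit_baselines(train: SpectraDataset, test: SpectraDataset, which: str,
                  seed: int = 0) -> EvalReport:
    """Fit one classical baseline and score it with the shared metric pipeline."""
    from sklearn.exceptions import ConvergenceWarning

    clf = _make_baseline(which, seed)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(train.X, train.y)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            log.warning("%s did not converge within its iteration budget "
                        "(results emitted anyway)", which)
    if which == "rf":
        depths = [est.get_depth() for est in clf.estimators_]
        assert max(depths) <= 40, "random forest exceeded its depth cap"
    preds = clf.predict(test.X)
    cm = ConfusionMatrix.from_predictions(preds, test.y, test.n_classes,
                                          list(test.class_names))
    a, p, s = compute_metrics(cm)
    hp = {k: v for k, v in clf.get_params().items()
          if k in ("C", "gamma", "kernel", "hidden_layer_sizes", "max_iter",
                   "learning_rate_init", "n_estimators", "max_depth")}
    return EvalReport(which.upper(), 1, np.array([a]), np.array([p]), np.array([s]),
                      cm, per_class_metrics(cm), config={"seed": seed, **hp})
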