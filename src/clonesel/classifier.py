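"""Ensemble of multi-task networks over the 16-statistic features.

Ten (configurable) identically structured networks are trained
independently, each on its own class-balanced bootstrap of the training
split.  At prediction time every member emits a softmax distribution
over the four evolutionary classes and four parameter estimates; the
ensemble reports the mean and standard error of each across members,
and the predicted class is the argmax of the mean softmax.

Features are preprocessed with log1p on the count-valued statistics
followed by z-scoring with train-split statistics; the constants are
stored inside the model artifact together with the feature-layout
version, hyperparameters, and per-member seeds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import h5py
import numpy as np
from scipy import stats

from .features import FEATURE_NAMES, LAYOUT_VERSION, FeatureVector
from .nn import MultiTaskMLP
from .params import CLASS_LABELS

#: Names of the four regressed evolutionary parameters.
PARAM_NAMES = ("log10_mu", "p_beneficial", "s_pos_mean", "s_neg_mean")

#: Indices of count-valued features, log1p-transformed before z-scoring.
COUNT_FEATURE_IDX = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 15])


@dataclass(frozen=True)
class Hyperparams:
    """Training hyperparameters of the ensemble."""

    hidden_layers: int = 3
    hidden_units: int = 512
    dropout: float = 0.1
    batch_size: int = 500
    epochs: int = 20
    learning_rate: float = 1e-3
    ensemble_size: int = 10
    subsample_size: int = 250_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        for name in ("hidden_layers", "hidden_units", "batch_size", "epochs",
                     "subsample_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def desk_scale(cls, **overrides) -> "Hyperparams":
        """Reduced ensemble: 3 members, 128-unit layers, 20k-row subsamples."""
        defaults = dict(hidden_units=128, ensemble_size=3, subsample_size=20_000)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class TrainingCorpus:
    """Feature matrix, class labels, regression targets, and the split."""

    X: np.ndarray                # (n, 16)
    y: np.ndarray                # (n,) class indices into CLASS_LABELS
    Y: np.ndarray                # (n, 4) regression targets
    split: np.ndarray            # (n,) "train" | "test"
    sim_ids: np.ndarray          # (n,) simulation identifiers

    @property
    def train_idx(self) -> np.ndarray:
        return np.flatnonzero(self.split == "train")

    @property
    def test_idx(self) -> np.ndarray:
        return np.flatnonzero(self.split == "test")


def build_training_corpus(
    X: np.ndarray,
    y,
    Y: np.ndarray,
    seed: int = 0,
    test_frac: float = 0.1,
    sim_ids: np.ndarray | None = None,
) -> TrainingCorpus:
    """Split featurized simulations 90/10 and remove test-set leakage.

    Rows are whole simulations, so the split is by simulation.  Any test
    row whose feature vector is bit-identical to a training row is
    dropped from the test set (information-leakage guard).  Class labels
    may be names or indices; every class must be represented.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        y = np.array([CLASS_LABELS.index(lbl) for lbl in y])
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("regression targets must be finite")
    n = X.shape[0]
    present = set(y.tolist())
    missing = [c for i, c in enumerate(CLASS_LABELS) if i not in present]
    if missing:
        raise ValueError(f"classes absent from corpus: {missing}")
    if sim_ids is None:
        sim_ids = np.arange(n)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(n * test_frac))
    test_set = set(order[:n_test].tolist())
    split = np.array(["test" if i in test_set else "train" for i in range(n)])

    train_keys = {X[i].tobytes() for i in range(n) if split[i] == "train"}
    dropped = [
        i for i in range(n)
        if split[i] == "test" and X[i].tobytes() in train_keys
    ]
    if dropped:
        keep = np.ones(n, bool)
        keep[dropped] = False
        X, y, Y, split, sim_ids = (
            X[keep], y[keep], Y[keep], split[keep], sim_ids[keep]
        )
    if not np.any(split == "test"):
        warnings.warn("test set is empty after deduplication", stacklevel=2)
    return TrainingCorpus(X=X, y=y, Y=Y, split=split, sim_ids=np.asarray(sim_ids))


def balance_subsample(
    corpus: TrainingCorpus, size: int, seed: int = 0
) -> np.ndarray:
    """Class-balanced bootstrap indices into the training split.

    Draws with replacement, size/n_classes rows per class, so every
    member training set has equal class representation (the grid's
    class imbalance is removed by construction, as if downsampled to
    the minority class before resampling).
    """
    if size < len(CLASS_LABELS):
        raise ValueError("size must allow at least one row per class")
    rng = np.random.default_rng(seed)
    tr = corpus.train_idx
    y_tr = corpus.y[tr]
    class_counts = [int(np.sum(y_tr == k)) for k in range(len(CLASS_LABELS))]
    if min(class_counts) == 0:
        empty = [CLASS_LABELS[k] for k, c in enumerate(class_counts) if c == 0]
        raise ValueError(f"empty class in training split: {empty}")
    per_class = size // len(CLASS_LABELS)
    picks = []
    for k in range(len(CLASS_LABELS)):
        pool = tr[y_tr == k]
        picks.append(rng.choice(pool, size=per_class, replace=True))
    return np.concatenate(picks)


def _transform(X: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    Z = np.asarray(X, dtype=float).copy()
    Z[:, COUNT_FEATURE_IDX] = np.log1p(Z[:, COUNT_FEATURE_IDX])
    return (Z - mean) / std


@dataclass
class EnsembleModel:
    """Trained ensemble plus everything needed to reproduce predictions."""

    members: list
    feature_mean: np.ndarray
    feature_std: np.ndarray
    target_mean: np.ndarray
    target_std: np.ndarray
    hyper: Hyperparams
    member_seeds: list
    layout_version: str = LAYOUT_VERSION
    class_labels: tuple = CLASS_LABELS

    def transform(self, X: np.ndarray) -> np.ndarray:
        return _transform(X, self.feature_mean, self.feature_std)


@dataclass(frozen=True)
class ClassPrediction:
    """Ensemble mean +/- SE softmax and parameter estimates for one sample."""

    probs_mean: np.ndarray
    probs_se: np.ndarray
    params_mean: np.ndarray
    params_se: np.ndarray
    predicted_class: str
    tie: bool = False

    def as_row(self) -> dict:
        row = {"predicted_class": self.predicted_class, "tie": self.tie}
        for k, lbl in enumerate(CLASS_LABELS):
            row[f"p_{lbl}"] = float(self.probs_mean[k])
            row[f"p_{lbl}_se"] = float(self.probs_se[k])
        for k, name in enumerate(PARAM_NAMES):
            row[f"{name}_hat"] = float(self.params_mean[k])
            row[f"{name}_se"] = float(self.params_se[k])
        return row


def train_ensemble(corpus: TrainingCorpus, hyper: Hyperparams) -> EnsembleModel:
    """Train ``ensemble_size`` members, each on its own balanced bootstrap."""
    tr = corpus.train_idx
    if len(tr) == 0:
        raise ValueError("empty training split")
    Z_raw = corpus.X[tr].copy()
    Z_raw[:, COUNT_FEATURE_IDX] = np.log1p(Z_raw[:, COUNT_FEATURE_IDX])
    mean = Z_raw.mean(axis=0)
    std = Z_raw.std(axis=0)
    std[std == 0] = 1.0
    # regression heads are trained on z-scored targets (raw scales differ
    # by orders of magnitude and would dominate the joint loss); the
    # constants are stored and predictions returned in original units
    t_mean = corpus.Y[tr].mean(axis=0)
    t_std = corpus.Y[tr].std(axis=0)
    t_std[t_std == 0] = 1.0
    Y_std = (corpus.Y - t_mean) / t_std

    members, seeds = [], []
    for m in range(hyper.ensemble_size):
        member_seed = hyper.seed * 10_000 + m
        idx = balance_subsample(corpus, hyper.subsample_size, seed=member_seed)
        X = _transform(corpus.X[idx], mean, std)
        net = MultiTaskMLP(
            n_in=corpus.X.shape[1],
            hidden=(hyper.hidden_units,) * hyper.hidden_layers,
            n_classes=len(CLASS_LABELS),
            n_reg=corpus.Y.shape[1],
            dropout=hyper.dropout,
            lr=hyper.learning_rate,
            seed=member_seed,
        )
        net.fit(
            X, corpus.y[idx], Y_std[idx],
            batch_size=hyper.batch_size, epochs=hyper.epochs,
            seed=member_seed + 777,
        )
        members.append(net)
        seeds.append(member_seed)
    return EnsembleModel(
        members=members, feature_mean=mean, feature_std=std,
        target_mean=t_mean, target_std=t_std,
        hyper=hyper, member_seeds=seeds,
    )


def _member_outputs(model: EnsembleModel, X: np.ndarray):
    Z = model.transform(X)
    probs = np.stack([net.predict(Z)[0] for net in model.members])
    regs = np.stack([net.predict(Z)[1] for net in model.members])
    regs = regs * model.target_std + model.target_mean  # back to raw units
    return probs, regs  # (M, n, 4) each


def _se(arr: np.ndarray, axis=0) -> np.ndarray:
    m = arr.shape[axis]
    if m < 2:
        return np.zeros(arr.mean(axis=axis).shape)
    return arr.std(axis=axis, ddof=1) / np.sqrt(m)


def predict_matrix(model: EnsembleModel, X: np.ndarray):
    """Ensemble mean/SE softmax and regressions for a feature matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(
            f"expected {len(FEATURE_NAMES)} features, got {X.shape[1]}"
        )
    probs, regs = _member_outputs(model, X)
    return probs.mean(axis=0), _se(probs), regs.mean(axis=0), _se(regs)


def predict_sample(model: EnsembleModel, fv) -> ClassPrediction:
    """Classify a single sample; ties on the mean softmax are flagged.

    ``fv`` is a FeatureVector (layout-checked against the model) or a
    bare length-16 array.
    """
    if isinstance(fv, FeatureVector):
        if fv.layout_version != model.layout_version:
            raise ValueError(
                f"feature layout {fv.layout_version} does not match model "
                f"layout {model.layout_version}"
            )
        x = fv.values
    else:
        x = np.asarray(fv, dtype=float)
    pm, ps, rm, rs = predict_matrix(model, x[None, :])
    pm, ps, rm, rs = pm[0], ps[0], rm[0], rs[0]
    best = int(np.argmax(pm))  # first max: fixed class-order tie-break
    tie = bool(np.sum(pm == pm[best]) > 1)
    return ClassPrediction(
        probs_mean=pm, probs_se=ps, params_mean=rm, params_se=rs,
        predicted_class=CLASS_LABELS[best], tie=tie,
    )


@dataclass
class ConfusionReport:
    """Held-out evaluation: confusion matrix plus parameter recovery."""

    confusion: np.ndarray          # (4, 4) true x predicted counts
    per_class_accuracy: dict
    overall_accuracy: float
    rmse: dict
    spearman: dict
    n_test: int

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "class_labels": list(CLASS_LABELS),
            "per_class_accuracy": self.per_class_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "rmse": self.rmse,
            "spearman": self.spearman,
            "n_test": self.n_test,
        }


def evaluate_classifier(
    model: EnsembleModel,
    X: np.ndarray,
    y,
    Y: np.ndarray | None = None,
) -> ConfusionReport:
    """Confusion matrix and parameter-recovery metrics on labeled data.

    Accepts either the held-out split of a corpus or a freshly simulated
    novel-parameter grid.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty test set")
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        y = np.array([CLASS_LABELS.index(lbl) for lbl in y])
    pm, _, rm, _ = predict_matrix(model, X)
    pred = pm.argmax(axis=1)

    K = len(CLASS_LABELS)
    conf = np.zeros((K, K), dtype=int)
    np.add.at(conf, (y, pred), 1)
    per_class = {}
    for k, lbl in enumerate(CLASS_LABELS):
        total = conf[k].sum()
        per_class[lbl] = float(conf[k, k] / total) if total else float("nan")
    overall = float(np.trace(conf) / conf.sum())

    rmse, rho = {}, {}
    if Y is not None:
        Y = np.asarray(Y, dtype=float)
        for k, name in enumerate(PARAM_NAMES):
            rmse[name] = float(np.sqrt(np.mean((rm[:, k] - Y[:, k]) ** 2)))
            if np.ptp(Y[:, k]) > 0:
                rho[name] = float(stats.spearmanr(Y[:, k], rm[:, k]).statistic)
            else:
                rho[name] = float("nan")
    return ConfusionReport(
        confusion=conf, per_class_accuracy=per_class,
        overall_accuracy=overall, rmse=rmse, spearman=rho, n_test=len(y),
    )


def evaluate_on_corpus(model: EnsembleModel, corpus: TrainingCorpus) -> ConfusionReport:
    te = corpus.test_idx
    return evaluate_classifier(model, corpus.X[te], corpus.y[te], corpus.Y[te])


# ---- persistence ------------------------------------------------------------

def save_model(model: EnsembleModel, path) -> None:
    """Write the ensemble to a single HDF5 artifact."""
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = model.layout_version
        f.attrs["class_labels"] = json.dumps(list(model.class_labels))
        f.attrs["hyper"] = json.dumps(asdict(model.hyper))
        f.attrs["member_seeds"] = json.dumps(list(model.member_seeds))
        f.create_dataset("feature_mean", data=model.feature_mean)
        f.create_dataset("feature_std", data=model.feature_std)
        f.create_dataset("target_mean", data=model.target_mean)
        f.create_dataset("target_std", data=model.target_std)
        for m, net in enumerate(model.members):
            grp = f.create_group(f"member_{m}")
            grp.attrs["config"] = json.dumps(
                dict(n_in=net.n_in, hidden=list(net.hidden),
                     n_classes=net.n_classes, n_reg=net.n_reg,
                     dropout=net.dropout, lr=net.lr, seed=net.seed)
            )
            for i, w in enumerate(net.get_weights()):
                grp.create_dataset(f"w{i}", data=w)


def load_model(path) -> EnsembleModel:
    with h5py.File(path, "r") as f:
        hyper = Hyperparams(**json.loads(f.attrs["hyper"]))
        members = []
        m = 0
        while f"member_{m}" in f:
            grp = f[f"member_{m}"]
            cfg = json.loads(grp.attrs["config"])
            cfg["hidden"] = tuple(cfg["hidden"])
            net = MultiTaskMLP(**cfg)
            weights = [grp[f"w{i}"][...] for i in range(len(net.get_weights()))]
            net.set_weights(weights)
            members.append(net)
            m += 1
        model = EnsembleModel(
            members=members,
            feature_mean=f["feature_mean"][...],
            feature_std=f["feature_std"][...],
            target_mean=f["target_mean"][...],
            target_std=f["target_std"][...],
            hyper=hyper,
            member_seeds=json.loads(f.attrs["member_seeds"]),
            layout_version=str(f.attrs["layout_version"]),
            class_labels=tuple(json.loads(f.attrs["class_labels"])),
        )
    return model
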