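"""Binary localization classifiers: chi-square feature selection, linear
SVM, bootstrap aggregation (bagging) with plurality voting, and 10-fold
cross-validation reporting.

Each binary classifier is an ensemble of 25 "bags".  A bag is trained on
1000 instances resampled with replacement (500 positive + 500 negative);
within each bag the k most class-discriminating features are selected by
a chi-square test of independence on equal-frequency-binned values, the
selected features are z-scored, and a linear maximum-margin classifier
(hinge loss, L2 penalty) is fitted.  The ensemble's call is a strict
plurality vote: positive iff at least 13 of 25 bags vote positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureVector

DEFAULT_N_BAGS = 25
DEFAULT_PER_CLASS_DRAW = 500
DEFAULT_K_FEATURES = 50
DEFAULT_N_BINS = 4
DEFAULT_COST = 1.0


@dataclass
class TrainingSet:
    """Labeled feature vectors for one binary classifier."""

    positives: np.ndarray  # (n_pos, n_features)
    negatives: np.ndarray
    class_name: str
    registry_hash: str

    def __post_init__(self) -> None:
        self.positives = np.atleast_2d(np.asarray(self.positives, dtype=np.float64))
        self.negatives = np.atleast_2d(np.asarray(self.negatives, dtype=np.float64))
        if len(self.positives) < 1 or len(self.negatives) < 1:
            raise ValueError("need at least one positive and one negative instance")
        if self.positives.shape[1] != self.negatives.shape[1]:
            raise ValueError("positive/negative feature dimensions differ")

    @classmethod
    def from_vectors(
        cls,
        positives: list[FeatureVector],
        negatives: list[FeatureVector],
        class_name: str,
    ) -> "TrainingSet":
        hashes = {v.registry_hash for v in positives + negatives}
        if len(hashes) != 1:
            raise ValueError("all vectors must share one registry hash")
        return cls(
            np.vstack([v.values for v in positives]),
            np.vstack([v.values for v in negatives]),
            class_name,
            hashes.pop(),
        )

    @property
    def X(self) -> np.ndarray:
        return np.vstack([self.positives, self.negatives])

    @property
    def y(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(len(self.positives), dtype=int), np.zeros(len(self.negatives), dtype=int)]
        )

    def subset(self, idx: np.ndarray) -> "TrainingSet":
        X, y = self.X[idx], self.y[idx]
        return TrainingSet(X[y == 1], X[y == 0], self.class_name, self.registry_hash)


@dataclass
class LinearModel:
    """One bag: selected features, z-scoring parameters, SVM weights."""

    selected_features: np.ndarray
    weights: np.ndarray
    bias: float
    mu: np.ndarray
    sd: np.ndarray
    trained_on: int
    registry_hash: str = ""

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        Z = (X[:, self.selected_features] - self.mu) / self.sd
        return Z @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.decision(X) > 0


@dataclass
class BagEnsemble:
    """A bagged binary classifier with plurality voting."""

    class_name: str
    bags: list[LinearModel]
    vote_threshold: int
    registry_hash: str = ""
    bag_seeds: list[int] = field(default_factory=list)

    def votes(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return np.sum([b.predict(X) for b in self.bags], axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.votes(X) >= self.vote_threshold


@dataclass
class CVReport:
    """Stratified cross-validation summary for one classifier."""

    class_name: str
    folds: int
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.tn, self.fn)


# ---------------------------------------------------------------------------
# chi-square feature selection


def chi2_scores(X: np.ndarray, y: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Chi-square statistic of each feature against the binary label.

    Each feature is discretized into ``n_bins`` equal-frequency bins over
    the pooled values; the statistic is computed on the bins x labels
    contingency table, dropping zero-expected cells from the sum.  A
    constant feature has a single occupied bin and statistic 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(bool)
    n, n_feat = X.shape
    scores = np.zeros(n_feat)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    n1 = int(y.sum())
    n0 = n - n1
    for j in range(n_feat):
        col = X[:, j]
        edges = np.unique(np.quantile(col, qs))
        # values equal to a bin edge fall in the lower bin
        bins = np.searchsorted(edges, col, side="left")
        n_used = int(bins.max()) + 1
        if n_used < 2:
            continue
        obs1 = np.bincount(bins[y], minlength=n_used).astype(float)
        obs0 = np.bincount(bins[~y], minlength=n_used).astype(float)
        tot = obs1 + obs0
        exp1 = tot * n1 / n
        exp0 = tot * n0 / n
        stat = 0.0
        for obs, exp in ((obs1, exp1), (obs0, exp0)):
            nz = exp > 0
            stat += (((obs[nz] - exp[nz]) ** 2) / exp[nz]).sum()
        scores[j] = stat
    return scores


def chi2_select(
    ts: TrainingSet, n_bins: int = DEFAULT_N_BINS, k: int = DEFAULT_K_FEATURES
) -> np.ndarray:
    """Indices of the ``k`` features with the largest chi-square statistic
    (ties broken toward the lower index)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = chi2_scores(ts.X, ts.y, n_bins)
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[: min(k, len(scores))])


# ---------------------------------------------------------------------------
# SVM fitting


def train_binary(
    ts: TrainingSet,
    selected: np.ndarray,
    cost: float = DEFAULT_COST,
) -> LinearModel:
    """Fit a linear maximum-margin classifier on z-scored selected features.

    The standardization parameters are stored in the model, so prediction
    is self-contained.  A training set containing a single class is
    rejected.
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("selected feature list must be nonempty")
    X, y = ts.X, ts.y
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    sub = X[:, selected]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (sub - mu) / sd
    # exact-margin linear SVM (libsvm SMO solves the dual QP to tolerance)
    svm = SVC(kernel="linear", C=cost, tol=1e-6)
    svm.fit(Z, y)
    return LinearModel(
        selected_features=selected,
        weights=svm.coef_.ravel().copy(),
        bias=float(svm.intercept_[0]),
        mu=mu,
        sd=sd,
        trained_on=len(y),
        registry_hash=ts.registry_hash,
    )


def train_bagged(
    ts: TrainingSet,
    n_bags: int = DEFAULT_N_BAGS,
    per_class_draw: int = DEFAULT_PER_CLASS_DRAW,
    seed: int = 0,
    *,
    k_features: int = DEFAULT_K_FEATURES,
    n_bins: int = DEFAULT_N_BINS,
    cost: float = DEFAULT_COST,
    select_per_bag: bool = True,
) -> BagEnsemble:
    """Train a bagged binary classifier.

    Each of the ``n_bags`` bags draws ``per_class_draw`` positives and as
    many negatives with replacement (defaults give 1000 instances per
    bag), selects features, and fits its own SVM.  The vote threshold is
    a strict majority (13 of 25 by default; for an even bag count ties
    are negative).  All randomness derives from ``seed`` via per-bag
    counter seeds recorded on the ensemble.
    """
    if n_bags < 1:
        raise ValueError("n_bags must be >= 1")
    ss = np.random.SeedSequence(seed)
    bag_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_bags)]
    global_sel = None
    if not select_per_bag:
        global_sel = chi2_select(ts, n_bins, k_features)
    n_pos, n_neg = len(ts.positives), len(ts.negatives)
    bags: list[LinearModel] = []
    for bseed in bag_seeds:
        rng = np.random.default_rng(bseed)
        pi = rng.integers(0, n_pos, size=per_class_draw)
        ni = rng.integers(0, n_neg, size=per_class_draw)
        bag = TrainingSet(
            ts.positives[pi], ts.negatives[ni], ts.class_name, ts.registry_hash
        )
        sel = global_sel if global_sel is not None else chi2_select(bag, n_bins, k_features)
        bags.append(train_binary(bag, sel, cost))
    return BagEnsemble(
        class_name=ts.class_name,
        bags=bags,
        vote_threshold=n_bags // 2 + 1,
        registry_hash=ts.registry_hash,
        bag_seeds=bag_seeds,
    )


def predict_bagged(model: BagEnsemble, fv: FeatureVector) -> bool:
    """Plurality-vote call for one cell (positive iff votes >= threshold)."""
    if fv.registry_hash and model.registry_hash and fv.registry_hash != model.registry_hash:
        raise ValueError(
            f"feature vector registry {fv.registry_hash} does not match "
            f"model registry {model.registry_hash}"
        )
    return bool(model.predict(fv.values[None, :])[0])


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate(
    ts: TrainingSet,
    folds: int = 10,
    seed: int = 0,
    **train_kwargs,
) -> CVReport:
    """Stratified k-fold cross-validation of the full pipeline.

    Selection and bagging are retrained from scratch inside every fold;
    recall = TP/(TP+FN) and precision = TP/(TP+FP) over the pooled
    held-out predictions.  Undefined ratios are reported as ``None``.
    """
    n_pos, n_neg = len(ts.positives), len(ts.negatives)
    if min(n_pos, n_neg) < folds:
        raise ValueError(
            f"each class needs >= {folds} members for {folds}-fold CV "
            f"(got {n_pos} positive, {n_neg} negative)"
        )
    X, y = ts.X, ts.y
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    for i, (tr, te) in enumerate(skf.split(X, y)):
        sub = ts.subset(tr)
        model = train_bagged(sub, seed=seed + 1000 * (i + 1), **train_kwargs)
        pred = model.predict(X[te])
        truth = y[te].astype(bool)
        tp += int(np.sum(pred & truth))
        fp += int(np.sum(pred & ~truth))
        tn += int(np.sum(~pred & ~truth))
        fn += int(np.sum(~pred & truth))
    return CVReport(ts.class_name, folds, tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# model files


def save_ensemble(model: BagEnsemble, path: str | Path) -> None:
    """Versioned JSON model file (registry hash, seeds, all bag weights)."""
    doc = {
        "format": "ensloc-model-v1",
        "class_name": model.class_name,
        "vote_threshold": model.vote_threshold,
        "registry_hash": model.registry_hash,
        "bag_seeds": model.bag_seeds,
        "bags": [
            {
                "selected_features": b.selected_features.tolist(),
                "weights": b.weights.tolist(),
                "bias": b.bias,
                "mu": b.mu.tolist(),
                "sd": b.sd.tolist(),
                "trained_on": b.trained_on,
            }
            for b in model.bags
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_ensemble(path: str | Path) -> BagEnsemble:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "ensloc-model-v1":
        raise ValueError(f"unrecognized model file format in {path}")
    bags = [
        LinearModel(
            selected_features=np.array(b["selected_features"], dtype=int),
            weights=np.array(b["weights"]),
            bias=b["bias"],
            mu=np.array(b["mu"]),
            sd=np.array(b["sd"]),
            trained_on=b["trained_on"],
            registry_hash=doc["registry_hash"],
        )
        for b in doc["bags"]
    ]
    return BagEnsemble(
        class_name=doc["class_name"],
        bags=bags,
        vote_threshold=doc["vote_threshold"],
        registry_hash=doc["registry_hash"],
        bag_seeds=doc["bag_seeds"],
    )


def write_cv_table(path: str | Path, reports: list[CVReport]) -> None:
    """TSV mirroring the validation-table columns of the classifier list."""
    with open(path, "w") as fh:
        fh.write("classifier\tfolds\trecall\tprecision\ttp\tfp\ttn\tfn\n")
        for r in reports:
            rec = f"{r.recall:.4f}" if r.recall is not None else "NA"
            prec = f"{r.precision:.4f}" if r.precision is not None else "NA"
            fh.write(
                f"{r.class_name}\t{r.folds}\t{rec}\t{prec}\t{r.tp}\t{r.fp}\t{r.tn}\t{r.fn}\n"
            )
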