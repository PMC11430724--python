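"""SVD-subspace trial classification with balanced, time-aware CV.

The classifier models each class as an affine low-rank subspace: after
feature standardization, the class mean is subtracted and the top right
singular vectors of the centered class matrix span the subspace.  A
trial is scored by its residual distance to each class subspace and
assigned to the nearest one; the two-class decision score is the signed
residual difference, whose ranking yields the ROC AUC.

Cross-validation respects trial time: test folds are contiguous blocks
of consecutive trials, while training uses the non-adjacent remainder
(a guard gap drops the trials bordering each test block), so training
trials are temporally disconnected from the tested ones.  Random
under-sampling equalizes class counts before folding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .features import TrialFeatureMatrix

__all__ = [
    "CVConfig",
    "SVDSubspaceClassifier",
    "DecodingResult",
    "undersample",
    "time_aware_folds",
    "evaluate",
    "relative_decoding_accuracy",
]


@dataclass(frozen=True)
class CVConfig:
    k: int = 5
    undersample: bool = True
    guard_gap: int = 2
    rank: int | None = None  # None -> smallest rank explaining >= 90% variance
    variance_kept: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.rank is not None and self.rank < 1:
            raise ValueError("rank must be >= 1")


def undersample(
    features: TrialFeatureMatrix, label_col: str, seed: int = 0
) -> TrialFeatureMatrix:
    """Equalize class counts by seeded sampling without replacement.

    All classes are downsampled to the minimum class count; the surviving
    rows keep their original (time) order.
    """
    y = features.meta[label_col].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to undersample")
    if counts.min() == 0:
        raise ValueError("a class has zero trials")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(y), dtype=bool)
    for c in classes:
        idx = np.nonzero(y == c)[0]
        keep[rng.choice(idx, size=n_min, replace=False)] = True
    return features.subset(np.nonzero(keep)[0])


def time_aware_folds(
    features: TrialFeatureMatrix, cv: CVConfig, time_col: str = "t_stim_onset"
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Contiguous test blocks in trial-time order with guard-gap training.

    The trials (already ordered by time) are split into ``k`` consecutive
    blocks; each serves once as the test fold, and the training set is
    every trial neither in the block nor within ``guard_gap`` trials of
    its edges.
    """
    n = len(features)
    if cv.k > n:
        raise ValueError(f"k={cv.k} folds but only {n} trials")
    if time_col in features.meta.columns:
        order = np.argsort(features.meta[time_col].to_numpy(), kind="stable")
    else:
        order = np.arange(n)
    blocks = np.array_split(order, cv.k)
    folds = []
    for b, test in enumerate(blocks):
        start = sum(len(blk) for blk in blocks[:b])
        lo = start - cv.guard_gap
        hi = start + len(test) + cv.guard_gap
        train_pos = [p for p in range(n) if p < lo or p >= hi]
        folds.append((order[train_pos], test))
    return folds


@dataclass
class _ClassSubspace:
    mean: np.ndarray
    basis: np.ndarray  # (rank, n_features), orthonormal rows


@dataclass
class SVDSubspaceClassifier:
    """Class-conditional low-rank subspace model with residual decision rule."""

    cv: CVConfig = field(default_factory=CVConfig)
    classes_: list = field(default_factory=list)
    subspaces_: dict = field(default_factory=dict)
    mu_: np.ndarray | None = None
    sd_: np.ndarray | None = None
    n_features_: int = 0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVDSubspaceClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = sorted(set(y.tolist()))
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self.mu_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        Z = (X - self.mu_) / self.sd_
        self.n_features_ = Z.shape[1]
        self.subspaces_ = {}
        for c in self.classes_:
            Zc = Z[y == c]
            if len(Zc) < 2:
                raise ValueError(f"class {c!r} has fewer than 2 training trials")
            mean = Zc.mean(axis=0)
            U, s, Vt = np.linalg.svd(Zc - mean, full_matrices=False)
            if self.cv.rank is not None:
                r = min(self.cv.rank, Vt.shape[0])
            else:
                power = s**2
                total = power.sum()
                if total == 0:
                    r = 1
                else:
                    r = int(np.searchsorted(np.cumsum(power) / total, self.cv.variance_kept) + 1)
                    # cap the subspace at half the available dimensions: an
                    # (almost) full-rank basis absorbs the residual complement
                    # where out-of-class trials are actually distinguished
                    r = min(r, Vt.shape[0], max(1, Vt.shape[0] // 2))
            self.subspaces_[c] = _ClassSubspace(mean, Vt[:r])
        return self

    def residuals(self, X: np.ndarray) -> np.ndarray:
        """(n_trials, n_classes) residual distances to each class subspace."""
        if self.mu_ is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"feature schema mismatch: {X.shape[1]} columns, expected {self.n_features_}"
            )
        Z = (X - self.mu_) / self.sd_
        out = np.empty((len(Z), len(self.classes_)))
        for j, c in enumerate(self.classes_):
            sub = self.subspaces_[c]
            D = Z - sub.mean
            proj = D @ sub.basis.T @ sub.basis
            out[:, j] = np.linalg.norm(D - proj, axis=1)
        return out

    def score_trials(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Two-class scores and predicted labels.

        The score is ``residual(class0) - residual(class1)`` (higher means
        more class-1-like); prediction is the argmin-residual class with
        ties broken toward the lower-indexed class.
        """
        res = self.residuals(X)
        # argmin returns the first (lower-indexed) class on exact ties
        pred = np.asarray(self.classes_)[np.argmin(res, axis=1)]
        score = res[:, 0] - res[:, 1] if res.shape[1] >= 2 else -res[:, 0]
        return score, pred


@dataclass
class DecodingResult:
    """Cross-validated decoding outcome for one condition."""

    pooled_auc: float
    fold_auc: list[float]
    accuracy: float
    per_class_accuracy: dict
    scores: pd.DataFrame  # trial_index, score, true, pred, fold
    classes: list

    def summary(self) -> str:
        lines = [
            "SVD-subspace decoding",
            f"  classes:  {self.classes}",
            f"  pooled AUC: {self.pooled_auc:.3f}",
            f"  fold AUCs:  {', '.join(f'{a:.3f}' for a in self.fold_auc)}",
            f"  accuracy:   {self.accuracy:.3f}",
        ]
        for c, a in self.per_class_accuracy.items():
            lines.append(f"    {c}: {a:.3f}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "pooled_auc": self.pooled_auc,
            "fold_auc": self.fold_auc,
            "accuracy": self.accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "classes": [str(c) for c in self.classes],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def evaluate(
    features: TrialFeatureMatrix,
    cv: CVConfig = CVConfig(),
    label_col: str = "category",
) -> DecodingResult:
    """Balanced, time-aware cross-validated decoding of one condition.

    Under-samples to equal class counts (if enabled), builds contiguous
    time folds, fits the SVD classifier per fold, and reports per-fold and
    pooled AUC over concatenated held-out scores plus fraction-correct
    accuracy (overall and per class).
    """
    feats = undersample(features, label_col, cv.seed) if cv.undersample else features
    y_all = feats.meta[label_col].to_numpy()
    classes = sorted(set(y_all.tolist()))
    if len(classes) != 2:
        raise ValueError("evaluate expects a two-class problem")
    X = feats.X.to_numpy(dtype=float)
    folds = time_aware_folds(feats, cv)
    rows = []
    fold_auc: list[float] = []
    skipped_folds = 0
    for f, (tr, te) in enumerate(folds):
        counts = [int((y_all[tr] == c).sum()) for c in classes]
        if min(counts) < 2:
            # guard gaps can starve a fold's training set at small n
            skipped_folds += 1
            continue
        model = SVDSubspaceClassifier(cv).fit(X[tr], y_all[tr])
        score, pred = model.score_trials(X[te])
        y_te = y_all[te]
        if len(set(y_te.tolist())) == 2:
            fold_auc.append(float(roc_auc_score(y_te == classes[1], score)))
        else:
            fold_auc.append(float("nan"))
        for i, t in enumerate(te):
            rows.append(
                {
                    "trial_index": int(feats.meta["trial_index"].iloc[t]),
                    "score": float(score[i]),
                    "true": y_te[i],
                    "pred": pred[i],
                    "fold": f,
                }
            )
    if skipped_folds:
        import warnings

        warnings.warn(
            f"{skipped_folds} of {len(folds)} folds skipped: too few training "
            "trials per class"
        )
    sc = pd.DataFrame(rows)
    if not len(sc):
        raise ValueError("every fold was skipped; too few trials for this CV setup")
    pooled = float(roc_auc_score(sc["true"] == classes[1], sc["score"]))
    acc = float((sc["true"] == sc["pred"]).mean())
    per_class = {
        str(c): float((sc.loc[sc["true"] == c, "pred"] == c).mean()) for c in classes
    }
    return DecodingResult(pooled, fold_auc, acc, per_class, sc, classes)


def relative_decoding_accuracy(
    results_by_condition: Mapping[tuple[str, bool], DecodingResult],
) -> pd.DataFrame:
    """TMS-minus-sham decoding accuracy per (site, class).

    ``results_by_condition`` maps ``(site, tms_flag)`` to a decoding
    result; every TMS condition needs its site-matched sham partner.
    """
    rows = []
    for (site, tms), res in results_by_condition.items():
        if not tms:
            continue
        sham_key = (site, False)
        if sham_key not in results_by_condition:
            raise KeyError(f"missing sham partner for site {site!r}")
        sham = results_by_condition[sham_key]
        for c in res.classes:
            rows.append(
                {
                    "site": site,
                    "class": c,
                    "tms_accuracy": res.per_class_accuracy[str(c)],
                    "sham_accuracy": sham.per_class_accuracy[str(c)],
                    "relative_accuracy": res.per_class_accuracy[str(c)]
                    - sham.per_class_accuracy[str(c)],
                }
            )
    return pd.DataFrame(rows)
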