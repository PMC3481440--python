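"""Weighted K-nearest-neighbour validation of the training classification.

Held-out samples are first discretised into F-scores with the *training*
features, cutoffs and survival directions, then classified against the
labelled training profiles.  The distance between a test profile F_f and a
training profile F_h is

    d_fh = max(#(F_f != F_h), 1) / #(F_f != 0 or F_h != 0)

(the max() guards the inverse-distance weights against zero), and the
discriminant is the weighted vote of the K nearest training samples

    P_f = sum_h (1/d_fh) l_h / sum_h (1/d_fh),      l_h in {-1 poor, +1 good}

with a *good* call iff P_f > 0 (ties go to poor).  K defaults to 3.
Neighbour ties at equal distance are broken by training-sample identifier
order so classification is deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import Thresholds, FeatureTest
from .fscore import FScoreMatrix, SurvivalFeatureDiscretizer, _mismatch_union

POOR, GOOD = -1, 1


def knn_distances(F_test, F_train) -> np.ndarray:
    """Pairwise test-to-train distances with the max(mismatch, 1) numerator.

    Pairs with no informative feature in either profile get distance 1.
    """
    A = (F_test.scores if isinstance(F_test, FScoreMatrix) else F_test)
    B = (F_train.scores if isinstance(F_train, FScoreMatrix) else F_train)
    B = B[A.columns] if list(A.columns) != list(B.columns) else B
    mismatch, union = _mismatch_union(A.to_numpy(np.int8), B.to_numpy(np.int8))
    num = np.maximum(mismatch, 1).astype(float)
    bad = union == 0
    if bad.any():
        warnings.warn("mutually uninformative test/train pairs: distance 1")
    return np.where(bad, 1.0, num / np.where(bad, 1, union))


class WeightedJaccardKNN(BaseEstimator, ClassifierMixin):
    """Inverse-distance-weighted KNN over ternary F-score profiles.

    Parameters
    ----------
    n_neighbors : int
        K, the number of training profiles that vote (default 3).

    Attributes
    ----------
    train_scores_ : pandas.DataFrame of training F-scores.
    train_labels_ : pandas.Series in {-1, +1}.
    """

    def __init__(self, n_neighbors: int = 3):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        scores = X.scores if isinstance(X, FScoreMatrix) else pd.DataFrame(X)
        y = pd.Series(y, index=scores.index) if not isinstance(y, pd.Series) \
            else y.loc[scores.index]
        if not set(np.unique(y)).issubset({POOR, GOOD}):
            raise ValueError("labels must be -1 (poor) or +1 (good)")
        if not 1 <= self.n_neighbors <= len(scores):
            raise ValueError("n_neighbors must be in [1, n_training_samples]")
        self.train_scores_ = scores
        self.train_labels_ = y.astype(int)
        self.classes_ = np.array([POOR, GOOD])
        return self

    def decision_function(self, X) -> pd.Series:
        """Weighted vote P_f in [-1, +1] per test sample."""
        scores = X.scores if isinstance(X, FScoreMatrix) else pd.DataFrame(X)
        d = knn_distances(scores, self.train_scores_)
        # stable neighbour order: distance, then training identifier
        id_rank = np.argsort(np.argsort(self.train_scores_.index.astype(str)))
        labels = self.train_labels_.to_numpy(float)
        out = np.empty(len(scores))
        k = self.n_neighbors
        for i in range(len(scores)):
            order = np.lexsort((id_rank, d[i]))[:k]
            w = 1.0 / d[i, order]
            out[i] = float(np.sum(w * labels[order]) / np.sum(w))
        return pd.Series(out, index=scores.index, name="P_f")

    def predict(self, X) -> pd.Series:
        p = self.decision_function(X)
        return pd.Series(np.where(p > 0, GOOD, POOR), index=p.index,
                         name="label")


@dataclass
class KnnModel:
    """A trained classifier: discretisation rules + labelled training scores."""

    discretizer: SurvivalFeatureDiscretizer
    knn: WeightedJaccardKNN

    def discretize_test(self, X: pd.DataFrame) -> FScoreMatrix:
        """F-scores for held-out samples using training-derived criteria."""
        return self.discretizer.transform(X)

    def classify(self, X_or_fscores) -> pd.DataFrame:
        """Per-sample discriminant P_f and poor/good label."""
        f = X_or_fscores if isinstance(X_or_fscores, FScoreMatrix) \
            else self.discretize_test(X_or_fscores)
        p = self.knn.decision_function(f)
        lab = np.where(p.to_numpy() > 0, "good", "poor")
        return pd.DataFrame({"P_f": p, "label": lab}, index=p.index)

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        disc = self.discretizer
        thr = disc.thresholds_
        return {
            "modality": disc.modality,
            "k": self.knn.n_neighbors,
            "thresholds": vars(thr).copy(),
            "tests": [{"feature_id": t.feature_id, "contrast": t.contrast,
                       "p_value": t.p_value, "longer": t.longer}
                      for t in disc.tests_],
            "cutoffs": (None if disc.cutoffs_ is None
                        else disc.cutoffs_.to_dict(orient="index")),
            "train_scores": {c: self.knn.train_scores_[c].tolist()
                             for c in self.knn.train_scores_.columns},
            "train_ids": list(map(str, self.knn.train_scores_.index)),
            "train_labels": self.knn.train_labels_.tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "KnnModel":
        disc = SurvivalFeatureDiscretizer(modality=d["modality"])
        disc.thresholds_ = Thresholds(**d["thresholds"])
        disc.tests_ = [FeatureTest(feature_id=t["feature_id"],
                                   modality=d["modality"],
                                   contrast=t["contrast"],
                                   p_value=t["p_value"], longer=t["longer"],
                                   group1_ids=[], group2_ids=[])
                       for t in d["tests"]]
        disc.cutoffs_ = (None if d["cutoffs"] is None else
                         pd.DataFrame.from_dict(d["cutoffs"], orient="index"))
        train = pd.DataFrame(d["train_scores"], index=d["train_ids"],
                             dtype=np.int8)
        knn = WeightedJaccardKNN(n_neighbors=d["k"])
        knn.fit(train, pd.Series(d["train_labels"], index=d["train_ids"]))
        return cls(disc, knn)

    @classmethod
    def load(cls, path) -> "KnnModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
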