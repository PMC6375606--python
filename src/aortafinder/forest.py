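"""Random-forest classification of candidate ROIs into {NA, PDA, AA}.

Candidates are labelled against ground truth by mask overlap (Dice > 0.75
against the annotated circle makes a candidate a positive for that vessel;
everything else is NA, "not aorta").  The classifier is a bagged ensemble
of unpruned Gini-split decision trees with a fixed number of features
sampled per split; class priors are the empirical training frequencies.
Out-of-bag (OOB) observations — on average a fraction 1 − (1 − 1/n)ⁿ ≈
63.2% of rows land in each bootstrap bag, leaving ~36.8% out — provide an
internal validation set for the error estimate and for permutation feature
importance.

The trees themselves are scikit-learn's; the OOB machinery (error,
per-tree permutation importance) is computed here directly from the
recorded bootstrap bags so it follows the definitions used throughout this
package.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .cht import CandidateROI
from .core import NOT_VISIBLE, CircleROI, GroundTruth, ROILabel, circle_mask, dice_coefficient
from .features import FEATURE_NAMES

__all__ = [
    "RFModel",
    "label_candidates",
    "gini_impurity",
    "bootstrap_distinct_fraction",
    "train_forest",
    "oob_error",
    "permutation_importance",
    "predict_posteriors",
]

#: Dice threshold above which a candidate counts as the annotated vessel.
LABEL_DSC_THRESHOLD = 0.75


def label_candidates(
    candidates: Sequence[CandidateROI],
    gt: GroundTruth,
    shape: tuple[int, int],
    pixel_spacing_mm: tuple[float, float],
    threshold: float = LABEL_DSC_THRESHOLD,
) -> list[ROILabel]:
    """Label candidates by rasterized overlap with the ground-truth circles.

    A candidate whose disc scores Dice > ``threshold`` against the AA
    (resp. PDA) annotation is labelled AA (resp. PDA); all others are NA.
    Several near-identical candidates may legitimately share a positive
    label.  A NOT_VISIBLE vessel produces no positives.  If a candidate
    clears the threshold for both vessels (only possible for nearly
    coincident annotations) the higher Dice wins.
    """

    def gt_mask(circle):
        if circle is NOT_VISIBLE:
            return None
        return circle_mask(circle, *shape, pixel_spacing_mm)

    aa_mask = gt_mask(gt.aa)
    pda_mask = gt_mask(gt.pda)
    labels = []
    for cand in candidates:
        disc = circle_mask(cand.circle, *shape, pixel_spacing_mm)
        d_aa = dice_coefficient(disc, aa_mask) if aa_mask is not None else 0.0
        d_pda = dice_coefficient(disc, pda_mask) if pda_mask is not None else 0.0
        if d_aa > threshold and d_aa >= d_pda:
            labels.append(ROILabel.AA)
        elif d_pda > threshold:
            labels.append(ROILabel.PDA)
        else:
            labels.append(ROILabel.NA)
    return labels


def gini_impurity(fractions: Sequence[float]) -> float:
    """Gini index Σ f_c (1 − f_c) of a node's class fractions.

    0 for a pure node; 2/3 for three perfectly mixed classes.  The split
    gain is ΔI = I_parent − f_left·I_left − f_right·I_right.
    """
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0) or not np.isclose(f.sum(), 1.0, atol=1e-8):
        raise ValueError("fractions must be non-negative and sum to 1")
    return float(np.sum(f * (1.0 - f)))


def bootstrap_distinct_fraction(n: int, n_replicates: int, seed: int = 0) -> float:
    """Mean fraction of distinct rows in bootstrap samples of size n.

    Converges to 1 − (1 − 1/n)ⁿ → 1 − 1/e ≈ 0.632 — the share of the
    training set that ends up inside each tree's bag.
    """
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(n_replicates):
        draw = rng.integers(0, n, size=n)
        total += np.unique(draw).size / n
    return total / n_replicates


@dataclasses.dataclass
class RFModel:
    """Trained ensemble plus the bookkeeping needed for OOB statistics."""

    forest: RandomForestClassifier
    classes: np.ndarray  # ROILabel integer codes in sklearn's class order
    class_priors: np.ndarray  # empirical training frequencies over classes
    bags: list[np.ndarray]  # per-tree bootstrap row indices
    feature_names: tuple[str, ...]
    n_trees: int
    mtry: int
    seed: int
    oob_error_: float | None = None
    importances_: np.ndarray | None = None

    def training_report(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "mtry": self.mtry,
            "seed": self.seed,
            "priors": {
                ROILabel(int(c)).name: float(p)
                for c, p in zip(self.classes, self.class_priors)
            },
            "oob_error": self.oob_error_,
            "importances": None
            if self.importances_ is None
            else dict(zip(self.feature_names, map(float, self.importances_))),
        }


def train_forest(
    X: np.ndarray,
    y: Sequence[int],
    n_trees: int = 1000,
    mtry: int = 6,
    seed: int = 0,
) -> RFModel:
    """Train the bagged, unpruned, Gini-split forest.

    Each tree sees a bootstrap sample of size n drawn with replacement and
    considers ``mtry`` randomly sampled features at every split; growth
    stops only when no split can decrease the Gini impurity.  Deterministic
    for a given seed.  All three classes must be present.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 training samples")
    present = set(np.unique(y).tolist())
    if not {int(ROILabel.NA), int(ROILabel.PDA), int(ROILabel.AA)} <= present:
        raise ValueError("all three classes (NA, PDA, AA) must be present")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        criterion="gini",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    bags = [np.asarray(s) for s in forest.estimators_samples_]
    classes = forest.classes_
    priors = np.array([(y == c).mean() for c in classes])
    names = FEATURE_NAMES if X.shape[1] == len(FEATURE_NAMES) else tuple(
        f"f{i}" for i in range(X.shape[1])
    )
    model = RFModel(
        forest=forest,
        classes=classes,
        class_priors=priors,
        bags=bags,
        feature_names=names,
        n_trees=n_trees,
        mtry=mtry,
        seed=seed,
    )
    model.oob_error_ = oob_error(model, X, y)
    return model


def _oob_votes(model: RFModel, X: np.ndarray, permute=None, rng=None) -> np.ndarray:
    """Per-sample OOB vote counts (n × n_classes).

    ``permute`` optionally names a feature column to shuffle within each
    tree's OOB subset before prediction (the permutation-importance path).
    """
    n = X.shape[0]
    votes = np.zeros((n, len(model.classes)), dtype=int)
    for tree, bag in zip(model.forest.estimators_, model.bags):
        oob = np.setdiff1d(np.arange(n), bag, assume_unique=False)
        if oob.size == 0:
            continue
        X_oob = X[oob]
        if permute is not None:
            X_oob = X_oob.copy()
            X_oob[:, permute] = rng.permutation(X_oob[:, permute])
        # trees inside a fitted forest predict encoded class indices
        # (positions in forest.classes_), not the original labels
        pred_idx = tree.predict(X_oob).astype(int)
        np.add.at(votes, (oob, pred_idx), 1)
    return votes


def oob_error(model: RFModel, X: np.ndarray, y: Sequence[int]) -> float:
    """Misclassified fraction under out-of-bag majority vote.

    Samples that were never out of bag (possible for very small forests)
    are skipped and reported via a warning from numpy's mean over the
    reduced set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    votes = _oob_votes(model, X)
    covered = votes.sum(axis=1) > 0
    if not covered.any():
        raise ValueError("no sample has out-of-bag coverage; grow more trees")
    pred = model.classes[np.argmax(votes, axis=1)]
    return float((pred[covered] != y[covered]).mean())


def permutation_importance(
    model: RFModel, X: np.ndarray, y: Sequence[int], seed: int = 0
) -> np.ndarray:
    """OOB permutation importance per feature, in canonical feature order.

    For each feature, its values are shuffled across each tree's OOB
    observations and the importance is the resulting increase in OOB
    classification error.  Uninformative features score ≈ 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    base = oob_error(model, X, y)
    rng = np.random.default_rng(seed)
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        votes = _oob_votes(model, X, permute=j, rng=rng)
        covered = votes.sum(axis=1) > 0
        pred = model.classes[np.argmax(votes, axis=1)]
        out[j] = float((pred[covered] != y[covered]).mean()) - base
    model.importances_ = out
    return out


def predict_posteriors(model: RFModel, X: np.ndarray) -> np.ndarray:
    """Class posterior probabilities, averaged over the trees' leaves.

    Returns an n × 3 array in the order (NA, PDA, AA); rows sum to 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.forest.n_features_in_:
        raise ValueError(
            f"expected {model.forest.n_features_in_} features, got {X.shape}"
        )
    proba = model.forest.predict_proba(X)
    order = np.argsort(model.classes)  # NA=1, PDA=2, AA=3
    return proba[:, order]
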