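"""Per-frame random-forest classifiers for the 11-behavior social ethogram.

One independent binary forest is trained per behavior (a frame may carry
several behaviors at once, so this is multi-label, not multi-class).
Training follows the study recipe: entropy split criterion, a stratified
20% held-out test split, no under/over-sampling.  Each classifier is then
assigned the detection threshold maximising F1 on its held-out
precision-recall curve; at prediction time a behavior is present in a frame
iff its forest probability is strictly above the threshold.  Minimum bout
length is 0: a single positive frame (1/12 s) counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

#: The 11 scored behavioral categories, alphabetical.
BEHAVIORS: tuple[str, ...] = (
    "adjacent lying",
    "anogenital sniffing",
    "crawling",
    "fighting",
    "following",
    "grooming",
    "mounting",
    "nosing",
    "rearing",
    "self-grooming",
    "sniffing",
)

#: Held-out fraction of the labeled frames ("20% of the training data").
TEST_FRACTION = 0.2
DEFAULT_N_TREES = 100


@dataclass
class BehaviorClassifier:
    """One behavior's fitted forest with its threshold provenance."""

    behavior: str
    forest: RandomForestClassifier | None
    detection_threshold: float
    max_f1: float
    min_bout_frames: int = 0
    untrainable: bool = False
    pr_curve: pd.DataFrame | None = None


@dataclass
class ClassifierBundle:
    """The full set of per-behavior classifiers plus the feature manifest."""

    classifiers: dict[str, BehaviorClassifier]
    feature_names: list[str]
    seed: int

    def thresholds(self) -> dict[str, float]:
        return {
            b: c.detection_threshold for b, c in self.classifiers.items()
        }

    def override_thresholds(self, overrides: dict[str, float]) -> None:
        """Config-driven threshold adjustment (replaces manual video-based
        tweaking)."""
        for b, t in overrides.items():
            if b not in self.classifiers:
                raise KeyError(f"unknown behavior {b!r}")
            self.classifiers[b].detection_threshold = float(t)

    def save(self, path) -> None:
        """Serialise the bundle (forests, thresholds, manifest, seed)."""
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ClassifierBundle":
        import joblib

        bundle = joblib.load(path)
        if not isinstance(bundle, ClassifierBundle):
            raise TypeError(f"{path} does not hold a ClassifierBundle")
        return bundle

    def to_config_yaml(self, path) -> None:
        """Write the per-behavior thresholds / bout lengths as a YAML config
        (the role the tracker suite's INI file plays)."""
        cfg = {
            "seed": self.seed,
            "behaviors": {
                b: {
                    "detection_threshold": float(c.detection_threshold),
                    "max_f1": float(c.max_f1),
                    "min_bout_frames": int(c.min_bout_frames),
                    "untrainable": bool(c.untrainable),
                }
                for b, c in self.classifiers.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


def pr_curve(scores: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Precision-recall curve evaluated at every distinct score value.

    A frame is predicted positive when its score is strictly above the
    threshold.  F1 = 2PR/(P+R), defined as 0 where P + R = 0 (also when
    precision is undefined because nothing is predicted positive).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    classes = np.unique(truth)
    if classes.size < 2:
        raise ValueError("pr_curve needs both classes in the truth vector")
    # thresholds: 0 plus every distinct score, ascending
    thresholds = np.unique(np.concatenate(([0.0], np.unique(scores))))
    rows = []
    n_pos = int(truth.sum())
    for t in thresholds:
        pred = scores > t
        tp = int(np.sum(pred & (truth == 1)))
        fp = int(np.sum(pred & (truth == 0)))
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / n_pos
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
        rows.append((float(t), precision, recall, f1))
    return pd.DataFrame(rows, columns=["threshold", "precision", "recall", "f1"])


def select_threshold(curve: pd.DataFrame) -> tuple[float, float]:
    """(threshold, max F1) from a PR curve; F1 ties break toward the higher
    threshold (the stricter detector)."""
    if len(curve) == 0:
        raise ValueError("empty PR curve")
    best_f1 = curve["f1"].max()
    at_best = curve[curve["f1"] == best_f1]
    return float(at_best["threshold"].max()), float(best_f1)


def train_classifiers(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    behaviors: tuple[str, ...] | None = None,
) -> ClassifierBundle:
    """Train one binary forest per behavior and pick its max-F1 threshold.

    ``features`` is the 111-column frame table; ``labels`` has one 0/1
    column per behavior on the same frames.  The split is 80/20
    train/held-out, stratified per behavior so rare classes keep positives
    on both sides.  A behavior with a single class in the data is marked
    untrainable and skipped; the others proceed.
    """
    if behaviors is None:
        behaviors = tuple(labels.columns)
    if len(features) != len(labels):
        raise ValueError("features and labels must cover the same frames")
    X = features.to_numpy(float)
    classifiers: dict[str, BehaviorClassifier] = {}
    for i, b in enumerate(behaviors):
        y = labels[b].to_numpy(int)
        if np.unique(y).size < 2:
            logger.warning("behavior %r has a single class; marked untrainable", b)
            classifiers[b] = BehaviorClassifier(
                behavior=b,
                forest=None,
                detection_threshold=0.5,
                max_f1=float("nan"),
                untrainable=True,
            )
            continue
        X_tr, X_te, y_tr, y_te = train_test_split(
            X,
            y,
            test_size=TEST_FRACTION,
            stratify=y,
            random_state=seed + i,
        )
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            criterion="entropy",
            random_state=seed + i,
            n_jobs=1,
        )
        forest.fit(X_tr, y_tr)
        scores = forest.predict_proba(X_te)[:, list(forest.classes_).index(1)]
        curve = pr_curve(scores, y_te)
        threshold, max_f1 = select_threshold(curve)
        # F1 is piecewise-constant between distinct scores (strict >), so
        # every threshold up to the next evaluated score sits on the same
        # plateau; operate at the midpoint — the stricter, more transferable
        # point of the plateau
        higher = curve.loc[curve["threshold"] > threshold, "threshold"]
        operating = (threshold + float(higher.min())) / 2 if len(higher) else threshold
        classifiers[b] = BehaviorClassifier(
            behavior=b,
            forest=forest,
            detection_threshold=operating,
            max_f1=max_f1,
            pr_curve=curve,
        )
    return ClassifierBundle(
        classifiers=classifiers,
        feature_names=list(features.columns),
        seed=seed,
    )


def predict_frames(
    bundle: ClassifierBundle, features: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame 0/1 and probability matrices for every trained behavior.

    A behavior is present iff its forest probability is strictly above its
    detection threshold (a probability exactly at the threshold is absent).
    Feature columns must match the training manifest; a mismatch raises and
    names the offending columns.  Untrainable behaviors predict all zeros.
    """
    missing = [c for c in bundle.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature table is missing training columns: {missing}")
    X = features[bundle.feature_names].to_numpy(float)
    binary = {}
    proba = {}
    for b, clf in bundle.classifiers.items():
        if clf.untrainable or clf.forest is None:
            p = np.zeros(len(features))
        else:
            p = clf.forest.predict_proba(X)[:, list(clf.forest.classes_).index(1)]
        proba[f"Probability_{b}"] = p
        binary[b] = (p > clf.detection_threshold).astype(int)
    idx = features.index
    return pd.DataFrame(binary, index=idx), pd.DataFrame(proba, index=idx)


def machine_results(
    bundle: ClassifierBundle, features: pd.DataFrame
) -> pd.DataFrame:
    """Interleaved probability + 0/1 table, one row per frame (the
    "machine results" export layout)."""
    binary, proba = predict_frames(bundle, features)
    cols = {}
    for b in bundle.classifiers:
        cols[f"Probability_{b}"] = proba[f"Probability_{b}"]
        cols[b] = binary[b]
    out = pd.DataFrame(cols, index=features.index)
    out.index.name = "frame"
    return out
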