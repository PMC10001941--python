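"""Cascade deep forest for binary classification.

A deep forest stacks levels of tree ensembles the way a neural network
stacks layers.  Each level holds ``n`` random forests (sqrt(d) candidate
features per split) and ``n`` completely random forests (a single random
candidate feature and a random threshold per split, grown to purity).
Each forest emits a 2-dim class vector per sample — the average over its
trees of the leaf-node class proportions — and the 2n class vectors are
concatenated into a 4n-dim augmented feature.  Level 1 sees the original
k features; every deeper level sees [original k | previous level's 4n],
i.e. k + 4n inputs.  Depth is chosen automatically: each level's accuracy
is estimated from out-of-fold class vectors, and growth stops once a level
fails to improve the best score by more than a small tolerance for
``patience`` consecutive levels; the cascade is truncated at the best
level.  The final prediction averages the last level's 2n class vectors
and takes the argmax (ties resolve to class 0, the non-ACP class).

Training-set class vectors are produced out-of-fold via internal
stratified cross-fitting so that the augmented features do not leak the
training labels into deeper levels; this can be disabled for ablation.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.exceptions import NotFittedError
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

_SCHEMA_VERSION = 1


class NotFittedCascadeError(RuntimeError):
    """Raised when predicting or introspecting an unfitted cascade."""


@dataclass(frozen=True)
class CascadeConfig:
    """Hyperparameters of the cascade.

    n_forests : forests per type per level (2n forests, 4n augmented dims).
    n_trees : trees per forest.
    crossfit_folds : stratified folds used to generate out-of-fold class
        vectors for training levels; also the source of the per-level
        accuracy estimate.  Set ``crossfit=False`` to disable (ablation;
        level scores then fall back to training accuracy).
    tol : minimum absolute accuracy gain counted as an improvement.
    patience : consecutive non-improving levels tolerated before stopping.
    max_levels : hard cap on cascade depth.
    """

    n_forests: int = 2
    n_trees: int = 100
    crossfit_folds: int = 3
    crossfit: bool = True
    tol: float = 1e-4
    patience: int = 1
    max_levels: int = 20
    min_samples_leaf: int = 1
    seed: int = 0
    n_jobs: int = 1


@dataclass
class CascadeLevel:
    """One fitted level: 2n forests (n random + n completely random)."""

    forests: list  # fitted estimators, random forests first
    n: int

    @property
    def out_dim(self) -> int:
        return 4 * self.n

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Concatenated class vectors of all forests: (m, 4n)."""
        return np.hstack([class_vector(f, X) for f in self.forests])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Average of the 2n class vectors: (m, 2)."""
        return self.transform(X).reshape(X.shape[0], 2 * self.n, 2).mean(axis=1)


def class_vector(forest, X: np.ndarray) -> np.ndarray:
    """Class-distribution vectors of a fitted forest: (m, 2).

    Each tree contributes the class proportions of the leaf the sample
    falls into; the forest averages these distributions over its trees.
    """
    try:
        check_is_fitted(forest)
    except NotFittedError as exc:
        raise NotFittedCascadeError("forest is not fitted") from exc
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return forest.predict_proba(X)


def _make_forests(config: CascadeConfig, rng: np.random.Generator) -> list:
    forests = []
    for _ in range(config.n_forests):
        forests.append(
            RandomForestClassifier(
                n_estimators=config.n_trees,
                max_features="sqrt",
                min_samples_leaf=config.min_samples_leaf,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=config.n_jobs,
            )
        )
    for _ in range(config.n_forests):
        forests.append(
            ExtraTreesClassifier(
                n_estimators=config.n_trees,
                max_features=1,
                min_samples_leaf=config.min_samples_leaf,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=config.n_jobs,
            )
        )
    return forests


def fit_level(
    X: np.ndarray, y: np.ndarray, config: CascadeConfig, rng: np.random.Generator
) -> tuple[CascadeLevel, np.ndarray]:
    """Fit one cascade level and return it with the training augmentation.

    The returned (m, 4n) augmented matrix holds out-of-fold class vectors
    when cross-fitting is enabled: each sample's vectors come from forests
    that never saw it.  The level's forests themselves are refitted on the
    full data for use at prediction time.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"cascade needs exactly 2 classes, got {classes.tolist()}")
    if np.min(np.bincount(y)) < 2:
        raise ValueError("each class needs at least 2 samples")
    templates = _make_forests(config, rng)
    aug = np.empty((X.shape[0], 4 * config.n_forests))
    if config.crossfit:
        skf = StratifiedKFold(
            n_splits=config.crossfit_folds,
            shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        folds = list(skf.split(X, y))
        for fi, template in enumerate(templates):
            col = slice(2 * fi, 2 * fi + 2)
            for train_idx, test_idx in folds:
                est = clone(template)
                est.fit(X[train_idx], y[train_idx])
                aug[test_idx, col] = est.predict_proba(X[test_idx])
    fitted = []
    for fi, template in enumerate(templates):
        est = clone(template)
        est.fit(X, y)
        fitted.append(est)
        if not config.crossfit:
            aug[:, 2 * fi : 2 * fi + 2] = est.predict_proba(X)
    return CascadeLevel(forests=fitted, n=config.n_forests), aug


@dataclass
class CascadeForest:
    """A fitted cascade of forest levels with early-stopped depth."""

    config: CascadeConfig = field(default_factory=CascadeConfig)
    levels: list[CascadeLevel] = field(default_factory=list, repr=False)
    level_scores: list[float] = field(default_factory=list)
    best_level: int = -1
    n_features_: int = 0

    @property
    def is_fitted(self) -> bool:
        return bool(self.levels)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CascadeForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.config.seed)
        self.levels, self.level_scores = [], []
        self.n_features_ = X.shape[1]
        z = X
        best_score, bad_streak = -np.inf, 0
        all_levels: list[CascadeLevel] = []
        stopped_early = False
        for _ in range(self.config.max_levels):
            level, aug = fit_level(z, y, self.config, rng)
            probs = aug.reshape(X.shape[0], 2 * self.config.n_forests, 2).mean(axis=1)
            score = float(np.mean(np.argmax(probs, axis=1) == y))
            all_levels.append(level)
            self.level_scores.append(score)
            if score > best_score + self.config.tol:
                best_score = score
                bad_streak = 0
            else:
                bad_streak += 1
                if bad_streak >= self.config.patience:
                    stopped_early = True
                    break
            z = np.hstack([X, aug])
        if not stopped_early and len(all_levels) == self.config.max_levels:
            warnings.warn(
                f"cascade reached max_levels={self.config.max_levels} without "
                "converging; keeping the best level",
                stacklevel=2,
            )
        self.best_level = int(np.argmax(self.level_scores))
        self.levels = all_levels[: self.best_level + 1]
        return self

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise NotFittedCascadeError("cascade is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"input has {X.shape[1]} features, model expects {self.n_features_}"
            )
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Propagate through the retained levels; (m, 2) class probabilities."""
        X = self._check_input(X)
        z = X
        for level in self.levels[:-1]:
            z = np.hstack([X, level.transform(z)])
        return self.levels[-1].predict_proba(z)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted labels; an exact (0.5, 0.5) tie resolves to class 0."""
        return np.argmax(self.predict_proba(X), axis=1)

    def gini_importance(self, block_index: dict[str, slice] | None = None):
        """Mean-decrease-in-impurity importance of the original features.

        Importances are averaged over all forests of the first level only:
        deeper levels mix in augmented class-vector coordinates that do not
        correspond to named input features.  Normalised to sum to 1.

        Returns ``(per_feature,)`` or ``(per_feature, per_block)`` when a
        block index is given; block totals sum importances over each slice.
        """
        if not self.is_fitted:
            raise NotFittedCascadeError("cascade is not fitted")
        imps = np.mean(
            [f.feature_importances_ for f in self.levels[0].forests], axis=0
        )
        total = imps.sum()
        if total > 0:
            imps = imps / total
        if block_index is None:
            return imps
        per_block = {name: float(imps[sl].sum()) for name, sl in block_index.items()}
        return imps, per_block

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Serialise to a single file (versioned schema)."""
        joblib.dump(
            {
                "schema_version": _SCHEMA_VERSION,
                "config": dataclasses.asdict(self.config),
                "levels": self.levels,
                "level_scores": self.level_scores,
                "best_level": self.best_level,
                "n_features": self.n_features_,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "CascadeForest":
        blob = joblib.load(path)
        if blob.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema {blob.get('schema_version')!r}"
            )
        model = cls(config=CascadeConfig(**blob["config"]))
        model.levels = blob["levels"]
        model.level_scores = blob["level_scores"]
        model.best_level = blob["best_level"]
        model.n_features_ = blob["n_features"]
        return model


def fit_cascade(X: np.ndarray, y: np.ndarray, config: CascadeConfig | None = None) -> CascadeForest:
    """Convenience wrapper: fit a :class:`CascadeForest` and return it."""
    return CascadeForest(config=config or CascadeConfig()).fit(X, y)
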