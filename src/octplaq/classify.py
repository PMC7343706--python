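"""Random-forest training and pixel-wise tissue-map prediction."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io_oct import BACKGROUND, TissueLabelMap

__all__ = ["RFConfig", "RFModel", "train_rf", "predict_tissue_map"]

log = logging.getLogger(__name__)


@dataclass
class RFConfig:
    """Random-forest hyperparameters.

    n_tree : number of trees to grow.
    m_try : number of features sampled at each node split.
    seed : RNG seed, makes training deterministic.
    class_weighting : "balanced" reweights classes inversely to their pixel
        prevalence (calcified pixels are typically rare), "none" does not.
    """

    n_tree: int = 100
    m_try: int = 5
    seed: int = 0
    class_weighting: str = "balanced"

    def __post_init__(self) -> None:
        if self.n_tree < 1:
            raise ValueError("n_tree must be positive")
        if self.m_try < 1:
            raise ValueError("m_try must be >= 1")
        if self.class_weighting not in ("none", "balanced"):
            raise ValueError("class_weighting must be 'none' or 'balanced'")


@dataclass
class RFModel:
    """A trained ensemble plus its feature-name manifest."""

    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    config: RFConfig = field(default_factory=RFConfig)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "RFModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not hold an RFModel")
        return model


def _feature_matrix(stack: pd.DataFrame,
                    names: tuple[str, ...] | None = None) -> np.ndarray:
    cols = [c for c in stack.columns if c not in ("row", "col", "label")]
    if names is not None:
        missing = set(names) - set(cols)
        extra = set(cols) - set(names)
        if missing or extra:
            raise ValueError(
                "feature manifest mismatch: "
                f"missing {sorted(missing)}, extra {sorted(extra)}")
        cols = list(names)
    return stack[cols].to_numpy(dtype=np.float64), tuple(cols)


def train_rf(stack: pd.DataFrame, labels, cfg: RFConfig | None = None
             ) -> RFModel:
    """Fit a random forest on a feature stack.

    ``stack`` holds one row per pixel (``row``/``col`` columns, if present,
    are ignored); ``labels`` the matching tissue labels.  Training is
    deterministic given ``cfg.seed``; the out-of-bag accuracy estimate is
    written to the module log.
    """
    cfg = cfg or RFConfig()
    X, names = _feature_matrix(stack)
    y = np.asarray(labels)
    if X.shape[0] != y.size:
        raise ValueError("feature stack and labels have different lengths")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    if not np.isfinite(X).all():
        raise ValueError("feature stack contains absent (non-finite) values")
    if cfg.m_try > X.shape[1]:
        raise ValueError("m_try exceeds the number of features")
    rf = RandomForestClassifier(
        n_estimators=cfg.n_tree,
        max_features=cfg.m_try,
        class_weight=None if cfg.class_weighting == "none" else "balanced",
        oob_score=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    log.info("random forest trained: %d trees, m_try=%d, OOB accuracy %.3f",
             cfg.n_tree, cfg.m_try, rf.oob_score_)
    return RFModel(estimator=rf, feature_names=names, config=cfg)


def predict_tissue_map(model: RFModel, stack: pd.DataFrame,
                       shape: tuple[int, int]):
    """Predict a pixel-wise tissue map from a feature stack.

    Returns ``(TissueLabelMap, probabilities)`` on the ``shape`` raster:
    per-pixel argmax of the ensemble votes (ties resolved toward the lower
    class index, i.e. fibrous < calcified < lipid), background outside the
    stack's pixels, and one probability raster per class that sums to 1
    over classes on stack pixels.
    """
    if not {"row", "col"} <= set(stack.columns):
        raise ValueError("stack must carry row/col pixel coordinates")
    X, _ = _feature_matrix(stack, model.feature_names)
    proba = model.estimator.predict_proba(X)
    classes = model.estimator.classes_
    # argmax picks the first (lowest-index) class on ties
    pred = classes[np.argmax(proba, axis=1)]
    rows = stack["row"].to_numpy(dtype=int)
    cols = stack["col"].to_numpy(dtype=int)
    label_map = np.full(shape, BACKGROUND, dtype=np.uint8)
    label_map[rows, cols] = pred
    prob_rasters = {}
    for k, cls in enumerate(classes):
        ras = np.zeros(shape)
        ras[rows, cols] = proba[:, k]
        prob_rasters[int(cls)] = ras
    return TissueLabelMap(label_map), prob_rasters
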