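"""Evaluation statistics: per-class sensitivity/specificity/accuracy,
image-grouped k-fold cross-validation with feature-set ablations, and
annotation-agreement statistics (ICC, Bland-Altman, regression).

Two per-class "accuracy" flavours are reported, clearly labelled:

* ``accuracy`` — per-class recall (the fraction of that tissue's pixels
  recovered), which when computed per image and averaged over images is
  how the cross-validation tables summarize per-class performance;
* ``accuracy_ovr`` — the standard one-vs-rest binary accuracy
  (TP+TN)/(TP+TN+FP+FN).

Both operate pixel-wise on the annotated region (truth labels 1-3);
background pixels are excluded from scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .classify import RFConfig, train_rf
from .io_oct import CALCIFIED, FIBROUS, LABEL_NAMES, LIPID
from .texture import feature_subset

__all__ = [
    "EvalReport",
    "CVReport",
    "class_metrics",
    "cross_validate",
    "patient_holdout_split",
    "icc_agreement",
    "bland_altman",
    "regression_agreement",
]

TISSUE_CLASSES = (FIBROUS, CALCIFIED, LIPID)
#: The six feature-set ablations reported by the evaluation tables.
ABLATIONS = ("OP+RP", "FOS+RP", "GLCM+RP", "NGTDM+RP", "FD+RP", "ALL")


@dataclass
class EvalReport:
    """Per-class metrics of one prediction/truth raster pair.

    ``confusion`` is a 3x4 count matrix: rows = truth (fibrous, calcified,
    lipid), columns = predicted (background, fibrous, calcified, lipid); a
    background prediction on an annotated pixel counts as a miss.
    """

    confusion: np.ndarray
    per_class: pd.DataFrame  # index: class name; sensitivity/specificity/...
    overall_accuracy: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (self.per_class.round(1).to_string()
                + f"\noverall accuracy: {self.overall_accuracy:.1f}%")


def class_metrics(pred, truth) -> EvalReport:
    """Pixel-wise one-vs-rest metrics restricted to annotated pixels.

    All metrics are percentages.  For a single image pair the per-class
    ``accuracy`` equals the class recall (= sensitivity); the distinction
    from ``accuracy_ovr`` matters once recalls are averaged over images.
    """
    p = np.asarray(getattr(pred, "labels", pred))
    t = np.asarray(getattr(truth, "labels", truth))
    if p.shape != t.shape:
        raise ValueError("prediction and truth rasters differ in shape")
    sel = np.isin(t, TISSUE_CLASSES)
    p, t = p[sel], t[sel]
    conf = np.zeros((3, 4), dtype=np.int64)
    for i, cls in enumerate(TISSUE_CLASSES):
        for j in range(4):
            conf[i, j] = np.sum((t == cls) & (p == j))
    total = conf.sum()
    rows = {}
    for i, cls in enumerate(TISSUE_CLASSES):
        tp = conf[i, cls]
        fn = conf[i].sum() - tp
        fp = conf[:, cls].sum() - tp
        tn = total - tp - fn - fp
        sen = 100.0 * tp / (tp + fn) if tp + fn else np.nan
        spe = 100.0 * tn / (tn + fp) if tn + fp else np.nan
        acc_ovr = 100.0 * (tp + tn) / total if total else np.nan
        rows[LABEL_NAMES[cls]] = {"sensitivity": sen, "specificity": spe,
                                  "accuracy": sen, "accuracy_ovr": acc_ovr}
    overall = 100.0 * np.trace(conf[:, 1:]) / total if total else np.nan
    return EvalReport(confusion=conf,
                      per_class=pd.DataFrame(rows).T,
                      overall_accuracy=overall)


@dataclass
class CVReport:
    """Cross-validation summary over folds.

    ``per_fold`` holds one row per (feature_set, fold, class) with the
    fold's per-class accuracy (mean per-image recall, %); ``summary``
    aggregates to mean, SD and median per feature set and class.
    """

    per_fold: pd.DataFrame
    summary: pd.DataFrame
    folds: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.summary.to_csv(path)


def _fold_partition(n_images: int, k: int, seed: int) -> list[np.ndarray]:
    order = np.random.default_rng(seed).permutation(n_images)
    return [np.sort(part) for part in np.array_split(order, k)]


def patient_holdout_split(patient_ids, n_test: int = 7, seed: int = 0):
    """Patient-level train/test split (whole patients held out).

    Returns (train_image_indices, test_image_indices).
    """
    ids = np.asarray(patient_ids)
    uniq = np.unique(ids)
    if n_test >= uniq.size:
        raise ValueError("n_test must leave at least one training patient")
    test_pat = np.random.default_rng(seed).choice(uniq, size=n_test,
                                                  replace=False)
    test = np.flatnonzero(np.isin(ids, test_pat))
    train = np.flatnonzero(~np.isin(ids, test_pat))
    return train, test


def cross_validate(stacks, k: int = 10,
                   feature_sets=("ALL",), cfg: RFConfig | None = None,
                   seed: int = 0) -> CVReport:
    """Image-grouped k-fold cross-validation with feature-set ablations.

    Parameters
    ----------
    stacks
        One DataFrame per image: the 25-feature stack plus a ``label``
        column (the annotated tissue label of each pixel).
    k
        Number of folds; images are partitioned into k groups of whole
        images (never split within an image).
    feature_sets
        Ablation names (see :data:`ABLATIONS`); each restricts the feature
        columns used for training and prediction.
    """
    n = len(stacks)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} images")
    cfg = cfg or RFConfig()
    folds = _fold_partition(n, k, seed)
    records = []
    for fs in feature_sets:
        cols = list(feature_subset(fs))
        # ablations with fewer features than m_try fall back to sqrt(p)
        fs_cfg = cfg
        if cfg.m_try > len(cols):
            fs_cfg = replace(cfg, m_try=max(1, int(np.sqrt(len(cols)))))
        for fold_idx, test_imgs in enumerate(folds):
            test_set = set(test_imgs.tolist())
            train_df = pd.concat([stacks[i] for i in range(n)
                                  if i not in test_set], ignore_index=True)
            model = train_rf(train_df[cols], train_df["label"].to_numpy(),
                             fs_cfg)
            # per-class recall per test image, then averaged over images
            per_class_acc = {cls: [] for cls in TISSUE_CLASSES}
            for i in test_imgs:
                te = stacks[i]
                X = te[cols].to_numpy(dtype=np.float64)
                pred = model.estimator.predict_proba(X)
                yhat = model.estimator.classes_[np.argmax(pred, axis=1)]
                y = te["label"].to_numpy()
                for cls in TISSUE_CLASSES:
                    m = y == cls
                    if m.any():
                        per_class_acc[cls].append(100.0 * np.mean(
                            yhat[m] == cls))
            for cls in TISSUE_CLASSES:
                vals = per_class_acc[cls]
                records.append({
                    "feature_set": fs, "fold": fold_idx,
                    "class": LABEL_NAMES[cls],
                    "accuracy": float(np.mean(vals)) if vals else np.nan,
                })
    per_fold = pd.DataFrame.from_records(records)
    summary = (per_fold.groupby(["feature_set", "class"])["accuracy"]
               .agg(mean="mean", sd="std", median="median"))
    return CVReport(per_fold=per_fold, summary=summary, folds=folds)


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float


def icc_agreement(areas_1, areas_2) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measurement ICC
    (ICC(2,1)) with its F-based 95% confidence interval."""
    a1 = np.asarray(areas_1, dtype=np.float64)
    a2 = np.asarray(areas_2, dtype=np.float64)
    if a1.size != a2.size or a1.size < 3:
        raise ValueError("need at least 3 paired measurements")
    n = a1.size
    df = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["r1", "r2"], n),
        "score": np.concatenate((a1, a2)),
    })
    res = pg.intraclass_corr(df, targets="target", raters="rater",
                             ratings="score")
    # pingouin labels ICC(2,1) either "ICC2" or "ICC(A,1)" across versions
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = row[ci_col]
    return ICCResult(icc=float(row["ICC"]), ci_low=float(lo),
                     ci_high=float(hi))


def bland_altman(areas_1, areas_2):
    """Bias and 95% limits of agreement of paired measurements.

    Returns ``(bias, loa_low, loa_high)`` where the limits are
    ``bias +- 1.96 * SD(differences)``.
    """
    a1 = np.asarray(areas_1, dtype=np.float64)
    a2 = np.asarray(areas_2, dtype=np.float64)
    if a1.size != a2.size or a1.size < 2:
        raise ValueError("need at least 2 paired measurements")
    d = a2 - a1
    bias = float(d.mean())
    half = 1.96 * float(d.std(ddof=1))
    return bias, bias - half, bias + half


def regression_agreement(areas_1, areas_2):
    """OLS of rater 2 on rater 1; returns (slope, intercept, R^2)."""
    a1 = np.asarray(areas_1, dtype=np.float64)
    a2 = np.asarray(areas_2, dtype=np.float64)
    if a1.size != a2.size or a1.size < 3:
        raise ValueError("need at least 3 paired measurements")
    if np.var(a1) == 0:
        raise ValueError("predictor has zero variance")
    fit = stats.linregress(a1, a2)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)
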