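"""Dual random-forest reedbed classifier.

The model is two 500-tree random forests (3 variables tried per split) fit
on the same point sample but with different seeds and, by default, different
class balancing; the map probability is the per-pixel *minimum* of the two
forests' reedbed probabilities, which trims false-positive area at little
cost in true positives.  The probability-to-presence cutoff is the threshold
maximising Cohen's kappa on out-of-bag predictions of the training points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .core import FeatureStack, ReedProbabilityMap
from .vector import TruthPolygon, sample_points_in_polygon

REED = "reedbed"
NONREED = "non-reedbed"


def binarize_label(label: str) -> str:
    return REED if label == REED else NONREED


@dataclass
class TrainingSample:
    """Point sample drawn from labelled polygons with attached features."""

    points: pd.DataFrame  # columns: row, col, label, polygon_id + feature cols
    feature_names: list[str]

    @property
    def X(self) -> np.ndarray:
        return self.points[self.feature_names].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.points["label"].to_numpy()

    @property
    def per_polygon_counts(self) -> pd.Series:
        return self.points.groupby("polygon_id").size()

    def subset_polygons(self, polygon_ids) -> "TrainingSample":
        keep = self.points["polygon_id"].isin(list(polygon_ids))
        return TrainingSample(self.points[keep].reset_index(drop=True),
                              list(self.feature_names))


def sample_training_points(
    polygons: list[TruthPolygon],
    stack: FeatureStack,
    n_per_polygon: int = 100,
    seed: int = 0,
) -> TrainingSample:
    """Draw up to ``n_per_polygon`` uniform points inside each polygon.

    Later points falling in the same pixel as an earlier point (within a
    polygon's draw) are discarded, as are points on invalid feature pixels.
    Polygon labels are binarised to reedbed / non-reedbed.
    """
    rng = np.random.default_rng(seed)
    h, w = stack.shape
    valid = stack.valid
    rows_out = []
    for pid, poly in enumerate(polygons):
        minx, miny, maxx, maxy = poly.geometry.bounds
        if minx < 0 or miny < 0 or maxx > w or maxy > h:
            raise ValueError(f"polygon {pid} ({poly.label}) lies outside the raster")
        pts = sample_points_in_polygon(poly.geometry, n_per_polygon, rng)
        seen: set[tuple[int, int]] = set()
        for x, y in pts:
            r, c = int(np.floor(y)), int(np.floor(x))
            if (r, c) in seen:
                continue
            seen.add((r, c))
            if not valid[r, c]:
                continue
            rows_out.append((r, c, binarize_label(poly.label), pid,
                             *stack.layers[:, r, c]))
    cols = ["row", "col", "label", "polygon_id", *stack.names]
    df = pd.DataFrame(rows_out, columns=cols)
    return TrainingSample(df, list(stack.names))


def _class_commission_from_oob(clf: RandomForestClassifier, y: np.ndarray) -> dict[str, float]:
    """Per-class OOB commission error: share of OOB predictions of a class
    that are wrong."""
    proba = clf.oob_decision_function_
    seen = ~np.isnan(proba).any(axis=1)
    pred = np.asarray(clf.classes_)[np.argmax(proba[seen], axis=1)]
    truth = y[seen]
    out = {}
    for cls in clf.classes_:
        m = pred == cls
        out[str(cls)] = float((truth[m] != cls).mean()) if m.any() else float("nan")
    return out


@dataclass
class ReedModel:
    """The fused dual-forest model.

    ``heldout_reed_proba`` holds, per training point and per forest, a
    reedbed probability the point did not influence (out-of-bag for points
    the forest trained on; a plain prediction for points outside a balanced
    subsample; NaN if unavailable) — the basis for threshold selection
    without in-bag optimism.
    """

    rf1: RandomForestClassifier
    rf2: RandomForestClassifier
    feature_names: list[str]
    variable_importance: pd.DataFrame  # index: feature, columns RF1/RF2 (Gini decrease)
    oob_by_class: dict[str, dict[str, float]]  # {'RF1': {class: commission}, ...}
    heldout_reed_proba: np.ndarray | None = None  # (n_points, 2)
    threshold: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def forests(self) -> tuple[RandomForestClassifier, RandomForestClassifier]:
        return (self.rf1, self.rf2)

    def reed_proba(self, X: np.ndarray, forest: RandomForestClassifier) -> np.ndarray:
        k = list(forest.classes_).index(REED)
        return forest.predict_proba(X)[:, k]


def fit_reed_model(
    sample: TrainingSample,
    balanced: bool = True,
    n_trees: int = 500,
    vars_per_split: int | str = 3,
    seeds: tuple[int, int] = (0, 1),
) -> ReedModel:
    """Fit the two forests (RF1 unbalanced; RF2 balanced when ``balanced``).

    Both forests use the same features; they differ by seed and, when
    ``balanced``, by RF2 training on a class-balanced subsample (the
    majority class downsampled to the minority count — the analogue of
    balanced per-class bootstrap sampling).  Gini variable importances,
    per-class OOB commission errors and held-out reedbed probabilities are
    recorded for both forests.
    """
    y = sample.y
    if len(np.unique(y)) < 2:
        raise ValueError("training sample must contain both classes")
    X = sample.X
    mf = vars_per_split if vars_per_split != "sqrt" else "sqrt"

    def make(seed: int, Xs, ys) -> RandomForestClassifier:
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features=mf, oob_score=True,
            random_state=seed, n_jobs=1)
        clf.fit(Xs, ys)
        return clf

    def oob_reed(clf: RandomForestClassifier) -> np.ndarray:
        k = list(clf.classes_).index(REED)
        return clf.oob_decision_function_[:, k]

    n = len(y)
    rf1 = make(seeds[0], X, y)
    h1 = oob_reed(rf1)
    if balanced:
        rng = np.random.default_rng(seeds[1])
        classes, counts = np.unique(y, return_counts=True)
        n_min = counts.min()
        idx_parts = []
        for cls in classes:
            rows = np.flatnonzero(y == cls)
            if rows.size > n_min:
                rows = np.sort(rng.choice(rows, n_min, replace=False))
            idx_parts.append(rows)
        idx2 = np.sort(np.concatenate(idx_parts))
        rf2 = make(seeds[1], X[idx2], y[idx2])
        h2 = np.full(n, np.nan)
        h2[idx2] = oob_reed(rf2)
        rest = np.setdiff1d(np.arange(n), idx2)
        if rest.size:
            k2 = list(rf2.classes_).index(REED)
            h2[rest] = rf2.predict_proba(X[rest])[:, k2]
        oob2 = _class_commission_from_oob(rf2, y[idx2])
    else:
        idx2 = np.arange(n)
        rf2 = make(seeds[1], X, y)
        h2 = oob_reed(rf2)
        oob2 = _class_commission_from_oob(rf2, y)
    imp = pd.DataFrame(
        {"RF1": rf1.feature_importances_, "RF2": rf2.feature_importances_},
        index=sample.feature_names,
    )
    oob = {"RF1": _class_commission_from_oob(rf1, y), "RF2": oob2}
    heldout = np.column_stack([h1, h2])
    return ReedModel(rf1, rf2, list(sample.feature_names), imp, oob, heldout,
                     meta={"n_trees": n_trees, "vars_per_split": vars_per_split,
                           "balanced": balanced, "seeds": list(seeds)})


def predict_probability(
    model: ReedModel, stack: FeatureStack, fusion: str = "dual_min"
) -> ReedProbabilityMap:
    """Predict the reedbed probability map: min(RF1, RF2) per valid pixel.

    ``fusion='single'`` uses RF1 alone (the single-forest workflow variant).
    """
    if list(stack.names) != list(model.feature_names):
        missing = set(model.feature_names) - set(stack.names)
        extra = set(stack.names) - set(model.feature_names)
        raise ValueError(
            f"feature names do not match training: missing={sorted(missing)}, "
            f"unexpected={sorted(extra)}"
        )
    valid = stack.valid
    X = stack.matrix(valid)
    p = np.full(stack.shape, np.nan)
    if X.shape[0]:
        p1 = model.reed_proba(X, model.rf1)
        if fusion == "dual_min":
            p2 = model.reed_proba(X, model.rf2)
            p[valid] = np.minimum(p1, p2)
        elif fusion == "single":
            p[valid] = p1
        else:
            raise ValueError(f"unknown fusion {fusion!r}")
    return ReedProbabilityMap(p, threshold=model.threshold)


def cohens_kappa(tp: float, fp: float, fn: float, tn: float) -> float:
    """Chance-corrected agreement from a 2x2 confusion matrix.

    kappa = (po - pe) / (1 - pe) with po the observed accuracy and pe the
    chance agreement from the marginals; a degenerate matrix with pe = 1
    returns 0 by convention.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    n = tp + fp + fn + tn
    if n <= 0:
        raise ValueError("empty confusion matrix")
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / (n * n)
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)


def _kappa_curve(probs: np.ndarray, y: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Kappa at each threshold (presence when p > t), vectorised."""
    order = np.argsort(probs, kind="stable")
    ps, ys = probs[order], y[order]
    n = len(ps)
    npos = int(ys.sum())
    cum_pos = np.concatenate([[0], np.cumsum(ys)])  # positives with p <= ps[i-1]
    # for threshold t: points with p > t are predicted positive
    idx = np.searchsorted(ps, thresholds, side="right")
    pred_pos = n - idx
    pos_below = cum_pos[idx]           # true positives predicted negative = fn
    fn = pos_below
    tp = npos - fn
    fp = pred_pos - tp
    tn = n - tp - fp - fn
    out = np.empty(len(thresholds))
    for i in range(len(thresholds)):
        out[i] = cohens_kappa(tp[i], fp[i], fn[i], tn[i])
    return out


def kappa_threshold(probs: np.ndarray, labels: np.ndarray) -> float:
    """Probability cutoff maximising Cohen's kappa.

    Candidates are 0, 1 and the midpoints between consecutive sorted unique
    probabilities; presence is p > threshold; the smallest candidate
    attaining the maximal kappa is returned.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind not in "bi":
        y = y == REED
    y = y.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    u = np.unique(probs)
    if u.size < 2:
        raise ValueError("all probabilities identical: no threshold exists")
    candidates = np.concatenate([[0.0], (u[:-1] + u[1:]) / 2.0, [1.0]])
    kappas = _kappa_curve(probs, y, candidates)
    best = kappas.max()
    return float(candidates[np.nonzero(kappas >= best - 1e-12)[0][0]])


def oob_learning_curve(
    sample: TrainingSample,
    polygon_order: list[int] | None = None,
    seeds: tuple[int, int] = (0, 1),
    **fit_kwargs,
) -> pd.DataFrame:
    """Per-class OOB commission error vs number of reedbed polygons.

    Refits the dual model on cumulative subsets of reedbed polygons (all
    non-reedbed polygons always included), emitting one row per subset with
    the mean commission error over the two forests.
    """
    df = sample.points
    reed_pids = sorted(df.loc[df["label"] == REED, "polygon_id"].unique())
    if len(reed_pids) < 2:
        raise ValueError("need at least 2 reedbed polygons for a curve")
    if polygon_order is not None:
        reed_pids = [p for p in polygon_order if p in reed_pids]
    non_pids = sorted(df.loc[df["label"] == NONREED, "polygon_id"].unique())
    rows = []
    for k in range(1, len(reed_pids) + 1):
        sub = sample.subset_polygons(list(non_pids) + reed_pids[:k])
        model = fit_reed_model(sub, seeds=seeds, **fit_kwargs)
        reed_c = np.nanmean([model.oob_by_class[f]["reedbed"] for f in ("RF1", "RF2")])
        non_c = np.nanmean([model.oob_by_class[f][NONREED] for f in ("RF1", "RF2")])
        rows.append({"n_reed_polygons": k,
                     "reed_commission_oob": reed_c,
                     "nonreed_commission_oob": non_c})
    return pd.DataFrame(rows)
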