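"""Stratified map validation and error-corrected extent estimation.

The field design over-samples predicted reedbed: within the quadrant of the
scene richest in non-zero predicted cover, up to 10 hectares are drawn from
each predicted-cover stratum {p = 0; 0 < p <= 0.33; 0.33 < p <= 0.66;
0.66 < p <= 1}; in each hectare, three predicted-presence and three
predicted-absence 10 m cells are visited.  Observed hectare cover is
recorded to the nearest 10%.  From the resulting records we derive 10 m and
hectare-scale confusion matrices, AUC, a cover regression, a chi-square test
of where false positives fall, and the commission/omission-corrected total
extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import cohens_kappa
from .core import HectareCoverMap

STRATUM_EDGES = (0.0, 0.33, 0.66, 1.0)
STRATUM_LABELS = ("p=0", "0<p<=0.33", "0.33<p<=0.66", "0.66<p<=1")


def stratum_of(cover: float) -> str:
    """Predicted-cover stratum; {0} is its own stratum, intervals are (lo, hi]."""
    if cover == 0:
        return STRATUM_LABELS[0]
    for lo, hi, lab in zip(STRATUM_EDGES[:-1], STRATUM_EDGES[1:], STRATUM_LABELS[1:]):
        if lo < cover <= hi:
            return lab
    raise ValueError(f"cover {cover} outside [0, 1]")


@dataclass
class ValidationDesign:
    n_per_stratum: int = 10
    cells_presence: int = 3
    cells_absence: int = 3
    seed: int = 0


@dataclass
class ConfusionMetrics:
    """2x2 confusion counts with the derived map-accuracy rates."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def commission_reed(self) -> float:
        """Share of predicted reedbed that is not reedbed (1 - precision)."""
        d = self.tp + self.fp
        return self.fp / d if d else float("nan")

    @property
    def omission_reed(self) -> float:
        """Share of true reedbed predicted as non-reedbed (1 - recall)."""
        d = self.tp + self.fn
        return self.fn / d if d else float("nan")

    @property
    def commission_nonreed(self) -> float:
        d = self.fn + self.tn
        return self.fn / d if d else float("nan")

    @property
    def overall(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def kappa(self) -> float:
        return cohens_kappa(self.tp, self.fp, self.fn, self.tn)

    @property
    def predicted_prevalence(self) -> float:
        return (self.tp + self.fp) / self.n

    @property
    def true_prevalence(self) -> float:
        return (self.tp + self.fn) / self.n

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "commission_reed": self.commission_reed,
            "omission_reed": self.omission_reed,
            "commission_nonreed": self.commission_nonreed,
            "overall": self.overall, "kappa": self.kappa,
            "predicted_prevalence": self.predicted_prevalence,
            "true_prevalence": self.true_prevalence,
        }


def stratify_hectares(
    cover: HectareCoverMap,
    design: ValidationDesign,
    scene_bounds: tuple[int, int, int, int] | None = None,
) -> pd.DataFrame:
    """Draw the stratified hectare sample for one scene.

    Within the geographic quadrant (2x2 split of the scene) holding the most
    non-zero-cover hectares, up to ``n_per_stratum`` valid hectares are drawn
    uniformly without replacement from each predicted-cover stratum; strata
    with fewer qualifying hectares contribute all of them.  Returns a frame
    with hectare (row, col), predicted cover and stratum.
    """
    grid = cover.cover
    if scene_bounds is None:
        scene_bounds = (0, 0, grid.shape[0], grid.shape[1])
    r0, c0, r1, c1 = scene_bounds
    sub = grid[r0:r1, c0:c1]
    if not np.isfinite(sub).any():
        raise ValueError("scene contains no valid hectares")
    rm, cm = (r1 - r0) // 2, (c1 - c0) // 2
    quads = {
        (0, 0): (slice(0, rm), slice(0, cm)),
        (0, 1): (slice(0, rm), slice(cm, c1 - c0)),
        (1, 0): (slice(rm, r1 - r0), slice(0, cm)),
        (1, 1): (slice(rm, r1 - r0), slice(cm, c1 - c0)),
    }
    def nz_count(sl):
        q = sub[sl]
        return int((np.isfinite(q) & (q > 0)).sum())
    best = max(quads, key=lambda k: (nz_count(quads[k]), -k[0], -k[1]))
    rs, cs = quads[best]
    rng = np.random.default_rng(design.seed)
    rows = []
    q = sub[rs, cs]
    rr, cc = np.nonzero(np.isfinite(q))
    strata = np.array([stratum_of(v) for v in q[rr, cc]])
    for lab in STRATUM_LABELS:
        idx = np.nonzero(strata == lab)[0]
        if idx.size == 0:
            continue
        take = rng.choice(idx, size=min(design.n_per_stratum, idx.size), replace=False)
        for k in np.sort(take):
            hr = r0 + rs.start + rr[k]
            hc = c0 + cs.start + cc[k]
            rows.append({"hectare_row": int(hr), "hectare_col": int(hc),
                         "predicted_cover": float(grid[hr, hc]), "stratum": lab})
    return pd.DataFrame(rows)


def sample_cells(
    presence: np.ndarray,
    valid: np.ndarray,
    hectare: tuple[int, int],
    design: ValidationDesign,
    rng: np.random.Generator,
    block: int = 10,
) -> pd.DataFrame:
    """Draw the within-hectare cell sample: 3 predicted-presence + 3 absence.

    If a predicted class has fewer qualifying cells than requested, all are
    taken and the shortfall recorded.
    """
    hr, hc = hectare
    r0, c0 = hr * block, hc * block
    blk_p = presence[r0:r0 + block, c0:c0 + block]
    blk_v = valid[r0:r0 + block, c0:c0 + block]
    rows = []
    for pred, want in ((True, design.cells_presence), (False, design.cells_absence)):
        rr, cc = np.nonzero(blk_v & (blk_p == pred))
        take = rng.choice(rr.size, size=min(want, rr.size), replace=False)
        shortfall = want - take.size
        for k in np.sort(take):
            rows.append({"cell_row": int(r0 + rr[k]), "cell_col": int(c0 + cc[k]),
                         "cell_pred": int(pred), "shortfall": shortfall})
    return pd.DataFrame(rows, columns=["cell_row", "cell_col", "cell_pred", "shortfall"])


def collect_validation_records(
    cover: HectareCoverMap,
    presence: np.ndarray,
    valid: np.ndarray,
    truth_presence: np.ndarray,
    design: ValidationDesign,
    landcover: np.ndarray | None = None,
    landcover_labels: list[str] | None = None,
    block: int = 10,
) -> pd.DataFrame:
    """Run the virtual field campaign against simulator truth.

    For each stratified hectare: observed cover is the true reed fraction
    quantised to the nearest 10%; each sampled cell contributes predicted and
    observed presence.  The hectare's land-cover class is the modal truth
    class (if a class map is supplied).  Returns the long-format record
    table (one row per visited cell).
    """
    hectares = stratify_hectares(cover, design)
    rng = np.random.default_rng(design.seed + 1)
    out = []
    for _, hrow in hectares.iterrows():
        hr, hc = int(hrow["hectare_row"]), int(hrow["hectare_col"])
        r0, c0 = hr * block, hc * block
        blk_t = truth_presence[r0:r0 + block, c0:c0 + block]
        blk_v = valid[r0:r0 + block, c0:c0 + block]
        obs_cover = float(blk_t[blk_v].mean()) if blk_v.any() else float("nan")
        obs_cover = round(obs_cover * 10.0) / 10.0  # to the nearest 10%
        if landcover is not None:
            blk_lc = landcover[r0:r0 + block, c0:c0 + block]
            vals, counts = np.unique(blk_lc, return_counts=True)
            lc = vals[np.argmax(counts)]
            lc_name = landcover_labels[int(lc)] if landcover_labels else str(lc)
        else:
            lc_name = ""
        cells = sample_cells(presence, valid, (hr, hc), design, rng, block)
        for _, crow in cells.iterrows():
            out.append({
                "hectare_id": f"{hr}_{hc}",
                "stratum": hrow["stratum"],
                "predicted_cover": hrow["predicted_cover"],
                "observed_cover": obs_cover,
                "landcover": lc_name,
                "cell_row": int(crow["cell_row"]),
                "cell_col": int(crow["cell_col"]),
                "cell_pred": int(crow["cell_pred"]),
                "cell_obs": int(truth_presence[int(crow["cell_row"]),
                                               int(crow["cell_col"])]),
            })
    return pd.DataFrame(out)


def confusion_from_records(
    records: pd.DataFrame, scale: str = "tenm", ha_presence_threshold: float = 0.0
) -> ConfusionMetrics:
    """Confusion counts from validation records at 10 m or hectare scale.

    At 10 m scale every visited cell contributes its predicted vs observed
    presence.  At hectare scale each hectare contributes once, with presence
    defined as cover > ``ha_presence_threshold`` on both the predicted and
    the observed side.
    """
    if records.empty:
        raise ValueError("no validation records")
    if scale == "tenm":
        pred = records["cell_pred"].to_numpy(dtype=bool)
        obs = records["cell_obs"].to_numpy(dtype=bool)
    elif scale == "hectare":
        ha = records.drop_duplicates("hectare_id")
        pred = ha["predicted_cover"].to_numpy() > ha_presence_threshold
        obs = ha["observed_cover"].to_numpy() > ha_presence_threshold
    else:
        raise ValueError(f"unknown scale {scale!r}")
    tp = int((pred & obs).sum())
    fp = int((pred & ~obs).sum())
    fn = int((~pred & obs).sum())
    tn = int((~pred & ~obs).sum())
    return ConfusionMetrics(tp, fp, fn, tn)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def cover_regression(predicted: np.ndarray, observed: np.ndarray
                     ) -> tuple[float, float, float]:
    """OLS of observed cover on predicted cover; returns (slope, intercept, R^2)."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(y) == 0 or np.var(x) == 0:
        raise ValueError("zero variance: regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fp_landcover_chisq(
    fp_counts: np.ndarray, composition: np.ndarray
) -> tuple[float, int, float]:
    """Pearson chi-square for false positives vs sample land-cover composition.

    ``composition`` gives each land-cover group's share of the sampled area;
    expected false positives are composition x total FP.  Returns
    (X^2, df, p).
    """
    obs = np.asarray(fp_counts, dtype=float)
    comp = np.asarray(composition, dtype=float)
    if obs.shape != comp.shape:
        raise ValueError("counts and composition must align")
    exp = comp / comp.sum() * obs.sum()
    if (exp == 0).any():
        raise ValueError("expected count of zero in some group")
    x2 = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    p = float(stats.chi2.sf(x2, df))
    return x2, df, p


def corrected_extent(
    predicted_total: float,
    commission: float,
    omission: float,
    variant: str = "standard",
) -> float:
    """Commission/omission-corrected total extent in hectares.

    True-positive area is predicted_total x (1 - commission).  The
    ``standard`` design-based estimator divides by (1 - omission) to add
    back the omitted share; ``as_printed`` divides by omission instead — the
    reverse-engineered form that reproduces the published national figure
    from its printed inputs.  Both are exposed because the published text
    does not disambiguate.
    """
    if not 0 <= commission < 1:
        raise ValueError("commission must be in [0, 1)")
    tp_area = predicted_total * (1.0 - commission)
    if variant == "standard":
        if omission >= 1:
            raise ValueError("omission must be < 1 for the standard variant")
        return tp_area / (1.0 - omission)
    if variant == "as_printed":
        if omission <= 0 or omission >= 1:
            raise ValueError("omission must be in (0, 1) for the as_printed variant")
        return tp_area / omission
    raise ValueError(f"unknown variant {variant!r}")


def extent_correction_from_metrics(
    predicted_total: float, metrics: ConfusionMetrics, variant: str = "standard"
) -> float:
    return corrected_extent(predicted_total, metrics.commission_reed,
                            metrics.omission_reed, variant)
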