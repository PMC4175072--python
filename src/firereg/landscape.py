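"""Landscape-level modeling of the historical fire-severity regime.

Terrain covariates come from a 30-m elevation grid (Horn slope/aspect,
quadratic-surface curvature, Euclidean feature distances). Site regimes,
collapsed to a binary low/mixed response, are modeled with a single CART
classifier grown on Gini impurity and pruned to the mean best size over a
10-fold cross-validation, the protocol that tends to yield a small,
generalizable tree. The fitted rule for Colorado Front Range montane
forests — low-severity at or below 2263 m elevation, or on slopes of at
most 4 degrees above that — can be applied directly to a covariate grid to
map the regime, and the mapped areas summarized by cover type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata
from sklearn.tree import DecisionTreeClassifier

from .raster import CELL_AREA_HA, Raster, require_aligned

__all__ = [
    "REGIME_LOW",
    "REGIME_MIXED",
    "RegimeRule",
    "FittedTree",
    "derive_terrain",
    "distance_to_feature",
    "fit_cart",
    "evaluate_model",
    "apply_rule",
    "summarize_area",
]

# Integer codes for regime rasters; chosen as fixed points of the MTBS
# class binarization ({1,2} -> 1, {3,4} -> 3) so that binarization is
# idempotent.
REGIME_LOW, REGIME_MIXED = 1, 3


@dataclass(frozen=True)
class RegimeRule:
    """Two-split decision rule mapping terrain to the historical regime.

    Predicts a low-severity regime where elevation <= ``elev_threshold_m``
    OR slope <= ``slope_threshold_deg``; mixed-severity elsewhere.
    """

    elev_threshold_m: float = 2263.0
    slope_threshold_deg: float = 4.0

    def predict_low(self, elevation_m, slope_deg) -> np.ndarray:
        elevation_m = np.asarray(elevation_m, dtype=float)
        slope_deg = np.asarray(slope_deg, dtype=float)
        return (elevation_m <= self.elev_threshold_m) | (
            slope_deg <= self.slope_threshold_deg
        )


# ---------------------------------------------------------------------------
# Terrain covariates
# ---------------------------------------------------------------------------

def _shifted(z: np.ndarray) -> dict[str, np.ndarray]:
    """Edge-replicated 3x3 neighborhood planes of ``z``."""
    zp = np.pad(z, 1, mode="edge")
    return {
        "a": zp[:-2, :-2], "b": zp[:-2, 1:-1], "c": zp[:-2, 2:],
        "d": zp[1:-1, :-2], "e": zp[1:-1, 1:-1], "f": zp[1:-1, 2:],
        "g": zp[2:, :-2], "h": zp[2:, 1:-1], "i": zp[2:, 2:],
    }


def derive_terrain(elevation: Raster) -> dict[str, Raster]:
    """Slope, aspect transforms and curvature from an elevation grid.

    Slope and aspect use Horn's 3x3 finite differences; curvature is the
    Laplacian of the local quadratic surface (negative = convex), in
    1/100 m. Aspect is degrees clockwise from north; the two aspect
    covariates are sin(aspect) (eastness) and arcsin-transformed northness.
    Nodata propagates to every derived band.
    """
    if elevation.cell_m <= 0:
        raise ValueError("cell size must be positive")
    z = np.asarray(elevation.values, dtype=float)
    n = _shifted(z)
    L = elevation.cell_m
    dzdx = ((n["c"] + 2 * n["f"] + n["i"]) - (n["a"] + 2 * n["d"] + n["g"])) / (8 * L)
    dzdy = ((n["g"] + 2 * n["h"] + n["i"]) - (n["a"] + 2 * n["b"] + n["c"])) / (8 * L)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # Aspect: downslope direction, clockwise from north (row axis points south).
    aspect = np.degrees(np.arctan2(-dzdx, dzdy)) % 360.0
    aspect_rad = np.radians(aspect)
    aspect_sin = np.sin(aspect_rad)
    northness = np.cos(aspect_rad)
    aspect_arcsine = np.arcsin(np.clip(northness, -1.0, 1.0))
    # Zevenbergen-Thorne quadratic surface curvature.
    D = ((n["d"] + n["f"]) / 2.0 - n["e"]) / L**2
    E = ((n["b"] + n["h"]) / 2.0 - n["e"]) / L**2
    curvature = -2.0 * (D + E) * 100.0

    bad = ~elevation.mask
    out = {}
    for name, band in (
        ("slope_deg", slope),
        ("aspect_deg", aspect),
        ("aspect_sin", aspect_sin),
        ("aspect_arcsine", aspect_arcsine),
        ("curvature", curvature),
    ):
        band = band.astype(float)
        band[bad] = np.nan
        out[name] = elevation.like(band, nodata=np.nan)
    return out


def distance_to_feature(
    mask_raster: Raster, min_area_ha: float = 0.1
) -> Raster:
    """Euclidean cell-center distance (m) to the nearest feature cell.

    Connected components (8-connectivity) smaller than ``min_area_ha`` are
    dropped before the distance transform: a single 30-m cell (0.09 ha)
    does not count as a grassland patch under the 0.1-ha minimum.
    """
    mask = np.asarray(mask_raster.values).astype(bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n:
        cell_ha = CELL_AREA_HA(mask_raster.cell_m)
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = sizes * cell_ha >= min_area_ha
        mask = keep[labels]
    if not mask.any():
        warnings.warn(
            "no feature patches remain after the minimum-area filter; "
            "distances are +inf",
            stacklevel=2,
        )
        return mask_raster.like(np.full(mask.shape, np.inf), nodata=np.nan)
    dist = ndimage.distance_transform_edt(~mask) * mask_raster.cell_m
    return mask_raster.like(dist.astype(float), nodata=np.nan)


# ---------------------------------------------------------------------------
# CART fitting and evaluation
# ---------------------------------------------------------------------------

@dataclass
class FittedTree:
    """A grown-and-pruned CART with its cross-validation diagnostics."""

    tree: DecisionTreeClassifier
    feature_names: list[str]
    cv_best_sizes: list[int]
    pruned_n_leaves: int
    grown_n_leaves: int
    pcc: float
    auc: float

    @property
    def root_split(self) -> tuple[str, float] | None:
        """(feature, threshold) at the root, or None for a stump."""
        t = self.tree.tree_
        if t.node_count < 2:
            return None
        return self.feature_names[t.feature[0]], float(t.threshold[0])


def _prune_to_size(
    X: np.ndarray, y: np.ndarray, target_leaves: int, **tree_kwargs
) -> DecisionTreeClassifier:
    """Refit with the cost-complexity alpha whose subtree size is closest
    to ``target_leaves`` (ties -> smaller subtree)."""
    base = DecisionTreeClassifier(criterion="gini", **tree_kwargs).fit(X, y)
    path = base.cost_complexity_pruning_path(X, y)
    best = None
    for alpha in path.ccp_alphas:
        sub = DecisionTreeClassifier(
            criterion="gini", ccp_alpha=alpha, **tree_kwargs
        ).fit(X, y)
        leaves = sub.get_n_leaves()
        key = (abs(leaves - target_leaves), leaves)
        if best is None or key < best[0]:
            best = (key, sub)
    return best[1]


def fit_cart(
    covariates: pd.DataFrame,
    labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    min_samples_leaf: int = 1,
    balanced_priors: bool = False,
) -> FittedTree:
    """Grow a Gini CART and prune it to the mean best cross-validated size.

    Per fold, the cost-complexity subtree with the highest held-out
    accuracy is recorded (ties -> smallest); the full-data tree is pruned
    to the rounded mean of those sizes. PCC and AUC score the pruned
    tree's classification of the sites. Deterministic for a given
    ``seed`` (fold assignment).
    """
    X = covariates.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; nothing to fit")
    kwargs = dict(
        min_samples_leaf=min_samples_leaf,
        random_state=seed,
        class_weight="balanced" if balanced_priors else None,
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    fold_of = np.empty(len(y), dtype=int)
    fold_of[order] = np.arange(len(y)) % folds

    best_sizes = []
    for k in range(folds):
        tr, te = fold_of != k, fold_of == k
        if len(np.unique(y[tr])) < 2 or te.sum() == 0:
            continue
        base = DecisionTreeClassifier(criterion="gini", **kwargs).fit(X[tr], y[tr])
        path = base.cost_complexity_pruning_path(X[tr], y[tr])
        best = None
        for alpha in path.ccp_alphas:
            sub = DecisionTreeClassifier(
                criterion="gini", ccp_alpha=alpha, **kwargs
            ).fit(X[tr], y[tr])
            acc = float(np.mean(sub.predict(X[te]) == y[te]))
            leaves = sub.get_n_leaves()
            if best is None or (-acc, leaves) < best[0]:
                best = ((-acc, leaves), leaves)
        best_sizes.append(best[1])

    target = int(round(float(np.mean(best_sizes)))) if best_sizes else 1
    pruned = _prune_to_size(X, y, target, **kwargs)

    pos = classes[-1]
    pred = pruned.predict(X)
    score = pruned.predict_proba(X)[:, list(pruned.classes_).index(pos)]
    pcc, auc = evaluate_model(pred, y, score, positive=pos)

    grown = DecisionTreeClassifier(criterion="gini", **kwargs).fit(X, y)
    return FittedTree(
        tree=pruned,
        feature_names=list(covariates.columns),
        cv_best_sizes=best_sizes,
        pruned_n_leaves=pruned.get_n_leaves(),
        grown_n_leaves=grown.get_n_leaves(),
        pcc=pcc,
        auc=auc,
    )


def evaluate_model(
    predictions: np.ndarray,
    labels: np.ndarray,
    scores: np.ndarray | None = None,
    positive=None,
) -> tuple[float, float]:
    """Percentage correctly classified and rank-based AUC.

    AUC is the Mann-Whitney statistic of ``scores`` for the positive class,
    with midranks for ties; NaN when scores are missing or one class is
    absent.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("empty input")
    pcc = 100.0 * float(np.mean(predictions == labels))
    if scores is None:
        return pcc, float("nan")
    if positive is None:
        positive = np.unique(labels)[-1]
    is_pos = labels == positive
    n1, n0 = int(is_pos.sum()), int((~is_pos).sum())
    if n1 == 0 or n0 == 0:
        return pcc, float("nan")
    ranks = rankdata(np.asarray(scores, dtype=float))
    auc = (ranks[is_pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return pcc, float(auc)


# ---------------------------------------------------------------------------
# Rule mapping and area summaries
# ---------------------------------------------------------------------------

def apply_rule(
    elevation: Raster, slope: Raster, rule: RegimeRule | None = None
) -> Raster:
    """Map the regime rule over aligned elevation and slope grids.

    The output is pointwise and idempotent: each cell depends only on its
    own covariates. Nodata in either band propagates.
    """
    if rule is None:
        rule = RegimeRule()
    require_aligned(elevation, slope)
    low = rule.predict_low(elevation.values, slope.values)
    out = np.where(low, REGIME_LOW, REGIME_MIXED).astype(int)
    nodata = -9999
    out[~(elevation.mask & slope.mask)] = nodata
    return elevation.like(out, nodata=nodata)


def summarize_area(
    regime: Raster, cover: Raster | None = None
) -> pd.DataFrame:
    """Mapped area by regime (and cover type): counts, hectares, percent.

    Percentages of low vs mixed sum to 100 within each row.
    """
    if cover is not None:
        require_aligned(regime, cover)
    valid = regime.mask
    if not valid.any():
        warnings.warn("all-nodata regime raster; empty summary", stacklevel=2)
        return pd.DataFrame(
            columns=["n_low", "n_mixed", "ha_low", "ha_mixed",
                     "pct_low", "pct_mixed"]
        )
    cell_ha = CELL_AREA_HA(regime.cell_m)
    vals = np.asarray(regime.values)

    def _row(sel: np.ndarray) -> dict:
        n_low = int(np.count_nonzero(vals[sel] == REGIME_LOW))
        n_mixed = int(np.count_nonzero(vals[sel] == REGIME_MIXED))
        total = n_low + n_mixed
        return {
            "n_low": n_low, "n_mixed": n_mixed,
            "ha_low": n_low * cell_ha, "ha_mixed": n_mixed * cell_ha,
            "pct_low": 100.0 * n_low / total if total else float("nan"),
            "pct_mixed": 100.0 * n_mixed / total if total else float("nan"),
        }

    rows = {"overall": _row(valid)}
    if cover is not None:
        cvals = np.asarray(cover.values)
        for ct in np.unique(cvals[valid & cover.mask]):
            rows[str(ct)] = _row(valid & cover.mask & (cvals == ct))
    return pd.DataFrame.from_dict(rows, orient="index")
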