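"""Terrain derivation, CART fitting/evaluation and regime mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from sklearn.metrics import roc_auc_score

from firereg import (
    REGIME_LOW,
    REGIME_MIXED,
    Raster,
    RegimeRule,
    apply_rule,
    derive_terrain,
    distance_to_feature,
    evaluate_model,
    fit_cart,
    summarize_area,
)
from firereg.raster import read_ascii_grid, write_ascii_grid


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def plane_fit_gradient_oracle(z, cell, r, c):
    """Least-squares plane through the 3x3 window centered at (r, c)."""
    win = z[r - 1 : r + 2, c - 1 : c + 2]
    ys, xs = np.mgrid[-1:2, -1:2]
    A = np.column_stack([xs.ravel() * cell, ys.ravel() * cell,
                         np.ones(9)])
    coef, *_ = np.linalg.lstsq(A, win.ravel(), rcond=None)
    return coef[0], coef[1]  # dz/dx (east), dz/dy (south)


def gini_best_split_oracle(X, y):
    """Exhaustive weighted-Gini search over all features and midpoints."""
    n = len(y)
    best = (np.inf, None, None)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        for i in range(n - 1):
            if xs[i] == xs[i + 1]:
                continue
            thr = (xs[i] + xs[i + 1]) / 2.0
            left, right = ys[: i + 1], ys[i + 1 :]
            imp = 0.0
            for part in (left, right):
                p = np.mean(part == y[0]) if len(part) else 0.0
                imp += len(part) / n * 2 * p * (1 - p)
            if imp < best[0] - 1e-12:
                best = (imp, j, thr)
    return best


def auc_pair_count_oracle(scores, labels, positive):
    """AUC as the probability a positive outranks a negative (ties = 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Terrain
# ---------------------------------------------------------------------------

def test_flat_surface_has_zero_slope_and_curvature():
    elev = Raster(np.full((6, 6), 2000.0))
    t = derive_terrain(elev)
    assert np.allclose(t["slope_deg"].values, 0.0)
    assert np.allclose(t["curvature"].values, 0.0)


def test_unit_gradient_plane_gives_45_degree_slope():
    # rises 30 m per 30-m cell eastward
    cols = np.arange(8) * 30.0
    elev = Raster(np.tile(cols, (8, 1)), cell_m=30.0)
    t = derive_terrain(elev)
    interior = t["slope_deg"].values[1:-1, 1:-1]
    assert np.allclose(interior, 45.0)
    assert np.allclose(t["curvature"].values[1:-1, 1:-1], 0.0)


def test_horn_gradient_matches_plane_fit_oracle_on_random_planes(rng):
    """On planar surfaces the Horn stencil equals the LSQ plane fit."""
    for _ in range(10):
        a, b, c = rng.uniform(-2, 2, size=3)
        ys, xs = np.mgrid[0:7, 0:7]
        z = a * xs * 30.0 + b * ys * 30.0 + c * 1000.0
        t = derive_terrain(Raster(z, cell_m=30.0))
        slope = t["slope_deg"].values
        for r, cc in [(2, 2), (3, 4), (5, 1)]:
            gx, gy = plane_fit_gradient_oracle(z, 30.0, r, cc)
            expect = np.degrees(np.arctan(np.hypot(gx, gy)))
            assert slope[r, cc] == pytest.approx(expect, abs=1e-6)


def test_nodata_propagates_to_derived_bands():
    z = np.full((5, 5), 2000.0)
    z[2, 2] = np.nan
    t = derive_terrain(Raster(z))
    assert np.isnan(t["slope_deg"].values[2, 2])


# ---------------------------------------------------------------------------
# Feature distance
# ---------------------------------------------------------------------------

def test_distance_orthogonal_and_diagonal_neighbors():
    mask = np.zeros((5, 5), dtype=int)
    mask[2, 2] = 1
    # a single 30-m cell is 0.09 ha -> removed by the 0.1-ha filter
    with pytest.warns(UserWarning, match="minimum-area"):
        gone = distance_to_feature(Raster(mask, cell_m=30.0))
    assert np.all(np.isinf(gone.values))

    mask[2, 3] = 1  # two cells: 0.18 ha, retained
    d = distance_to_feature(Raster(mask, cell_m=30.0))
    assert d.values[2, 2] == 0.0
    assert d.values[1, 2] == pytest.approx(30.0)
    assert d.values[1, 1] == pytest.approx(30.0 * np.sqrt(2))


def test_distance_min_area_uses_8_connectivity():
    mask = np.zeros((6, 6), dtype=int)
    mask[0, 0] = mask[1, 1] = 1  # diagonal pair forms one 0.18-ha patch
    d = distance_to_feature(Raster(mask, cell_m=30.0))
    assert d.values[0, 0] == 0.0


# ---------------------------------------------------------------------------
# CART
# ---------------------------------------------------------------------------

def test_cart_separable_single_covariate():
    x = np.concatenate([np.arange(1, 11), np.arange(11, 21)]).astype(float)
    labels = np.array(["low"] * 10 + ["mixed"] * 10)
    fitted = fit_cart(pd.DataFrame({"x": x}), labels, folds=5, seed=0)
    feat, thr = fitted.root_split
    assert feat == "x"
    assert 10.0 < thr <= 11.0
    assert fitted.pcc == 100.0
    assert fitted.pruned_n_leaves == 2


def test_cart_single_class_errors():
    with pytest.raises(ValueError, match="single class"):
        fit_cart(pd.DataFrame({"x": [1.0, 2.0]}), np.array(["a", "a"]))


def test_cart_constant_covariates_degenerate_stump():
    X = pd.DataFrame({"x": np.ones(20)})
    y = np.array(["a"] * 10 + ["b"] * 10)
    fitted = fit_cart(X, y, folds=5, seed=0)
    assert fitted.root_split is None
    assert fitted.pruned_n_leaves == 1


def test_cart_root_split_equals_exhaustive_gini_oracle(rng):
    """The fitted root equals the globally Gini-optimal threshold."""
    for trial in range(5):
        X = rng.normal(size=(120, 3))
        y = np.where(X[:, 1] + 0.3 * rng.normal(size=120) > 0, "m", "l")
        if len(np.unique(y)) < 2:
            continue
        fitted = fit_cart(
            pd.DataFrame(X, columns=["a", "b", "c"]), y, folds=5, seed=trial
        )
        _, j, thr = gini_best_split_oracle(X, y)
        feat, got_thr = fitted.root_split
        assert feat == ["a", "b", "c"][j]
        # sklearn stores features as float32; thresholds agree to that precision
        assert got_thr == pytest.approx(thr, abs=1e-5)


def test_cart_deterministic_given_seed(rng):
    X = pd.DataFrame({"x": rng.normal(size=60), "y": rng.normal(size=60)})
    labels = np.where(X["x"] > 0, "m", "l")
    a = fit_cart(X, labels, seed=7)
    b = fit_cart(X, labels, seed=7)
    assert a.root_split == b.root_split
    assert a.pcc == b.pcc and a.auc == b.auc


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def test_pcc_of_187_correct_of_232_sites():
    labels = np.array(["low"] * 232)
    pred = np.array(["low"] * 187 + ["mixed"] * 45)
    pcc, _ = evaluate_model(pred, labels)
    assert pcc == pytest.approx(80.6, abs=0.05)


def test_auc_perfect_ranking_and_random_scores(rng):
    labels = np.array([0] * 50 + [1] * 50)
    perfect = np.concatenate([np.arange(50), 100 + np.arange(50)])
    _, auc = evaluate_model(labels, labels, perfect, positive=1)
    assert auc == 1.0
    random_scores = rng.normal(size=5000)
    big_labels = rng.integers(0, 2, size=5000)
    _, auc_rand = evaluate_model(big_labels, big_labels, random_scores,
                                 positive=1)
    assert auc_rand == pytest.approx(0.5, abs=0.05)


def test_auc_equals_pair_count_oracle_with_ties(rng):
    for _ in range(10):
        n = int(rng.integers(8, 30))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        scores = rng.integers(0, 5, size=n).astype(float)  # heavy ties
        _, auc = evaluate_model(labels, labels, scores, positive=1)
        assert auc == pytest.approx(
            auc_pair_count_oracle(scores, labels, 1), abs=1e-12
        )
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_evaluate_model_empty_errors():
    with pytest.raises(ValueError):
        evaluate_model(np.array([]), np.array([]))


# ---------------------------------------------------------------------------
# Rule application and area summary
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "elev, slope, expected",
    [
        (2263.0, 35.0, REGIME_LOW),   # at the elevation threshold: low
        (2300.0, 4.0, REGIME_LOW),    # at the slope threshold: low
        (2300.0, 5.0, REGIME_MIXED),  # fails both clauses
        (2262.9, 0.0, REGIME_LOW),
    ],
)
def test_rule_boundaries(elev, slope, expected):
    e = Raster(np.full((2, 2), elev))
    s = Raster(np.full((2, 2), slope))
    out = apply_rule(e, s)
    assert np.all(out.values == expected)


def test_apply_rule_pointwise_and_idempotent(rng):
    e = Raster(rng.uniform(1800, 3000, size=(10, 10)))
    s = Raster(rng.uniform(0, 45, size=(10, 10)))
    full = apply_rule(e, s)
    # pointwise: any single cell viewed alone gives the same answer
    r, c = 4, 7
    single = apply_rule(
        Raster(e.values[r : r + 1, c : c + 1]),
        Raster(s.values[r : r + 1, c : c + 1]),
    )
    assert single.values[0, 0] == full.values[r, c]


def test_apply_rule_misaligned_errors():
    with pytest.raises(ValueError, match="misaligned"):
        apply_rule(Raster(np.zeros((3, 3))), Raster(np.zeros((4, 4))))


def test_summarize_area_counts_hectares_percentages():
    regime = Raster(np.array([[REGIME_LOW, REGIME_LOW],
                              [REGIME_LOW, REGIME_MIXED]]), cell_m=30.0)
    table = summarize_area(regime)
    row = table.loc["overall"]
    assert row["pct_low"] == 75.0
    assert row["ha_low"] == pytest.approx(0.27)
    assert row["pct_low"] + row["pct_mixed"] == pytest.approx(100.0, abs=0.1)


def test_summarize_area_invariant_to_cell_permutation(rng):
    vals = rng.choice([REGIME_LOW, REGIME_MIXED], size=36)
    a = summarize_area(Raster(vals.reshape(6, 6)))
    b = summarize_area(Raster(rng.permutation(vals).reshape(6, 6)))
    pd.testing.assert_frame_equal(a, b)


def test_summarize_area_all_nodata_warns_empty():
    regime = Raster(np.full((3, 3), -9999), nodata=-9999)
    with pytest.warns(UserWarning, match="all-nodata"):
        table = summarize_area(regime)
    assert table.empty


def test_summarize_area_by_cover_type():
    regime = Raster(np.array([[REGIME_LOW, REGIME_LOW],
                              [REGIME_MIXED, REGIME_MIXED]]))
    cover = Raster(np.array([[7, 8], [7, 8]]), nodata=-9999)
    table = summarize_area(regime, cover)
    assert table.loc["7", "pct_low"] == 50.0
    assert table.loc["overall", "n_low"] == 2


# ---------------------------------------------------------------------------
# ASCII grid round trip
# ---------------------------------------------------------------------------

def test_ascii_grid_round_trip(tmp_path, rng):
    vals = rng.uniform(1800, 3000, size=(5, 7))
    vals[0, 0] = np.nan
    r = Raster(vals, cell_m=30.0, xll=100.0, yll=200.0)
    p = tmp_path / "g.asc"
    write_ascii_grid(r, p, fmt="%.3f")
    back = read_ascii_grid(p)
    assert back.cell_m == 30.0 and back.xll == 100.0
    assert np.isnan(back.values[0, 0])
    ok = ~np.isnan(vals)
    assert np.allclose(back.values[ok], vals[ok], atol=1e-3)
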