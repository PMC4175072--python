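"""Comparison of the historical regime map with observed and modeled fire.

Observed severity comes as MTBS thematic classes (1 unburned/low, 2 low,
3 moderate, 4 high) per fire perimeter; classes {1,2} correspond to the
historical low-severity regime and {3,4} to mixed severity. Per fire, a
two-cell chi-square goodness-of-fit tests the observed low-severity pixel
count against the expectation under the historical map; the test is
invalid when either expected count is zero (as happens for a perimeter
mapped entirely as one historical regime).

Modeled fire behavior comes as a crown-activity class (surface vs
torch/crown) and fireline intensity (kW/m). The four-way crossmap of
historical regime x behavior partitions the landscape into
little-change/shifted categories; behavior realism is verified at random
points against observed severity with Kruskal-Wallis tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .raster import CELL_AREA_HA, Raster, require_aligned
from .landscape import REGIME_LOW, REGIME_MIXED

__all__ = [
    "MTBS_CLASSES",
    "INTENSITY_MODERATE_KWM",
    "INTENSITY_HIGH_KWM",
    "FireComparison",
    "binarize_observed",
    "compare_fire",
    "fire_severity_proportions",
    "classify_behavior",
    "crossmap",
    "verify_behavior",
]

MTBS_CLASSES = {1: "unburned_low", 2: "low", 3: "moderate", 4: "high"}

# Approximate median fireline intensities of moderate and high severity
# fire across the verification fires.
INTENSITY_MODERATE_KWM = 33_000.0
INTENSITY_HIGH_KWM = 40_000.0

SURFACE, CROWN_OR_TORCH = 1, 2


@dataclass(frozen=True)
class FireComparison:
    """Observed-vs-historical low-severity comparison for one fire."""

    fire_id: str
    n_pixels: int
    observed_low_pct: float
    expected_low_pct: float
    chi2: float
    df: int
    p: float
    valid: bool


def binarize_observed(observed: Raster) -> Raster:
    """Collapse MTBS classes 1-4 to the binary low/mixed regime scale.

    Classes {1,2} -> low, {3,4} -> mixed; any other value (e.g. post-fire
    regrowth codes) becomes nodata. Idempotent on its own output because
    the regime codes 1 and 2 are themselves MTBS classes 1 and 2.
    """
    vals = np.asarray(observed.values)
    out = np.full(vals.shape, -9999, dtype=int)
    out[np.isin(vals, (1, 2))] = REGIME_LOW
    out[np.isin(vals, (3, 4))] = REGIME_MIXED
    return observed.like(out, nodata=-9999)


def compare_fire(
    observed: Raster,
    historical: Raster,
    perimeter: Raster | None = None,
    fire_id: str = "",
    continuity_correction: bool = False,
) -> FireComparison:
    """Two-cell chi-square of observed vs historically expected low severity.

    Within the perimeter (and the historical map's extent), O_low counts
    observed low-severity pixels and E_low = N * p_hist_low; then
    chi2 = sum (O-E)^2/E over the two cells with df = 1. The test is
    flagged invalid whenever an expected count is zero.
    """
    require_aligned(observed, historical)
    binary = binarize_observed(observed)
    sel = binary.mask & historical.mask
    if perimeter is not None:
        require_aligned(observed, perimeter)
        sel &= np.asarray(perimeter.values).astype(bool)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("no classified pixels inside the perimeter")
    obs = np.asarray(binary.values)[sel]
    hist = np.asarray(historical.values)[sel]
    o_low = int(np.count_nonzero(obs == REGIME_LOW))
    p_low = float(np.count_nonzero(hist == REGIME_LOW)) / n
    e_low, e_mixed = n * p_low, n * (1.0 - p_low)
    valid = e_low > 0 and e_mixed > 0
    if valid:
        terms = []
        for o, e in ((o_low, e_low), (n - o_low, e_mixed)):
            d = abs(o - e) - (0.5 if continuity_correction else 0.0)
            terms.append(max(d, 0.0) ** 2 / e)
        chi2 = float(sum(terms))
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = float("nan"), float("nan")
    return FireComparison(
        fire_id=fire_id,
        n_pixels=n,
        observed_low_pct=100.0 * o_low / n,
        expected_low_pct=100.0 * p_low,
        chi2=chi2,
        df=1,
        p=p,
        valid=valid,
    )


def fire_severity_proportions(
    observed: Raster, perimeter: Raster | None = None
) -> pd.DataFrame:
    """Per-MTBS-class pixel counts, hectares and percentages for one fire."""
    sel = np.isin(np.asarray(observed.values), list(MTBS_CLASSES))
    if perimeter is not None:
        require_aligned(observed, perimeter)
        sel &= np.asarray(perimeter.values).astype(bool)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("no classified pixels inside the perimeter")
    vals = np.asarray(observed.values)[sel]
    cell_ha = CELL_AREA_HA(observed.cell_m)
    rows = {}
    for cls, name in MTBS_CLASSES.items():
        count = int(np.count_nonzero(vals == cls))
        rows[name] = {
            "mtbs_class": cls,
            "n_pixels": count,
            "area_ha": count * cell_ha,
            "pct": 100.0 * count / n,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def classify_behavior(
    crown_class: Raster | None = None,
    intensity: Raster | None = None,
    moderate_kwm: float = INTENSITY_MODERATE_KWM,
    high_kwm: float = INTENSITY_HIGH_KWM,
) -> Raster:
    """Collapse modeled behavior to the binary surface vs crown/torch scale.

    With a crown-activity band, surface -> 1 and torch/crown -> 2. In
    intensity-only mode, cells below ``moderate_kwm`` are the surface
    equivalent; values above are the moderate band, and above ``high_kwm``
    the high band (codes 2 and 3).
    """
    if crown_class is not None:
        vals = np.asarray(crown_class.values)
        out = np.where(vals == SURFACE, SURFACE, CROWN_OR_TORCH).astype(int)
        out[~crown_class.mask] = -9999
        return crown_class.like(out, nodata=-9999)
    if intensity is None:
        raise ValueError("either crown_class or intensity is required")
    vals = np.asarray(intensity.values, dtype=float)
    out = np.full(vals.shape, SURFACE, dtype=int)
    out[vals >= moderate_kwm] = 2
    out[vals > high_kwm] = 3
    out[~intensity.mask] = -9999
    return intensity.like(out, nodata=-9999)


def crossmap(
    historical: Raster,
    behavior: Raster,
    intensity: Raster | None = None,
) -> pd.DataFrame:
    """Four-way partition of historical regime x modeled behavior.

    Categories (low->surface, low->crown/torch, mixed->surface,
    mixed->crown/torch) partition the jointly classified area; percentages
    sum to 100. Mean fireline intensity per category is included when an
    intensity band is supplied.
    """
    require_aligned(historical, behavior)
    if intensity is not None:
        require_aligned(historical, intensity)
    sel = historical.mask & behavior.mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError("no jointly classified cells")
    hist = np.asarray(historical.values)[sel]
    behav = np.asarray(behavior.values)[sel]
    inten = np.asarray(intensity.values, dtype=float)[sel] if intensity is not None else None
    cell_ha = CELL_AREA_HA(historical.cell_m)
    rows = {}
    for (hcode, hname) in ((REGIME_LOW, "low"), (REGIME_MIXED, "mixed")):
        for (bcode, bname) in ((SURFACE, "surface"), (CROWN_OR_TORCH, "crown_or_torch")):
            m = (hist == hcode) & (behav == bcode)
            count = int(m.sum())
            rows[f"{hname}->{bname}"] = {
                "n_pixels": count,
                "area_ha": count * cell_ha,
                "pct": 100.0 * count / n,
                "mean_intensity_kwm": (
                    float(np.mean(inten[m])) if inten is not None and count else float("nan")
                ),
            }
    return pd.DataFrame.from_dict(rows, orient="index")


def verify_behavior(
    observed: Raster,
    intensity: Raster,
    crown_class: Raster,
    perimeter: Raster | None = None,
    n_points: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """Check that modeled behavior tracks observed severity at random points.

    Samples ``n_points`` cells uniformly without replacement from the
    classified perimeter area, then per MTBS class reports the median
    fireline intensity and percentage of crown/torch cells, plus a
    tie-corrected Kruskal-Wallis test of intensity across classes
    (chi-square approximation, df = k-1). Deterministic given ``seed``.

    Returns ``(per_class_table, H, p)``; H and p are NaN when fewer than
    two classes are present.
    """
    require_aligned(observed, intensity)
    require_aligned(observed, crown_class)
    sel = np.isin(np.asarray(observed.values), list(MTBS_CLASSES))
    sel &= intensity.mask & crown_class.mask
    if perimeter is not None:
        require_aligned(observed, perimeter)
        sel &= np.asarray(perimeter.values).astype(bool)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise ValueError("no classified cells to sample")
    rng = np.random.default_rng(seed)
    take = rng.choice(idx, size=min(n_points, idx.size), replace=False)

    obs = np.asarray(observed.values).ravel()[take]
    inten = np.asarray(intensity.values, dtype=float).ravel()[take]
    crown = np.asarray(crown_class.values).ravel()[take]
    rows, groups = {}, []
    for cls, name in MTBS_CLASSES.items():
        m = obs == cls
        if not m.any():
            continue
        rows[name] = {
            "mtbs_class": cls,
            "n_points": int(m.sum()),
            "median_intensity_kwm": float(np.median(inten[m])),
            "pct_crown": 100.0 * float(np.mean(crown[m] == CROWN_OR_TORCH)),
        }
        groups.append(inten[m])
    table = pd.DataFrame.from_dict(rows, orient="index")
    if len(groups) < 2:
        return table, float("nan"), float("nan")
    if np.ptp(np.concatenate(groups)) == 0:
        # all values identical: no variation to test
        return table, 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return table, float(h), float(p)
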