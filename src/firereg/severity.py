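"""Site-level fire-severity reconstruction from scars and age structure.

The reconstruction proceeds per site:

1. *Spreading fires* — calendar years in which at least ``min_trees``
   (default 2) distinct trees were scarred.
2. *Severity calls* — each spreading fire is classified from two stand
   metrics, both percentages of all retained dated trees at the site:
   the remnant percentage (trees predating the fire, i.e. survivors) and
   the establishment percentage (trees establishing within 40 years after
   the fire). A fire is **low** severity when >=80% remnant and <=20%
   establishment, **high** when <20% remnant and >80% establishment, and
   **moderate** otherwise. Fires with no establishment within the window
   are excluded (no structural evidence the site burned).
3. *Sequence exclusion* — calls that precede a site's first moderate/high
   fire and lack an establishment pulse (>20%) are excluded: survivorship
   evidence for fires predating a stand-replacing event is unreliable.
4. *Site regime* — a site is ``low_only`` when fires were frequent (mean
   fire interval < 30 yr) and every retained call is low; otherwise it is
   mixed, split into ``mixed_with_high`` / ``mixed_no_high``.

Historical analyses use fires before a fire-exclusion cutoff
(default 1920).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FireScarRecord, TreeRecord

__all__ = [
    "DEFAULT_CUTOFF_YEAR",
    "DEFAULT_WINDOW_YR",
    "DEFAULT_MIN_TREES",
    "DEFAULT_PULSE_THRESHOLD",
    "MFI_FREQUENT_YR",
    "SpreadingFire",
    "FireSeverityCall",
    "SiteRegime",
    "find_spreading_fires",
    "recorder_sites_by_year",
    "widespread_fire_years",
    "mean_fire_interval",
    "classify_severity",
    "classify_fire",
    "apply_sequence_exclusions",
    "classify_site_regime",
    "reconstruct_site",
    "establishment_histogram",
]

DEFAULT_CUTOFF_YEAR = 1920   # ca. effective fire exclusion
DEFAULT_WINDOW_YR = 40       # post-fire establishment window
DEFAULT_MIN_TREES = 2        # scarred trees needed for a spreading fire
DEFAULT_PULSE_THRESHOLD = 20.0   # % establishment defining a pulse
MFI_FREQUENT_YR = 30.0       # MFI below this counts as frequent fire


@dataclass(frozen=True)
class SpreadingFire:
    """A fire year evidenced by scars on >= 2 trees at one site."""

    site_id: str
    year: int
    n_trees_scarred: int


@dataclass(frozen=True)
class FireSeverityCall:
    site_id: str
    year: int
    pct_remnant: float
    pct_establish: float
    severity: str                      # {low, moderate, high, excluded}
    exclusion_reason: str | None = None


@dataclass(frozen=True)
class SiteRegime:
    site_id: str
    regime: str                        # {low_only, mixed_no_high, mixed_with_high}
    mfi_yr: float | None
    n_spreading_fires: int


# ---------------------------------------------------------------------------
# Spreading fires and composite chronology
# ---------------------------------------------------------------------------

def find_spreading_fires(
    scars: Sequence[FireScarRecord],
    min_trees: int = DEFAULT_MIN_TREES,
    merge_window: int = 0,
) -> list[SpreadingFire]:
    """Identify fire years scarred on at least ``min_trees`` distinct trees.

    Ambiguous year ranges (1859-60 style) count toward the start year.
    With ``merge_window=1``, dormant-season or ambiguous scars in adjacent
    years are merged into one event dated to the earlier year — dormant
    scars sit on a ring boundary, so the calendar year is uncertain by one.
    """
    if min_trees < 1:
        raise ValueError("min_trees must be >= 1")
    if not scars:
        return []
    site_ids = {s.site_id for s in scars}
    if len(site_ids) > 1:
        raise ValueError(f"scars span multiple sites: {sorted(site_ids)}")
    site_id = site_ids.pop()

    by_year: dict[int, set[str]] = {}
    mergeable: dict[int, bool] = {}
    for s in scars:
        y = s.scar_year_start
        by_year.setdefault(y, set()).add(s.tree_id)
        mergeable[y] = mergeable.get(y, False) or s.season == "dormant" or s.ambiguous

    years = sorted(by_year)
    groups: list[list[int]] = []
    for y in years:
        if (
            merge_window > 0
            and groups
            and y - groups[-1][-1] <= merge_window
            and (mergeable.get(groups[-1][-1], False) or mergeable.get(y, False))
        ):
            groups[-1].append(y)
        else:
            groups.append([y])

    fires = []
    for grp in groups:
        trees: set[str] = set()
        for y in grp:
            trees |= by_year[y]
        if len(trees) >= min_trees:
            fires.append(SpreadingFire(site_id, grp[0], len(trees)))
    return fires


def recorder_sites_by_year(
    scars_by_site: Mapping[str, Sequence[FireScarRecord]],
    min_trees: int = DEFAULT_MIN_TREES,
    merge_window: int = 0,
) -> pd.DataFrame:
    """Composite chronology: per-year counts of recorder and recording sites.

    A tree records from its first scar year onward; a site is a *recorder*
    in years when at least ``min_trees`` of its trees are recording, and is
    *recording* in its spreading-fire years. Returns a DataFrame indexed by
    year with columns ``n_recorder_sites``, ``n_sites_recording`` and
    ``pct_recording`` (NaN where no site could record).
    """
    first_scar: dict[str, dict[str, int]] = {}
    fire_years: dict[str, set[int]] = {}
    last_year = None
    for site_id, scars in scars_by_site.items():
        firsts: dict[str, int] = {}
        for s in scars:
            firsts[s.tree_id] = min(
                firsts.get(s.tree_id, s.scar_year_start), s.scar_year_start
            )
            last_year = (
                s.scar_year_start if last_year is None
                else max(last_year, s.scar_year_start)
            )
        first_scar[site_id] = firsts
        fire_years[site_id] = {
            f.year for f in find_spreading_fires(scars, min_trees, merge_window)
        }
    if last_year is None:
        return pd.DataFrame(
            columns=["n_recorder_sites", "n_sites_recording", "pct_recording"]
        )

    first_year = min(
        min(f.values()) for f in first_scar.values() if f
    )
    index = pd.RangeIndex(first_year, last_year + 1, name="year")
    n_recorder = pd.Series(0, index=index)
    n_recording = pd.Series(0, index=index)
    for site_id, firsts in first_scar.items():
        if not firsts:
            continue
        starts = np.sort(np.fromiter(firsts.values(), dtype=int))
        if len(starts) >= min_trees:
            # year from which >= min_trees trees are recording
            site_start = int(starts[min_trees - 1])
            n_recorder.loc[site_start:] += 1
        for y in fire_years[site_id]:
            if y in index:
                n_recording.loc[y] += 1
    pct = 100.0 * n_recording / n_recorder.replace(0, np.nan)
    return pd.DataFrame(
        {
            "n_recorder_sites": n_recorder,
            "n_sites_recording": n_recording,
            "pct_recording": pct,
        }
    )


def widespread_fire_years(
    chronology: pd.DataFrame, min_sites: int = 4
) -> list[int]:
    """Years in which at least ``min_sites`` sites recorded a spreading fire."""
    if chronology.empty:
        return []
    mask = chronology["n_sites_recording"] >= min_sites
    return [int(y) for y in chronology.index[mask]]


def mean_fire_interval(years: Iterable[int]) -> float | None:
    """Mean interval between successive fire years; None if < 2 fires."""
    ys = sorted(set(years))
    if len(ys) < 2:
        return None
    return float(np.mean(np.diff(ys)))


# ---------------------------------------------------------------------------
# Per-fire severity
# ---------------------------------------------------------------------------

def classify_severity(
    pct_remnant: float, pct_establish: float
) -> tuple[str, str | None]:
    """Map the two stand metrics to a severity class.

    Returns ``(severity, exclusion_reason)``. Precedence: the
    no-establishment exclusion first, then high, then low, with moderate as
    the residual class. Boundaries are inclusive for low (>=80% remnant,
    <=20% establishment) and exclusive for high (<20%, >80%).
    """
    for pct in (pct_remnant, pct_establish):
        if not 0.0 <= pct <= 100.0:
            raise ValueError(f"percentage {pct} outside [0, 100]")
    if pct_establish == 0.0:
        return "excluded", "no_establishment_40yr"
    if pct_remnant < 20.0 and pct_establish > 80.0:
        return "high", None
    if pct_remnant >= 80.0 and pct_establish <= 20.0:
        return "low", None
    return "moderate", None


def classify_fire(
    trees: Sequence[TreeRecord],
    fire_year: int,
    window: int = DEFAULT_WINDOW_YR,
) -> FireSeverityCall:
    """Classify one spreading fire from the site's dated-tree age structure.

    Both percentages use the same denominator: every retained
    (non-excluded) dated tree at the site, so they are comparable across
    that site's fires.
    """
    retained = [
        t for t in trees
        if not t.excluded and t.establishment_year is not None
    ]
    if not retained:
        raise ValueError("no retained dated trees at site")
    site_id = retained[0].site_id
    est = np.array([t.establishment_year for t in retained])
    n = len(est)
    pct_remnant = 100.0 * np.count_nonzero(est < fire_year) / n
    pct_establish = (
        100.0 * np.count_nonzero((est > fire_year) & (est <= fire_year + window)) / n
    )
    severity, reason = classify_severity(pct_remnant, pct_establish)
    return FireSeverityCall(
        site_id, fire_year, pct_remnant, pct_establish, severity, reason
    )


def apply_sequence_exclusions(
    calls: Sequence[FireSeverityCall],
    pulse_threshold: float = DEFAULT_PULSE_THRESHOLD,
) -> list[FireSeverityCall]:
    """Exclude pulse-less calls preceding the first moderate/high fire.

    Survivorship evidence for fires older than a subsequent stand-altering
    fire is unreliable; such calls are retained only when backed by an
    establishment pulse (> ``pulse_threshold`` % of trees).
    """
    calls = sorted(calls, key=lambda c: c.year)
    first_mixed = next(
        (c.year for c in calls if c.severity in {"moderate", "high"}), None
    )
    if first_mixed is None:
        return list(calls)
    out = []
    for c in calls:
        if (
            c.year < first_mixed
            and c.severity not in {"excluded"}
            and c.pct_establish <= pulse_threshold
        ):
            out.append(
                FireSeverityCall(
                    c.site_id, c.year, c.pct_remnant, c.pct_establish,
                    "excluded", "pre_mixed_no_pulse",
                )
            )
        else:
            out.append(c)
    return out


def classify_site_regime(
    calls: Sequence[FireSeverityCall],
    mfi: float | None,
    mfi_frequent: float = MFI_FREQUENT_YR,
) -> SiteRegime:
    """Assign the site's predominant historical fire regime.

    ``low_only`` requires both frequent fire (MFI < 30 yr) and an absence
    of moderate/high calls; any retained high call makes the site
    ``mixed_with_high``; everything else is ``mixed_no_high``.
    """
    retained = [c for c in calls if c.severity != "excluded"]
    if not retained:
        raise ValueError("site unclassifiable: no retained severity calls")
    site_id = retained[0].site_id
    n_fires = len({c.year for c in calls})
    severities = {c.severity for c in retained}
    if severities == {"low"} and mfi is not None and mfi < mfi_frequent:
        regime = "low_only"
    elif "high" in severities:
        regime = "mixed_with_high"
    else:
        regime = "mixed_no_high"
    return SiteRegime(site_id, regime, mfi, n_fires)


def reconstruct_site(
    trees: Sequence[TreeRecord],
    scars: Sequence[FireScarRecord],
    cutoff_year: int = DEFAULT_CUTOFF_YEAR,
    window: int = DEFAULT_WINDOW_YR,
    min_trees: int = DEFAULT_MIN_TREES,
    merge_window: int = 0,
    pulse_threshold: float = DEFAULT_PULSE_THRESHOLD,
) -> tuple[list[FireSeverityCall], SiteRegime]:
    """Run the full per-site reconstruction: fires -> calls -> regime.

    Only spreading fires before ``cutoff_year`` (pre fire exclusion) enter
    the historical classification.
    """
    fires = [
        f for f in find_spreading_fires(scars, min_trees, merge_window)
        if f.year < cutoff_year
    ]
    calls = [classify_fire(trees, f.year, window) for f in fires]
    calls = apply_sequence_exclusions(calls, pulse_threshold)
    mfi = mean_fire_interval([f.year for f in fires])
    regime = classify_site_regime(calls, mfi)
    return calls, regime


# ---------------------------------------------------------------------------
# Age-structure summaries
# ---------------------------------------------------------------------------

def establishment_histogram(
    trees: Sequence[TreeRecord],
    groups: Mapping[str, str] | None = None,
    bin_yr: int = 20,
    origin_year: int = 1500,
) -> pd.DataFrame:
    """Proportions of tree establishment dates in fixed-width year bins.

    ``groups`` maps site_id -> group label (e.g. regime); ungrouped trees
    fall into ``"all"``. Within each group the proportions sum to 1.
    Bins are [origin, origin+bin), labelled by their left edge.
    """
    rows = []
    for t in trees:
        if t.excluded or t.establishment_year is None:
            continue
        label = groups.get(t.site_id, None) if groups is not None else "all"
        if label is None:
            continue
        left = origin_year + bin_yr * ((t.establishment_year - origin_year) // bin_yr)
        rows.append((label, left))
    if not rows:
        warnings.warn("no dated trees to histogram", stacklevel=2)
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["group", "bin_start"])
    counts = df.groupby(["group", "bin_start"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)
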