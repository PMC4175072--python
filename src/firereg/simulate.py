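"""Synthetic fire-history and landscape data with known ground truth.

No field or GIS data ship with this package, so every pipeline stage is
exercised against simulated datasets whose generating regime is known:

* ``simulate_site_history`` — a stochastic stand history under a stated
  fire regime: a Weibull renewal process of fire years, per-fire severity
  and canopy mortality, surface-fire mortality of juveniles, post-fire
  establishment pulses after moderate/high fire, background recruitment
  and mortality, fire scars on survivors, and a field-style sample of the
  2012 stand (the oldest survivors are always cored).
* ``simulate_landscape`` — a smooth elevation field with slope, regime
  labels from the elevation/slope rule plus label noise, and sampled site
  locations.
* ``simulate_observed_fire`` — an MTBS-style class raster whose binary
  severity matches the historical regime with a set concordance.
* ``simulate_behavior`` — crown-activity and lognormal fireline-intensity
  rasters anchored to surface/crown mean intensities.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import FireScarRecord, TreeRecord
from .landscape import REGIME_LOW, REGIME_MIXED, RegimeRule, derive_terrain
from .comparison import CROWN_OR_TORCH, SURFACE
from .raster import Raster

__all__ = [
    "RegimeParams",
    "LandscapeParams",
    "simulate_site_history",
    "simulate_landscape",
    "simulate_observed_fire",
    "simulate_behavior",
]


@dataclass
class RegimeParams:
    """Generating parameters of one site's fire regime.

    The defaults encode the two regime archetypes: ``low_only`` sites burn
    frequently (mean interval < 30 yr) at low severity only; ``mixed``
    sites burn less often (default 45 yr) with a mixture of low, moderate
    and high severities. Canopy mortality fractions per severity follow
    the severity definitions (low kills almost no canopy trees, high kills
    nearly all); surface fires of any severity kill most juveniles, which
    is what keeps frequently burned stands open and old.
    """

    regime: str = "low_only"                 # {low_only, mixed}
    mean_interval_yr: float = 15.0
    weibull_shape: float = 2.0
    scar_prob: float = 0.5
    severity_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # low/mod/high
    mortality_low: tuple[float, float] = (0.0, 0.1)
    mortality_moderate: tuple[float, float] = (0.25, 0.75)
    mortality_high: tuple[float, float] = (0.85, 1.0)
    juvenile_kill_prob: float = 0.9
    juvenile_age_yr: int = 20
    background_establish_rate: float = 0.2   # canopy-candidate recruits / yr
    background_hazard: float = 0.003         # per-tree annual mortality
    init_cohort: int = 2000                  # canopy trees predating the span
    pulse_size: float = 200.0                # mean cohort after mod/high fire
    pulse_decay_yr: float = 10.0             # exp decay of cohort timing
    pulse_max_lag_yr: int = 30
    sim_span: tuple[int, int] = (1500, 2012)
    fire_exclusion_year: int | None = 1920   # fires cease here (suppression era)
    sampling_year: int = 2012
    n_sampled_trees: int = 50
    n_oldest_cored: int = 5
    snag_persistence_yr: int = 200           # dead scarred wood stays sampleable

    def __post_init__(self) -> None:
        if self.regime not in {"low_only", "mixed"}:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.mean_interval_yr <= 0:
            raise ValueError("mean_interval_yr must be positive")
        if not math.isclose(sum(self.severity_mix), 1.0, abs_tol=1e-9):
            raise ValueError("severity_mix must sum to 1")
        if not 0.0 <= self.scar_prob <= 1.0:
            raise ValueError("scar_prob must be in [0, 1]")

    @classmethod
    def mixed(cls, **kwargs) -> "RegimeParams":
        kwargs.setdefault("mean_interval_yr", 45.0)
        return cls(regime="mixed", **kwargs)


def _draw_fire_years(params: RegimeParams, rng: np.random.Generator) -> list[int]:
    """Weibull renewal process of fire years up to the fire-exclusion era.

    Fires run from the span start until ``fire_exclusion_year`` (or the
    span end if exclusion is disabled), emulating the historical record:
    a centuries-long fire regime truncated by 20th-century suppression,
    followed by a fire-free recruitment era up to the sampling year.
    """
    k = params.weibull_shape
    scale = params.mean_interval_yr / math.gamma(1.0 + 1.0 / k)
    stop = params.sim_span[1]
    if params.fire_exclusion_year is not None:
        stop = min(stop, params.fire_exclusion_year)
    t = float(params.sim_span[0])
    years = []
    while True:
        t += max(1.0, scale * rng.weibull(k))
        if t >= stop:
            break
        years.append(int(round(t)))
    return sorted(set(years))


def simulate_site_history(
    params: RegimeParams, seed: int, site_id: str = "S1"
) -> tuple[list[TreeRecord], list[FireScarRecord], str]:
    """Simulate one site's stand and fire-scar history.

    Returns establishment-corrected tree records for the sampled trees,
    the fire scars observable on those trees, and the generating regime
    label (``"low_only"`` or ``"mixed"``). Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    span0, span1 = params.sim_span
    fire_years = _draw_fire_years(params, rng)

    # Establishment years: an old initial cohort plus background recruits.
    est = list(rng.integers(span0 - 100, span0, size=params.init_cohort))
    n_bg = rng.poisson(params.background_establish_rate * (span1 - span0))
    est.extend(rng.integers(span0, span1, size=n_bg))
    est = np.array(sorted(int(e) for e in est))
    # Background mortality: geometric lifetime after establishment.
    death = est + rng.geometric(params.background_hazard, size=est.size)

    mort_range = {
        "low": params.mortality_low,
        "moderate": params.mortality_moderate,
        "high": params.mortality_high,
    }
    sev_labels = ("low", "moderate", "high")
    scars: list[tuple[int, int]] = []   # (tree index, year)

    for fy in fire_years:
        if params.regime == "low_only":
            severity = "low"
        else:
            severity = sev_labels[rng.choice(3, p=params.severity_mix)]
        alive = (est < fy) & (death > fy)
        idx = np.flatnonzero(alive)
        if idx.size:
            lo, hi = mort_range[severity]
            frac = rng.uniform(lo, hi)
            kill = rng.random(idx.size) < frac
            # Surface fire kills juveniles regardless of canopy severity.
            juvenile = (fy - est[idx]) < params.juvenile_age_yr
            kill |= juvenile & (rng.random(idx.size) < params.juvenile_kill_prob)
            death[idx[kill]] = fy
            survivors = idx[~kill]
            adults = survivors[(fy - est[survivors]) >= params.juvenile_age_yr]
            scarred = adults[rng.random(adults.size) < params.scar_prob]
            scars.extend((int(i), fy) for i in scarred)
        if severity in {"moderate", "high"}:
            n_pulse = rng.poisson(params.pulse_size)
            lags = np.minimum(
                1 + rng.exponential(params.pulse_decay_yr, size=n_pulse),
                params.pulse_max_lag_yr,
            ).astype(int)
            new_est = np.minimum(fy + lags, span1)
            new_death = new_est + rng.geometric(
                params.background_hazard, size=n_pulse
            )
            est = np.concatenate([est, new_est])
            death = np.concatenate([death, new_death])

    # Field sample at sampling_year, mirroring the two-part protocol:
    # (1) an age-structure transect of live survivors old enough to core
    # (age >= 20 yr, the ~4 cm dbh proxy), always including the oldest
    # trees; (2) a systematic collection of every fire-scarred tree whose
    # wood is still sampleable -- alive, or dead recently enough that the
    # snag/stump persists.
    sy = params.sampling_year
    candidates = np.flatnonzero((death > sy) & (est <= sy - params.juvenile_age_yr))
    if candidates.size == 0:
        raise RuntimeError(
            "stand extinction: no survivors to sample; lengthen intervals or "
            "lower mortality"
        )
    by_age = candidates[np.argsort(est[candidates], kind="stable")]
    oldest = by_age[: params.n_oldest_cored]
    rest = by_age[params.n_oldest_cored :]
    n_more = max(0, params.n_sampled_trees - oldest.size)
    extra = (
        rng.choice(rest, size=min(n_more, rest.size), replace=False)
        if rest.size else np.array([], dtype=int)
    )
    live_sample = set(int(i) for i in np.concatenate([oldest, extra]))

    carrier_ids = {i for i, _ in scars}
    sampleable_dead = {
        i for i in carrier_ids
        if death[i] <= sy and death[i] >= sy - params.snag_persistence_yr
    }
    sampleable_live = {i for i in carrier_ids if death[i] > sy}
    sampled = sorted(live_sample | sampleable_dead | sampleable_live)

    trees = []
    tree_id_of = {}
    for k, i in enumerate(sampled):
        tid = f"{site_id}-T{k + 1:03d}"
        tree_id_of[i] = tid
        trees.append(
            TreeRecord(
                site_id=site_id,
                tree_id=tid,
                species="PIPO",
                inner_ring_year=int(est[i]),
                establishment_year=int(est[i]),
                status="live" if death[i] > sy else "dead",
                dbh_cm=10.0,
            )
        )
    scar_records = sorted(
        (
            FireScarRecord(site_id=site_id, tree_id=tree_id_of[i],
                           scar_year_start=y)
            for i, y in scars
            if i in tree_id_of
        ),
        key=lambda s: (s.tree_id, s.scar_year_start),
    )
    return trees, scar_records, params.regime


@dataclass
class LandscapeParams:
    """Parameters of the synthetic covariate landscape."""

    shape: tuple[int, int] = (150, 150)
    cell_m: float = 30.0
    elev_range_m: tuple[float, float] = (1800.0, 3000.0)
    smooth_sigma: float = 6.0
    rule: RegimeRule = field(default_factory=RegimeRule)
    label_noise: float = 0.05
    n_sites: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.n_sites > self.shape[0] * self.shape[1]:
            raise ValueError("n_sites exceeds the number of grid cells")


def simulate_landscape(
    params: LandscapeParams, seed: int
) -> tuple[dict[str, Raster], Raster, pd.DataFrame]:
    """Generate a covariate grid, true regime raster and labeled site table.

    Elevation is a Gaussian-smoothed random field rescaled to the montane
    band (1800-3000 m); slope is derived from it; the regime raster
    applies the elevation/slope rule exactly, and the site table's labels
    flip with probability ``label_noise`` at the sampled cells only.
    """
    rng = np.random.default_rng(seed)
    rough = rng.normal(size=params.shape)
    smooth = ndimage.gaussian_filter(rough, params.smooth_sigma)
    lo, hi = params.elev_range_m
    smin, smax = smooth.min(), smooth.max()
    elev_vals = lo + (smooth - smin) / (smax - smin) * (hi - lo)
    elevation = Raster(elev_vals, cell_m=params.cell_m)
    terrain = derive_terrain(elevation)
    slope = terrain["slope_deg"]

    low = params.rule.predict_low(elevation.values, slope.values)
    regime = elevation.like(
        np.where(low, REGIME_LOW, REGIME_MIXED).astype(int), nodata=-9999
    )

    cells = rng.choice(
        params.shape[0] * params.shape[1], size=params.n_sites, replace=False
    )
    rows, cols = np.unravel_index(cells, params.shape)
    true_low = low[rows, cols]
    flip = rng.random(params.n_sites) < params.label_noise
    label_low = true_low ^ flip
    sites = pd.DataFrame(
        {
            "site_id": [f"L{k + 1:04d}" for k in range(params.n_sites)],
            "row": rows,
            "col": cols,
            "elevation_m": elevation.values[rows, cols],
            "slope_deg": slope.values[rows, cols],
            "aspect_sin": terrain["aspect_sin"].values[rows, cols],
            "aspect_arcsine": terrain["aspect_arcsine"].values[rows, cols],
            "curvature": terrain["curvature"].values[rows, cols],
            "true_regime": np.where(true_low, "low", "mixed"),
            "regime": np.where(label_low, "low", "mixed"),
        }
    )
    covariates = {"elevation_m": elevation, **terrain}
    return covariates, regime, sites


def simulate_observed_fire(
    regime: Raster,
    perimeter: Raster,
    concordance: float = 0.8,
    seed: int = 0,
) -> Raster:
    """MTBS-style class raster matching the historical regime stochastically.

    Each perimeter cell's binary severity equals the historical regime
    with probability ``concordance``; the thematic class within the binary
    outcome is drawn uniformly ({1,2} for low, {3,4} for mixed). Cells
    outside the perimeter are nodata.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must be in [0, 1]")
    perim = np.asarray(perimeter.values).astype(bool) & regime.mask
    if not perim.any():
        raise ValueError("empty fire perimeter")
    rng = np.random.default_rng(seed)
    hist_low = np.asarray(regime.values) == REGIME_LOW
    match = rng.random(regime.shape) < concordance
    obs_low = np.where(match, hist_low, ~hist_low)
    low_class = rng.integers(1, 3, size=regime.shape)    # {1, 2}
    mixed_class = rng.integers(3, 5, size=regime.shape)  # {3, 4}
    out = np.where(obs_low, low_class, mixed_class).astype(int)
    out[~perim] = -9999
    return regime.like(out, nodata=-9999)


def simulate_behavior(
    regime: Raster,
    seed: int = 0,
    p_crown_low: float = 0.2,
    p_crown_mixed: float = 0.8,
    mean_surface_kwm: float = 14_020.0,
    mean_crown_kwm: float = 43_620.0,
    sigma: float = 0.5,
) -> tuple[Raster, Raster]:
    """Crown-activity and fireline-intensity rasters for a regime map.

    Crown activity is Bernoulli per cell with probability depending on the
    historical regime; fireline intensity is lognormal with the location
    set so that the surface and crown/torch class means default to the
    14,020 and 43,620 kW/m anchors.
    """
    rng = np.random.default_rng(seed)
    hist_low = np.asarray(regime.values) == REGIME_LOW
    p_crown = np.where(hist_low, p_crown_low, p_crown_mixed)
    crown = rng.random(regime.shape) < p_crown
    mu_surface = math.log(mean_surface_kwm) - sigma**2 / 2.0
    mu_crown = math.log(mean_crown_kwm) - sigma**2 / 2.0
    mu = np.where(crown, mu_crown, mu_surface)
    intensity = rng.lognormal(mean=mu, sigma=sigma)
    crown_vals = np.where(crown, CROWN_OR_TORCH, SURFACE).astype(int)
    bad = ~regime.mask
    crown_vals[bad] = -9999
    intensity = intensity.astype(float)
    intensity[bad] = np.nan
    return (
        regime.like(crown_vals, nodata=-9999),
        regime.like(intensity, nodata=np.nan),
    )
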