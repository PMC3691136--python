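"""Synthetic landscapes, survey designs, and roadside count data.

This module emulates the structure of the study data so the downstream
stages (landscape metrics, hierarchical count adjustment, change-point
detection) can be exercised with known ground truth:

* a dated series of 30-m categorical rasters produced by a modified
  random-clusters neutral landscape, with exurban development growing as
  scattered small clusters seeded at forest/other boundaries so that
  fragmentation metrics genuinely change over time;
* a roadside survey design — routes as transects with regularly spaced
  stops, one observer per route per year, observer turnover with a
  first-year flag;
* Poisson counts generated on the log link from stop-level intercepts and
  trends, a first-year observer effect, route and observer random effects,
  per-observation noise, and an optional step (threshold) response to a
  named landscape variable.

Defaults mirror the study design: 125 stops on 13 routes surveyed
1986–2009, rasters for 1986/1993/2000/2009, forest cover declining from
about 49% to 41% while exurban cover grows from under 2% to 6%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import EXURBAN, FOREST, OTHER, RasterLandscape

_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class SynthConfig:
    """Scenario parameters for the synthetic study.

    ``exurban_growth_rates`` gives, per raster date, the fraction of grid
    area newly converted to exurban development (the first entry is the
    baseline exurban fraction at the first date).  ``forest_clearing_rates``
    is an analogous schedule of forest converted to open land, which lets
    forest cover fall faster than exurban cover grows, as observed in
    exurbanising regions.
    """

    n_stops: int = 125
    n_routes: int = 13
    years: tuple[int, int] = (1986, 2009)
    raster_dates: tuple[int, ...] = (1986, 1993, 2000, 2009)
    grid_size: int = 1400
    cell_size: float = 30.0
    initial_forest_fraction: float = 0.492
    exurban_growth_rates: tuple[float, ...] = (0.017, 0.008, 0.012, 0.023)
    forest_clearing_rates: tuple[float, ...] = (0.0, 0.012, 0.013, 0.018)
    observer_turnover_prob: float = 0.2
    min_spacing_m: float = 4000.0
    route_margin_m: float = 1100.0
    cluster_prob: float = 0.45
    exurban_cluster_size: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.years
        if not set(self.raster_dates) <= set(range(lo, hi + 1)):
            raise ValueError("raster_dates must be a subset of years")
        for p in (self.initial_forest_fraction, self.observer_turnover_prob,
                  *self.exurban_growth_rates, *self.forest_clearing_rates):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion out of [0, 1]: {p}")
        if self.n_stops < 1:
            raise ValueError("n_stops must be >= 1")
        if len(self.exurban_growth_rates) != len(self.raster_dates):
            raise ValueError("need one exurban growth rate per raster date")
        if len(self.forest_clearing_rates) != len(self.raster_dates):
            raise ValueError("need one forest clearing rate per raster date")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def extent_m(self) -> float:
        return self.grid_size * self.cell_size


@dataclass
class TaxonParams:
    """Ground-truth generating parameters for one taxon (log link)."""

    beta0: float  # taxon-level mean intercept
    beta1: float  # taxon-level mean year trend (per year)
    beta2: float = 0.0  # first-year observer effect
    route_sd: float = 0.1
    observer_sd: float = 0.1
    noise_sd: float = 0.1
    beta0_sd: float = 0.2  # sd of stop-level intercepts around beta0
    beta1_sd: float = 0.005  # sd of stop-level trends around beta1
    response_var: str | None = None  # landscape variable driving the step
    response_radius: float | None = None  # buffer radius of that variable
    response_cp: float | None = None  # change point x0, in variable units
    response_delta: float = 0.0  # step size on the log scale
    response_direction: str = "+"  # '+': step applies at x >= x0; '-': below
    response_shape: str = "step"  # 'step' or 'logistic'
    response_scale: float = 1.0  # logistic steepness (variable units)

    def __post_init__(self) -> None:
        for sd in (self.route_sd, self.observer_sd, self.noise_sd,
                   self.beta0_sd, self.beta1_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.response_direction not in ("+", "-"):
            raise ValueError("response_direction must be '+' or '-'")


def default_taxa() -> dict[str, TaxonParams]:
    """Eleven taxa with contrasting habitat responses.

    Seven forest-interior taxa respond positively to forest cover (step up
    above the change point) and four forest-edge taxa respond positively
    to low forest cover / developing landscapes.  Intercepts and trends
    echo the magnitudes typical of roadside counts of these guilds
    (mean counts well below one bird per 3-minute stop, trends of a few
    percent per year).
    """
    forest = {
        "AMRE": TaxonParams(beta0=-2.2, beta1=0.042),
        "OVEN": TaxonParams(beta0=-2.1, beta1=0.029),
        "REVI": TaxonParams(beta0=-1.1, beta1=0.024),
        "EAPH": TaxonParams(beta0=-2.5, beta1=0.005),
        "WOTH": TaxonParams(beta0=-1.0, beta1=0.008),
        "SCTA": TaxonParams(beta0=-1.8, beta1=-0.004),
        "EAWP": TaxonParams(beta0=-1.5, beta1=-0.001),
    }
    edge = {
        "GRCA": TaxonParams(beta0=-1.0, beta1=0.025),
        "NOCA": TaxonParams(beta0=-0.8, beta1=0.022),
        "EATO": TaxonParams(beta0=-1.2, beta1=0.007),
        "INBU": TaxonParams(beta0=-0.4, beta1=-0.006),
    }
    for p in forest.values():
        p.beta2 = 0.2
        p.response_var = "forest_pct"
        p.response_radius = 400.0
        p.response_cp = 45.0
        p.response_delta = 1.2
        p.response_direction = "+"
    for p in edge.values():
        p.beta2 = 0.2
        p.response_var = "forest_pct"
        p.response_radius = 400.0
        p.response_cp = 45.0
        p.response_delta = 1.2
        p.response_direction = "-"
    return {**forest, **edge}


# ---------------------------------------------------------------------------
# landscapes


def _random_cluster_map(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Modified random-clusters forest map at the exact target fraction.

    Cells are marked at ``cluster_prob``, marked clusters (4-connected)
    are assigned to forest in random order until the target cell count is
    reached, the last cluster is peeled back from its boundary to hit the
    count exactly, and any remaining deficit is grown from the forest
    boundary.
    """
    n = config.grid_size
    target = int(round(config.initial_forest_fraction * n * n))
    forest = np.zeros((n, n), dtype=bool)
    if target == 0:
        return forest
    marked = rng.random((n, n)) < config.cluster_prob
    labels, nlab = ndimage.label(marked, structure=_STRUCT4)
    order = rng.permutation(nlab) + 1
    counts = np.bincount(labels.ravel(), minlength=nlab + 1)
    placed = 0
    for lab in order:
        forest[labels == lab] = True
        placed += counts[lab]
        if placed >= target:
            break
    # majority smoothing welds the assigned clusters into coherent
    # patches with interior (core) forest, as in real forest tracts
    for _ in range(3):
        neigh = ndimage.uniform_filter(forest.astype(float), size=3,
                                       mode="constant")
        forest = neigh > 0.5
    placed = int(forest.sum())
    # trim back to the exact target from the patch boundaries
    while placed > target:
        interior = ndimage.binary_erosion(forest, structure=_STRUCT4,
                                          border_value=0)
        cand = np.argwhere(forest & ~interior)
        if len(cand) == 0:
            cand = np.argwhere(forest)
        take = min(placed - target, max(1, len(cand) // 3))
        pick = rng.choice(len(cand), size=take, replace=False)
        forest[cand[pick, 0], cand[pick, 1]] = False
        placed -= take
    while placed < target:
        # grow from the boundary (or seed randomly if no forest yet)
        if not forest.any():
            forest[rng.integers(n), rng.integers(n)] = True
            placed += 1
            continue
        ring = ndimage.binary_dilation(forest, structure=_STRUCT4) & ~forest
        cand = np.argwhere(ring)
        take = min(len(cand), target - placed)
        pick = rng.choice(len(cand), size=take, replace=False)
        forest[cand[pick, 0], cand[pick, 1]] = True
        placed += take
    return forest


def _grow_exurban(
    grid: np.ndarray,
    n_cells: int,
    mean_cluster: float,
    rng: np.random.Generator,
) -> None:
    """Convert ``n_cells`` cells to exurban, in small clusters seeded at
    forest/other boundaries, growing into either class (in place)."""
    available = int(np.sum(grid != EXURBAN))
    if n_cells > available:
        raise ValueError(
            f"grid too small: cannot place {n_cells} new exurban cells "
            f"({available} non-exurban cells remain)"
        )
    placed = 0
    while placed < n_cells:
        # boundary cells between forest and other (either side), not exurban
        forest = grid == FOREST
        other = grid == OTHER
        near_forest = ndimage.binary_dilation(forest, structure=_STRUCT4)
        near_other = ndimage.binary_dilation(other, structure=_STRUCT4)
        seeds = np.argwhere((forest | other) & near_forest & near_other)
        if len(seeds) == 0:  # degenerate single-class landscape
            seeds = np.argwhere(grid != EXURBAN)
        size = min(1 + rng.geometric(1.0 / mean_cluster), n_cells - placed)
        r, c = seeds[rng.integers(len(seeds))]
        cluster = np.zeros_like(grid, dtype=bool)
        cluster[r, c] = True
        grid[r, c] = EXURBAN
        placed += 1
        for _ in range(size - 1):
            ring = ndimage.binary_dilation(cluster, structure=_STRUCT4) & ~cluster
            cand = np.argwhere(ring & (grid != EXURBAN))
            if len(cand) == 0:
                break
            rr, cc = cand[rng.integers(len(cand))]
            cluster[rr, cc] = True
            grid[rr, cc] = EXURBAN
            placed += 1


def _clear_forest(
    grid: np.ndarray, n_cells: int, rng: np.random.Generator
) -> None:
    """Convert ``n_cells`` forest cells to open land, preferring boundary
    cells so clearing nibbles patch edges (in place)."""
    remaining = n_cells
    while remaining > 0:
        forest = grid == FOREST
        if not forest.any():
            return
        interior = ndimage.binary_erosion(forest, structure=_STRUCT4,
                                          border_value=0)
        cand = np.argwhere(forest & ~interior)
        if len(cand) == 0:
            cand = np.argwhere(forest)
        # clear a batch of boundary cells per round, then re-derive the edge
        take = min(remaining, max(1, len(cand) // 4))
        pick = rng.choice(len(cand), size=take, replace=False)
        grid[cand[pick, 0], cand[pick, 1]] = OTHER
        remaining -= take


def generate_landscape_series(config: SynthConfig) -> list[RasterLandscape]:
    """One raster per raster date, with monotone forest loss and exurban
    growth; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.grid_size
    total = n * n
    if sum(config.exurban_growth_rates) > 1.0:
        raise ValueError("cumulative exurban growth exceeds the grid area")
    forest = _random_cluster_map(config, rng)
    grid = np.where(forest, FOREST, OTHER).astype(np.int8)
    out: list[RasterLandscape] = []
    for date, g_ex, g_cl in zip(config.raster_dates,
                                config.exurban_growth_rates,
                                config.forest_clearing_rates):
        n_ex = int(round(g_ex * total))
        if n_ex:
            _grow_exurban(grid, n_ex, config.exurban_cluster_size, rng)
        n_cl = int(round(g_cl * total))
        if n_cl:
            _clear_forest(grid, n_cl, rng)
        out.append(RasterLandscape(grid=grid.copy(),
                                   cell_size=config.cell_size,
                                   origin=(0.0, 0.0), date=date))
    return out


# ---------------------------------------------------------------------------
# survey design


def generate_survey_design(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stop table and observer-assignment table.

    Routes are horizontal transects; stops sit at ``min_spacing_m``
    intervals along each route, at least ``route_margin_m`` from every
    raster edge so the largest buffer fits.  Each route has one observer
    per year; with probability ``observer_turnover_prob`` a new observer
    takes over in a given year.  ``first_year`` is true exactly in an
    observer's first year.
    """
    if config.n_stops > config.n_routes * 10:
        raise ValueError("at most 10 stops per route")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    extent = config.extent_m
    margin = config.route_margin_m
    usable = extent - 2 * margin
    if usable <= 0:
        raise ValueError("grid too small for the buffer margin")
    per_route = int(np.ceil(config.n_stops / config.n_routes))
    span = (per_route - 1) * config.min_spacing_m
    if span > usable:
        raise ValueError(
            f"cannot place {per_route} stops {config.min_spacing_m} m apart "
            f"in a usable extent of {usable:.0f} m"
        )
    if config.n_routes > 1:
        ys = margin + usable * np.arange(config.n_routes) / (config.n_routes - 1)
    else:
        ys = np.array([extent / 2.0])
    rows = []
    k = 0
    for r in range(config.n_routes):
        x0 = margin + rng.uniform(0, usable - span)
        jitter = rng.uniform(-0.25, 0.25, size=per_route) * config.min_spacing_m
        if per_route == 1:
            jitter[:] = 0.0
        for s in range(per_route):
            if k >= config.n_stops:
                break
            x = float(np.clip(x0 + s * config.min_spacing_m
                              + 0.5 * jitter[s], margin, extent - margin))
            rows.append({"stop": f"R{r + 1:02d}S{s + 1:02d}",
                         "route": f"R{r + 1:02d}", "x": x, "y": float(ys[r])})
            k += 1
    stops = pd.DataFrame(rows)

    years = config.year_list
    obs_rows = []
    next_id = 1
    for r in range(config.n_routes):
        route = f"R{r + 1:02d}"
        current = next_id
        next_id += 1
        first = {current: years[0]}
        for i, year in enumerate(years):
            if i > 0 and rng.random() < config.observer_turnover_prob:
                current = next_id
                next_id += 1
                first[current] = year
            obs_rows.append({"route": route, "year": year,
                             "observer": f"O{current:03d}",
                             "first_year": first[current] == year})
    observers = pd.DataFrame(obs_rows)
    return stops, observers


# ---------------------------------------------------------------------------
# counts


def _step_effect(x: np.ndarray, p: TaxonParams) -> np.ndarray:
    """Threshold contribution to the log mean for variable values ``x``."""
    if p.response_var is None or p.response_cp is None:
        return np.zeros_like(x, dtype=float)
    if p.response_shape == "logistic":
        s = 1.0 / (1.0 + np.exp(-(x - p.response_cp) / p.response_scale))
        ind = s if p.response_direction == "+" else 1.0 - s
    else:
        ind = (x >= p.response_cp) if p.response_direction == "+" \
            else (x < p.response_cp)
        ind = ind.astype(float)
    return p.response_delta * ind


def generate_counts(
    stops: pd.DataFrame,
    observers: pd.DataFrame,
    metrics: pd.DataFrame,
    params: dict[str, TaxonParams],
    seed: int,
    year_to_date: dict[int, int] | None = None,
    log_mean_cap: float = 10.0,
) -> pd.DataFrame:
    """Simulate the count table for all taxa.

    The log mean for stop *i* in year *t* is
    ``b0_i + b1_i * (t - t̄) + beta2 * first_year + route + observer +
    noise + step(x_it)`` where ``x_it`` is the taxon's response variable at
    the raster date matched to year *t*; route and observer effects are
    drawn once per unit, noise per observation.  Deterministic given
    ``seed``; log means are capped at ``log_mean_cap``.
    """
    from .pipeline import match_years_to_rasters  # avoid a module cycle

    years = sorted(observers["year"].unique())
    tbar = float(np.mean(years))
    if year_to_date is None:
        dates = sorted(metrics["date"].unique())
        year_to_date = match_years_to_rasters(years, dates)

    design = observers.merge(stops, on="route")  # one row per stop-year
    routes = sorted(stops["route"].unique())
    obs_ids = sorted(observers["observer"].unique())

    rows = []
    ss = np.random.SeedSequence([seed, 2])
    for taxon, child in zip(sorted(params), ss.spawn(len(params))):
        p = params[taxon]
        rng = np.random.default_rng(child)
        b0 = {s: p.beta0 + rng.normal(0, p.beta0_sd) for s in stops["stop"]}
        b1 = {s: p.beta1 + rng.normal(0, p.beta1_sd) for s in stops["stop"]}
        route_eff = dict(zip(routes, rng.normal(0, p.route_sd, len(routes))))
        obs_eff = dict(zip(obs_ids, rng.normal(0, p.observer_sd, len(obs_ids))))

        if p.response_var is not None:
            sel = metrics[np.isclose(metrics["radius_m"], p.response_radius)]
            xlut = sel.set_index(["stop", "date"])[p.response_var]
            x = np.array([
                xlut.loc[(s, year_to_date[y])]
                for s, y in zip(design["stop"], design["year"])
            ])
        else:
            x = np.zeros(len(design))

        lp = (
            np.array([b0[s] for s in design["stop"]])
            + np.array([b1[s] for s in design["stop"]])
            * (design["year"].to_numpy() - tbar)
            + p.beta2 * design["first_year"].to_numpy().astype(float)
            + np.array([route_eff[r] for r in design["route"]])
            + np.array([obs_eff[o] for o in design["observer"]])
            + rng.normal(0, p.noise_sd, len(design))
            + _step_effect(x, p)
        )
        lp = np.minimum(lp, log_mean_cap)
        counts = rng.poisson(np.exp(lp))
        for (_, row), c in zip(design.iterrows(), counts):
            rows.append({
                "stop": row["stop"], "year": int(row["year"]),
                "route": row["route"], "observer": row["observer"],
                "first_year": bool(row["first_year"]),
                "taxon": taxon, "count": int(c),
            })
    return pd.DataFrame(rows)
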