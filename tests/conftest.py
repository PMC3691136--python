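from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from birdscape.raster import FOREST, OTHER, RasterLandscape


def make_raster(grid, cell_size=30.0, date=2000) -> RasterLandscape:
    return RasterLandscape(grid=np.asarray(grid, dtype=np.int8),
                           cell_size=cell_size, origin=(0.0, 0.0), date=date)


def random_raster(rng, n=60, p_forest=0.5, p_exurban=0.05,
                  smooth=0) -> RasterLandscape:
    """Random categorical raster; optional majority smoothing for
    clumpier (more realistic) class maps."""
    from scipy import ndimage

    forest = rng.random((n, n)) < p_forest
    for _ in range(smooth):
        forest = ndimage.uniform_filter(forest.astype(float), 3) > 0.5
    grid = np.where(forest, FOREST, OTHER).astype(np.int8)
    ex = (~forest) & (rng.random((n, n)) < p_exurban / max(1e-9, 1 - p_forest))
    grid[ex] = 2
    return make_raster(grid)


def simulate_counts(seed: int, S: int = 30, T: int = 12, beta2: float = 0.5,
                    b1_mean: float = 0.03, b0_mean: float = -0.5,
                    route_sd: float = 0.1, obs_sd: float = 0.1,
                    noise_sd: float = 0.1, turnover: float = 0.25):
    """Direct simulation of the count-generating process, written
    independently of the package's synthetic-data module.

    Returns the count table and the realised true parameters.
    """
    rng = np.random.default_rng(seed)
    years = list(range(1998, 1998 + T))
    tbar = float(np.mean(years))
    stops = [f"S{i:02d}" for i in range(S)]
    routes = {s: f"R{i // 5}" for i, s in enumerate(stops)}
    b0 = rng.normal(b0_mean, 0.2, S)
    b1 = rng.normal(b1_mean, 0.005, S)
    route_eff = {r: rng.normal(0, route_sd) for r in sorted(set(routes.values()))}
    obs_of, first_seen = {}, {}
    for r in sorted(set(routes.values())):
        oid = 0
        for y in years:
            if y != years[0] and rng.random() < turnover:
                oid += 1
            o = f"{r}O{oid}"
            obs_of[(r, y)] = o
            first_seen.setdefault(o, y)
    obs_eff = {o: rng.normal(0, obs_sd) for o in sorted(set(obs_of.values()))}
    rows = []
    for i, s in enumerate(stops):
        r = routes[s]
        for y in years:
            o = obs_of[(r, y)]
            fy = first_seen[o] == y
            lp = (b0[i] + b1[i] * (y - tbar) + beta2 * fy
                  + route_eff[r] + obs_eff[o] + rng.normal(0, noise_sd))
            rows.append(dict(stop=s, year=y, route=r, observer=o,
                             first_year=fy, count=rng.poisson(np.exp(lp))))
    truth = {"b0": b0, "b1": b1, "b1_mean": float(b1.mean()),
             "beta2": beta2, "route_eff": route_eff, "obs_eff": obs_eff}
    return pd.DataFrame(rows), truth


@pytest.fixture(scope="session")
def tiny_synth_config():
    from birdscape.synth import SynthConfig

    return SynthConfig(
        n_stops=8, n_routes=2, years=(2000, 2009),
        raster_dates=(2000, 2003, 2006, 2009), grid_size=80,
        initial_forest_fraction=0.55,
        exurban_growth_rates=(0.02, 0.03, 0.04, 0.05),
        forest_clearing_rates=(0.0, 0.02, 0.03, 0.03),
        min_spacing_m=250.0, route_margin_m=420.0, seed=7,
    )
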