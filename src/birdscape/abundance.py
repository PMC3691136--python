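"""Hierarchical Bayesian adjustment of roadside count data.

The observation model for the count ``C_it`` of one taxon at stop *i* in
year *t* is an overdispersed Poisson on the log link::

    C_it ~ Poisson(mu_it)
    log mu_it = b0_i + b1_i * (t - t̄) + b2 * FirstYear_it
                + Route_it + Observer_it + Noise_it

Each stop has its own intercept ``b0_i`` and trend ``b1_i``, exchangeable
around taxon-level means with vague normal hyper-means; the first-year
observer effect ``b2`` is a scalar; route and observer effects are drawn
once per unit and the noise term once per observation, all centred
normals.  Every precision carries an InverseGamma(0.001, 0.001) prior
(equivalently a Gamma prior on the precision itself).

Sampling is Metropolis-within-Gibbs: conjugate Gibbs draws for the
hyper-means and precisions, vectorised random-walk Metropolis for the
location parameters (which are conditionally independent within each
block), plus translation moves along the additively confounded directions
(intercepts vs. route / observer / noise means) to speed mixing.  Step
sizes adapt toward a 44% acceptance rate during burn-in only, so the
post-burn-in chain is a fixed Markov kernel.

Two (or more) chains run from dispersed starts; convergence is gated on
the Gelman-Rubin potential scale reduction factor of the monitored
scalar parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_CAP = 30.0  # cap on the log mean inside the likelihood
_MU_PRIOR_VAR = 100.0  # vague normal variance for the taxon-level means


class ConvergenceError(RuntimeError):
    """Raised when monitored parameters fail the Gelman-Rubin gate."""


@dataclass
class McmcConfig:
    n_chains: int = 2
    n_iterations: int = 30_000
    n_burnin: int = 5_000
    thin: int = 10
    seed: int = 0
    rhat_threshold: float = 1.1
    prior_shape: float = 0.001
    prior_rate: float = 0.001
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if self.n_iterations <= self.n_burnin:
            raise ValueError("n_iterations must exceed n_burnin")


@dataclass
class _TaxonData:
    C: np.ndarray
    stop_idx: np.ndarray
    route_idx: np.ndarray
    obs_idx: np.ndarray
    first: np.ndarray
    tc: np.ndarray  # centred year
    stops: list
    routes: list
    observers: list
    years: list
    tbar: float
    stop_route: np.ndarray  # route index of each stop


@dataclass
class AbundanceFit:
    """Posterior draws plus the index structure needed to interpret them.

    ``draws`` maps parameter names to arrays of shape
    ``(n_chains, n_kept, ...)``.
    """

    draws: dict[str, np.ndarray]
    data: _TaxonData
    config: McmcConfig
    degenerate: bool = False

    def stacked(self, name: str) -> np.ndarray:
        """Draws with the chain axis folded into the draw axis."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])


def _prepare(counts: pd.DataFrame) -> _TaxonData:
    c = counts["count"].to_numpy()
    if not np.issubdtype(c.dtype, np.integer):
        if not np.allclose(c, np.round(c)):
            raise ValueError("counts must be integers")
        c = np.round(c).astype(int)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    years = sorted(counts["year"].unique())
    if len(years) < 2:
        raise ValueError("need at least 2 years of data")
    if counts[["route", "observer"]].isna().any().any():
        raise ValueError("every record must map to a route and observer")
    stops = sorted(counts["stop"].unique())
    routes = sorted(counts["route"].unique())
    observers = sorted(counts["observer"].unique())
    s_map = {s: i for i, s in enumerate(stops)}
    r_map = {r: i for i, r in enumerate(routes)}
    o_map = {o: i for i, o in enumerate(observers)}
    tbar = float(np.mean(years))
    stop_route = np.zeros(len(stops), dtype=int)
    for s, r in counts.groupby("stop")["route"].first().items():
        stop_route[s_map[s]] = r_map[r]
    return _TaxonData(
        C=c.astype(float),
        stop_idx=counts["stop"].map(s_map).to_numpy(),
        route_idx=counts["route"].map(r_map).to_numpy(),
        obs_idx=counts["observer"].map(o_map).to_numpy(),
        first=counts["first_year"].to_numpy().astype(float),
        tc=counts["year"].to_numpy().astype(float) - tbar,
        stops=stops, routes=routes, observers=observers, years=years,
        tbar=tbar, stop_route=stop_route,
    )


def _run_chain(data: _TaxonData, config: McmcConfig,
               rng: np.random.Generator) -> dict[str, np.ndarray]:
    C, K = data.C, len(data.C)
    S, R, O = len(data.stops), len(data.routes), len(data.observers)
    a, b = config.prior_shape, config.prior_rate
    sidx, ridx, oidx = data.stop_idx, data.route_idx, data.obs_idx
    first, tc = data.first, data.tc

    # dispersed start
    base = np.log(C.mean() + 0.1)
    b0 = np.full(S, base) + rng.normal(0, 0.5) + rng.normal(0, 0.1, S)
    b1 = rng.normal(0, 0.01, S)
    mu0, mu1 = float(b0.mean()), float(b1.mean())
    b2 = rng.normal(0, 0.3)
    route = rng.normal(0, 0.1, R)
    obsf = rng.normal(0, 0.1, O)
    eta = np.zeros(K)
    lam = {"b0": 1.0, "b1": 100.0, "b2": 1.0,
           "route": 10.0, "obs": 10.0, "noise": 10.0}

    def linpred():
        return (b0[sidx] + b1[sidx] * tc + b2 * first
                + route[ridx] + obsf[oidx] + eta)

    lp = linpred()
    elp = np.exp(np.minimum(lp, _CAP))

    # adaptive RW-MH step sizes (log scale), frozen after burn-in
    step = {"eta": 0.5, "b0": 0.2, "b1": 0.05, "b2": 0.2,
            "route": 0.2, "obs": 0.2, "mu0": 0.05}
    acc_n = {k: 0.0 for k in step}
    acc_d = {k: 0.0 for k in step}

    def mh_block(name, nG, idx, delta_obs, prior_diff, apply):
        nonlocal lp, elp
        lpn = lp + delta_obs
        ll = C * delta_obs - (np.exp(np.minimum(lpn, _CAP)) - elp)
        if idx is None:
            gd = ll + prior_diff
        else:
            gd = np.bincount(idx, weights=ll, minlength=nG) + prior_diff
        acc = np.log(rng.random(nG)) < gd
        apply(acc)
        lp = linpred()
        elp = np.exp(np.minimum(lp, _CAP))
        acc_n[name] += acc.sum()
        acc_d[name] += nG

    n_kept = (config.n_iterations - config.n_burnin) // config.thin
    out = {
        "b0": np.empty((n_kept, S)), "b1": np.empty((n_kept, S)),
        "mu0": np.empty(n_kept), "mu1": np.empty(n_kept),
        "b2": np.empty(n_kept),
        "route": np.empty((n_kept, R)), "obs": np.empty((n_kept, O)),
        "sd_b0": np.empty(n_kept), "sd_b1": np.empty(n_kept),
        "sd_b2": np.empty(n_kept), "sd_route": np.empty(n_kept),
        "sd_obs": np.empty(n_kept), "sd_noise": np.empty(n_kept),
    }
    kept = 0

    for it in range(config.n_iterations):
        # --- per-observation noise: independence proposal from the
        # Laplace approximation of each conditional (the conditionals are
        # log-concave and independent given the rest), which avoids the
        # funnel between the noise terms and their precision
        rest = lp - eta
        mode = np.zeros(K)
        for _ in range(6):  # Newton on C*e - exp(rest+e) - lam/2 e^2
            ex = np.exp(np.minimum(rest + mode, _CAP))
            mode += (C - ex - lam["noise"] * mode) / (ex + lam["noise"])
        ex = np.exp(np.minimum(rest + mode, _CAP))
        psd = 1.0 / np.sqrt(ex + lam["noise"])
        prop = mode + psd * rng.normal(size=K)

        def logf(e):
            return (C * e - np.exp(np.minimum(rest + e, _CAP))
                    - 0.5 * lam["noise"] * e**2)

        logq_prop = -0.5 * ((prop - mode) / psd) ** 2
        logq_cur = -0.5 * ((eta - mode) / psd) ** 2
        alpha = logf(prop) - logf(eta) - (logq_prop - logq_cur)
        acc = np.log(rng.random(K)) < alpha
        eta[acc] = prop[acc]
        lp = linpred()
        elp = np.exp(np.minimum(lp, _CAP))
        acc_n["eta"] += acc.sum()
        acc_d["eta"] += K

        # --- stop intercepts
        d = rng.normal(0, step["b0"], S)
        pr = -0.5 * lam["b0"] * ((b0 + d - mu0) ** 2 - (b0 - mu0) ** 2)

        def ap_b0(acc, d=d):
            b0[acc] += d[acc]
        mh_block("b0", S, sidx, d[sidx], pr, ap_b0)

        # --- stop trends
        d = rng.normal(0, step["b1"], S)
        pr = -0.5 * lam["b1"] * ((b1 + d - mu1) ** 2 - (b1 - mu1) ** 2)

        def ap_b1(acc, d=d):
            b1[acc] += d[acc]
        mh_block("b1", S, sidx, d[sidx] * tc, pr, ap_b1)

        # --- first-year effect (scalar)
        d = rng.normal(0, step["b2"])
        pr = -0.5 * lam["b2"] * ((b2 + d) ** 2 - b2**2)

        def ap_b2(acc, d=d):
            nonlocal b2
            if acc[0]:
                b2 += d
        mh_block("b2", 1, np.zeros(K, dtype=int), d * first,
                 np.array([pr]), ap_b2)

        # --- route effects
        d = rng.normal(0, step["route"], R)
        pr = -0.5 * lam["route"] * ((route + d) ** 2 - route**2)

        def ap_r(acc, d=d):
            route[acc] += d[acc]
        mh_block("route", R, ridx, d[ridx], pr, ap_r)

        # --- observer effects
        d = rng.normal(0, step["obs"], O)
        pr = -0.5 * lam["obs"] * ((obsf + d) ** 2 - obsf**2)

        def ap_o(acc, d=d):
            obsf[acc] += d[acc]
        mh_block("obs", O, oidx, d[oidx], pr, ap_o)

        # --- translation moves along confounded directions (exact Gibbs
        # on the shift; the likelihood is invariant, priors are normal)
        for vec, nV, lam_v in ((route, R, lam["route"]),
                               (obsf, O, lam["obs"]),
                               (eta, K, lam["noise"])):
            P = nV * lam_v + S * lam["b0"]
            m = (lam_v * vec.sum() - lam["b0"] * (b0 - mu0).sum()) / P
            c_shift = rng.normal(m, 1.0 / np.sqrt(P))
            vec -= c_shift
            b0 += c_shift
        lp = linpred()
        elp = np.exp(np.minimum(lp, _CAP))

        # --- interweaving (non-centered) scale moves: with the
        # standardised effects held fixed, propose the precision on the
        # log scale and rescale the effects, so the scale parameters do
        # not random-walk through the funnel
        def scale_interweave(key, vec, obs_map):
            nonlocal lp, elp
            theta = np.log(lam[key])
            theta_new = theta + rng.normal(0, 0.6)
            ratio = np.exp(0.5 * (theta - theta_new))
            vnew = vec * ratio
            delta = obs_map(vnew - vec)
            lpn = lp + delta
            dll = np.sum(C * delta - (np.exp(np.minimum(lpn, _CAP)) - elp))
            dpr = (a * (theta_new - theta)
                   - b * (np.exp(theta_new) - np.exp(theta)))
            if np.log(rng.random()) < dll + dpr:
                vec[:] = vnew
                lam[key] = float(np.exp(theta_new))
                lp = lpn
                elp = np.exp(np.minimum(lp, _CAP))

        scale_interweave("noise", eta, lambda d: d)
        scale_interweave("route", route, lambda d: d[ridx])
        scale_interweave("obs", obsf, lambda d: d[oidx])
        u0 = b0 - mu0
        scale_interweave("b0", u0, lambda d: d[sidx])
        b0 = mu0 + u0
        u1 = b1 - mu1
        scale_interweave("b1", u1, lambda d: d[sidx] * tc)
        b1 = mu1 + u1
        lp = linpred()
        elp = np.exp(np.minimum(lp, _CAP))

        # --- likelihood-driven location move for the intercept level
        # (non-centered in mu0: shifts every stop intercept together)
        dmu = rng.normal(0, step["mu0"])
        lpn = lp + dmu
        dll = np.sum(C * dmu - (np.exp(np.minimum(lpn, _CAP)) - elp))
        dpr = -((mu0 + dmu) ** 2 - mu0**2) / (2 * _MU_PRIOR_VAR)
        acc_d["mu0"] += 1
        if np.log(rng.random()) < dll + dpr:
            mu0 += dmu
            b0 += dmu
            lp = lpn
            elp = np.exp(np.minimum(lp, _CAP))
            acc_n["mu0"] += 1

        # --- conjugate updates: hyper-means and precisions
        P0 = 1.0 / _MU_PRIOR_VAR + S * lam["b0"]
        mu0 = rng.normal(lam["b0"] * b0.sum() / P0, 1.0 / np.sqrt(P0))
        P1 = 1.0 / _MU_PRIOR_VAR + S * lam["b1"]
        mu1 = rng.normal(lam["b1"] * b1.sum() / P1, 1.0 / np.sqrt(P1))
        lam["b0"] = rng.gamma(a + S / 2, 1.0 / (b + 0.5 * np.sum((b0 - mu0) ** 2)))
        lam["b1"] = rng.gamma(a + S / 2, 1.0 / (b + 0.5 * np.sum((b1 - mu1) ** 2)))
        lam["b2"] = rng.gamma(a + 0.5, 1.0 / (b + 0.5 * b2**2))
        lam["route"] = rng.gamma(a + R / 2, 1.0 / (b + 0.5 * np.sum(route**2)))
        lam["obs"] = rng.gamma(a + O / 2, 1.0 / (b + 0.5 * np.sum(obsf**2)))
        lam["noise"] = rng.gamma(a + K / 2, 1.0 / (b + 0.5 * np.sum(eta**2)))

        # --- step-size adaptation during burn-in
        if config.adapt and it < config.n_burnin and (it + 1) % 50 == 0:
            for k in step:
                rate = acc_n[k] / max(acc_d[k], 1.0)
                step[k] *= float(np.exp(0.3 * (rate - 0.44)))
                acc_n[k] = acc_d[k] = 0.0

        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            if kept < n_kept:
                out["b0"][kept] = b0
                out["b1"][kept] = b1
                out["mu0"][kept] = mu0
                out["mu1"][kept] = mu1
                out["b2"][kept] = b2
                out["route"][kept] = route
                out["obs"][kept] = obsf
                for nm, key in (("sd_b0", "b0"), ("sd_b1", "b1"),
                                ("sd_b2", "b2"), ("sd_route", "route"),
                                ("sd_obs", "obs"), ("sd_noise", "noise")):
                    out[nm][kept] = 1.0 / np.sqrt(lam[key])
                kept += 1
    return out


def fit_abundance_model(counts: pd.DataFrame,
                        config: McmcConfig) -> AbundanceFit:
    """Fit the hierarchical model to one taxon's count table.

    ``counts`` needs columns ``stop, year, route, observer, first_year,
    count``.  Returns draws from ``config.n_chains`` independent chains
    started from dispersed initial values; deterministic given
    ``config.seed``.
    """
    data = _prepare(counts)
    chains = []
    for child in np.random.SeedSequence(config.seed).spawn(config.n_chains):
        chains.append(_run_chain(data, config, np.random.default_rng(child)))
    draws = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
    return AbundanceFit(draws=draws, data=data, config=config,
                        degenerate=bool(counts["count"].sum() == 0))


# ---------------------------------------------------------------------------
# diagnostics


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_draws).  Classic (non-split)
    between/within formulation.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0 if B_over_n == 0 else np.inf
    vhat = (n - 1) / n * W + (1 + 1 / m) * B_over_n
    return float(np.sqrt(vhat / W))


MONITORED = ["mu0", "mu1", "b2", "sd_b0", "sd_route", "sd_obs", "sd_noise"]


def convergence_report(fit: AbundanceFit,
                       params: list[str] | None = None) -> dict[str, float]:
    """R̂ for each monitored scalar parameter."""
    params = params or MONITORED
    return {p: gelman_rubin(fit.draws[p]) for p in params}


def check_convergence(fit: AbundanceFit,
                      threshold: float | None = None) -> dict[str, float]:
    """Gate the pipeline on R̂; raises listing the offending parameters."""
    threshold = threshold if threshold is not None else fit.config.rhat_threshold
    report = convergence_report(fit)
    bad = {p: r for p, r in report.items() if r > threshold}
    if bad:
        raise ConvergenceError(
            "Gelman-Rubin diagnostic above "
            f"{threshold}: " + ", ".join(f"{p}={r:.3f}" for p, r in bad.items())
        )
    return report


# ---------------------------------------------------------------------------
# derived quantities


def expected_counts_draws(fit: AbundanceFit) -> np.ndarray:
    """Per-draw expected count surface mu[draw, stop, year] at the
    reference observer.

    Observer, first-year, and noise effects are set to zero so stop-years
    are comparable across observers; the route effect is retained because
    it is part of the stop's expected abundance.
    """
    b0 = fit.stacked("b0")  # (D, S)
    b1 = fit.stacked("b1")
    route = fit.stacked("route")[:, fit.data.stop_route]  # (D, S)
    tcs = np.array(fit.data.years, dtype=float) - fit.data.tbar  # (T,)
    lp = (b0 + route)[:, :, None] + b1[:, :, None] * tcs[None, None, :]
    return np.exp(np.minimum(lp, _CAP))


def adjusted_counts(fit: AbundanceFit) -> pd.DataFrame:
    """Posterior mean / median / 95% interval of mu_it per stop-year."""
    mu = expected_counts_draws(fit)  # (D, S, T)
    mean = mu.mean(axis=0)
    med = np.median(mu, axis=0)
    lo = np.quantile(mu, 0.025, axis=0)
    hi = np.quantile(mu, 0.975, axis=0)
    rows = []
    for i, s in enumerate(fit.data.stops):
        for j, y in enumerate(fit.data.years):
            rows.append({"stop": s, "year": y, "mean": mean[i, j],
                         "median": med[i, j], "lo": lo[i, j], "hi": hi[i, j]})
    return pd.DataFrame(rows)


def percent_annual_change(first: float, last: float, n_years: int,
                          convention: str = "intervals") -> float:
    """Percent annual change from first- to last-year expected counts.

    ``convention='intervals'`` raises the ratio to ``1/(n_years - 1)``
    (the number of year-to-year intervals); ``'years'`` uses ``1/n_years``.
    """
    if first <= 0:
        raise ValueError("first-year expected count must be positive")
    k = n_years - 1 if convention == "intervals" else n_years
    return 100.0 * ((last / first) ** (1.0 / k) - 1.0)


def trend_summary(fit: AbundanceFit, convention: str = "intervals",
                  trend_kind: str = "hierarchical_mean") -> dict:
    """Trend coefficient and percent annual change with 95% intervals.

    The trend coefficient is the posterior of the mean of stop-level
    slopes (``trend_kind='hierarchical_mean'``) or of the taxon-level
    hyper-mean (``'hyper'``).  Percent annual change is computed per draw
    from the ratio of mean expected counts in the last and first years.
    """
    if trend_kind == "hierarchical_mean":
        trend = fit.stacked("b1").mean(axis=1)
    elif trend_kind == "hyper":
        trend = fit.stacked("mu1")
    else:
        raise ValueError(f"unknown trend_kind {trend_kind!r}")
    mu = expected_counts_draws(fit)
    e_first = mu[:, :, 0].mean(axis=1)
    e_last = mu[:, :, -1].mean(axis=1)
    ok = e_first > 0
    n_excluded = int((~ok).sum())
    k = len(fit.data.years) - 1 if convention == "intervals" else len(fit.data.years)
    pct = 100.0 * ((e_last[ok] / e_first[ok]) ** (1.0 / k) - 1.0)

    def ci(x):
        return (float(np.mean(x)), float(np.quantile(x, 0.025)),
                float(np.quantile(x, 0.975)))

    tm, tlo, thi = ci(trend)
    pm, plo, phi = ci(pct)
    return {
        "trend_mean": tm, "trend_lo": tlo, "trend_hi": thi,
        "trend_significant": bool(tlo > 0 or thi < 0),
        "pct_change_mean": pm, "pct_change_lo": plo, "pct_change_hi": phi,
        "pct_change_significant": bool(plo > 0 or phi < 0),
        "n_excluded_draws": n_excluded,
    }


def draws_frame(fit: AbundanceFit) -> pd.DataFrame:
    """Scalar posterior draws in long columnar form (chain, draw, value),
    suitable for persisting as CSV."""
    frames = []
    for name, arr in fit.draws.items():
        if arr.ndim != 2:
            continue
        m, n = arr.shape
        frames.append(pd.DataFrame({
            "parameter": name,
            "chain": np.repeat(np.arange(m), n),
            "draw": np.tile(np.arange(n), m),
            "value": arr.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def save_draws(fit: AbundanceFit, path) -> None:
    """Persist the scalar draws as CSV."""
    draws_frame(fit).to_csv(path, index=False, float_format="%.10g")


def summarize_abundance(fit: AbundanceFit, taxon: str,
                        convention: str = "intervals") -> dict:
    """One summary-table row: detections, mean adjusted abundance ± sd,
    trend and percent annual change with significance flags."""
    mu = expected_counts_draws(fit)
    grand = mu.mean(axis=(1, 2))  # per-draw mean over stop-years
    tr = trend_summary(fit, convention=convention)
    return {
        "taxon": taxon,
        "mean_adjusted_abundance": float(grand.mean()),
        "sd_adjusted_abundance": float(grand.std(ddof=1)),
        "degenerate": fit.degenerate,
        **tr,
    }
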