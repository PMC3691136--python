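"""Threshold Indicator Taxa Analysis (TITAN) and loess screening.

TITAN locates, for each taxon, the value of an environmental gradient
that best splits the samples into two groups, as measured by the
indicator value (IndVal) of Dufrêne & Legendre::

    IndVal_g = 100 * (mean abundance in g / sum of group mean abundances)
                   * (fraction of g's samples where the taxon occurs)

Candidate change points are the midpoints between consecutive distinct
sorted gradient values with at least ``min_split`` samples on each side.
At each candidate the larger-side IndVal is standardised against a
label-permutation null (z score); the selected change point maximises z.
Taxa whose IndVal peaks in the low-gradient group are negative (z-)
responders, those peaking in the high group positive (z+) responders.

Uncertainty and indicator quality come from resampling the samples with
replacement: *purity* is the fraction of bootstrap replicates whose
response direction matches the observed one, *reliability* the fraction
whose IndVal permutation p-value is at or below the stated level, and the
5/50/95% quantiles of the replicate change points bound the threshold
location.  Sharp (threshold-like) responses give narrow quantile
intervals; gradual responses give broad ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_EPS = 1e-6  # occurrence cutoff for real-valued (adjusted) abundances


@dataclass
class TitanConfig:
    min_split: int = 5
    n_permutations: int = 250
    n_bootstrap: int = 250
    p_threshold: float = 0.05
    purity_threshold: float = 0.95
    reliability_threshold: float = 0.95
    cp_quantiles: tuple[float, float] = (0.05, 0.95)
    max_boot_retries: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_split < 3:
            raise ValueError("min_split must be >= 3")
        for t in (self.p_threshold, self.purity_threshold,
                  self.reliability_threshold):
            if not 0.0 < t <= 1.0:
                raise ValueError("thresholds must be in (0, 1]")


@dataclass
class ChangePointResult:
    taxon: str
    variable: str
    extent: float | str
    change_point: float
    direction: str  # 'z-' (low-side indicator) or 'z+'
    z: float
    p_value: float
    indval: float
    purity: float = np.nan
    reliability: float = np.nan
    cp05: float = np.nan
    cp50: float = np.nan
    cp95: float = np.nan
    degenerate: bool = False

    def is_indicator(self, config: TitanConfig) -> bool:
        return (self.purity >= config.purity_threshold
                and self.reliability >= config.reliability_threshold)


# ---------------------------------------------------------------------------
# IndVal


def indval(abund: np.ndarray, right: np.ndarray) -> tuple[float, float]:
    """Indicator values (left group, right group), each in [0, 100].

    ``right`` is a boolean mask assigning samples to the high-gradient
    group; occurrence means abundance above a small epsilon.
    """
    abund = np.asarray(abund, dtype=float)
    right = np.asarray(right, dtype=bool)
    if not right.any() or right.all():
        raise ValueError("both groups must be non-empty")
    out = []
    means = [abund[~right].mean(), abund[right].mean()]
    denom = means[0] + means[1]
    for g, mask in enumerate((~right, right)):
        if denom == 0:
            out.append(0.0)
            continue
        ra = means[g] / denom
        rf = float(np.mean(abund[mask] > _EPS))
        out.append(100.0 * ra * rf)
    return out[0], out[1]


def _indval_curves(a_sorted: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """IndVal for both sides at every split, vectorised.

    ``a_sorted``: abundances ordered by gradient, shape (..., n).
    ``ks``: left-group sizes (split after rank k).  Returns an array of
    shape (..., len(ks), 2) with [left, right] IndVal.
    """
    a = np.asarray(a_sorted, dtype=float)
    n = a.shape[-1]
    csum = np.cumsum(a, axis=-1)
    cocc = np.cumsum(a > _EPS, axis=-1)
    tot = csum[..., -1:]
    totocc = cocc[..., -1:]
    k = ks  # (m,)
    lm = csum[..., k - 1] / k
    rm = (tot - csum[..., k - 1]) / (n - k)
    denom = lm + rm
    with np.errstate(invalid="ignore", divide="ignore"):
        ra_l = np.where(denom > 0, lm / denom, 0.0)
        ra_r = np.where(denom > 0, rm / denom, 0.0)
    rf_l = cocc[..., k - 1] / k
    rf_r = (totocc - cocc[..., k - 1]) / (n - k)
    return np.stack([100.0 * ra_l * rf_l, 100.0 * ra_r * rf_r], axis=-1)


def _candidates(x_sorted: np.ndarray, min_split: int) -> tuple[np.ndarray, np.ndarray]:
    """Left-group sizes and midpoint locations of the admissible splits."""
    n = len(x_sorted)
    # splits after rank k (1-based count of left samples), between
    # consecutive *distinct* x values, with >= min_split on both sides
    ks, mids = [], []
    for k in range(min_split, n - min_split + 1):
        if x_sorted[k] > x_sorted[k - 1]:
            ks.append(k)
            mids.append(0.5 * (x_sorted[k - 1] + x_sorted[k]))
    return np.array(ks, dtype=int), np.array(mids)


def _scan(x: np.ndarray, a: np.ndarray, config: TitanConfig,
          rng: np.random.Generator) -> dict:
    """Full change-point scan for one taxon on one gradient.

    Returns the z-maximising candidate with its permutation z and p.
    """
    order = np.argsort(x, kind="stable")
    xs, asort = np.asarray(x, float)[order], np.asarray(a, float)[order]
    ks, mids = _candidates(xs, config.min_split)
    if len(ks) == 0:
        raise ValueError(
            f"too few samples for min_split={config.min_split}"
        )
    obs = _indval_curves(asort, ks)  # (m, 2)
    perm = rng.permuted(
        np.broadcast_to(asort, (config.n_permutations, len(asort))), axis=1
    )
    pcurves = _indval_curves(perm, ks)  # (P, m, 2)
    pmean = pcurves.mean(axis=0)
    psd = pcurves.std(axis=0, ddof=1)
    side = np.argmax(obs, axis=1)  # 0 = left, 1 = right
    ar = np.arange(len(ks))
    obs_side = obs[ar, side]
    mean_side = pmean[ar, side]
    sd_side = psd[ar, side]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd_side > 0, (obs_side - mean_side) / sd_side, 0.0)
    best = int(np.argmax(z))  # argmax takes the first (smallest-x) tie
    degenerate = sd_side[best] == 0
    if degenerate:
        p = 1.0
    else:
        # each permutation contributes its own maximum IndVal over
        # candidates and sides, so the p-value accounts for the
        # change-point search (otherwise noise taxa look significant)
        perm_max = pcurves.max(axis=(1, 2))
        p = (1.0 + np.sum(perm_max >= obs_side[best])) / (config.n_permutations + 1.0)
    return {
        "change_point": float(mids[best]),
        "side": int(side[best]),
        "z": float(z[best]),
        "p_value": float(p),
        "indval": float(obs_side[best]),
        "degenerate": bool(degenerate),
    }


def find_change_point(x: np.ndarray, a: np.ndarray, config: TitanConfig,
                      rng: np.random.Generator | None = None) -> dict:
    """Candidate change point maximising the permutation z score.

    Returns a dict with the change point, the winning side (0 = left /
    negative responder, 1 = right / positive responder), the z score, the
    permutation p-value and the observed IndVal.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _scan(np.asarray(x), np.asarray(a), config, rng)


def permutation_z(x: np.ndarray, a: np.ndarray, candidate_k: int,
                  config: TitanConfig,
                  rng: np.random.Generator | None = None) -> dict:
    """Permutation z score and p-value at one fixed split.

    ``candidate_k`` is the left-group size of the split (samples sorted by
    gradient).  The larger-side IndVal is standardised by the mean/sd of
    its permutation null; p uses the add-one estimator.  A zero
    permutation sd yields z = 0, p = 1 and a degenerate flag.
    """
    if config.n_permutations < 50:
        raise ValueError("n_permutations must be >= 50")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    order = np.argsort(x, kind="stable")
    asort = np.asarray(a, float)[order]
    ks = np.array([candidate_k])
    obs = _indval_curves(asort, ks)[0]  # (2,)
    side = int(np.argmax(obs))
    perm = rng.permuted(
        np.broadcast_to(asort, (config.n_permutations, len(asort))), axis=1
    )
    pcurves = _indval_curves(perm, ks)[:, 0, :]  # (P, 2)
    same_side = pcurves[:, side]
    sd = same_side.std(ddof=1)
    if sd == 0:
        return {"z": 0.0, "p_value": 1.0, "side": side, "degenerate": True}
    z = (obs[side] - same_side.mean()) / sd
    # the observed statistic is the larger-side IndVal, so the null
    # must also take each permutation's larger side (otherwise the
    # data-driven side choice inflates the rejection rate)
    p = (1.0 + np.sum(pcurves.max(axis=1) >= obs[side])) \
        / (config.n_permutations + 1.0)
    return {"z": float(z), "p_value": float(p), "side": side,
            "degenerate": False}


def bootstrap_diagnostics(x: np.ndarray, a: np.ndarray, config: TitanConfig,
                          rng: np.random.Generator | None = None,
                          observed: dict | None = None) -> dict:
    """Purity, reliability and change-point quantiles by bootstrap.

    Samples are resampled with replacement; each replicate reruns the
    full change-point scan with fresh permutations.  Replicates whose
    resample cannot honour ``min_split`` are redrawn up to
    ``max_boot_retries`` times.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = np.asarray(x, float)
    a = np.asarray(a, float)
    if observed is None:
        observed = _scan(x, a, config, rng)
    n = len(x)
    sides = np.empty(config.n_bootstrap, dtype=int)
    ps = np.empty(config.n_bootstrap)
    cps = np.empty(config.n_bootstrap)
    for bidx in range(config.n_bootstrap):
        for attempt in range(config.max_boot_retries):
            idx = rng.integers(0, n, n)
            xs = np.sort(x[idx])
            if len(_candidates(xs, config.min_split)[0]) > 0:
                break
        else:
            raise RuntimeError("bootstrap resample cannot honour min_split")
        res = _scan(x[idx], a[idx], config, rng)
        sides[bidx], ps[bidx], cps[bidx] = res["side"], res["p_value"], res["change_point"]
    qlo, qhi = config.cp_quantiles
    return {
        "purity": float(np.mean(sides == observed["side"])),
        "reliability": float(np.mean(ps <= config.p_threshold)),
        "cp05": float(np.quantile(cps, qlo)),
        "cp50": float(np.quantile(cps, 0.5)),
        "cp95": float(np.quantile(cps, qhi)),
        "observed": observed,
    }


def run_titan(samples: pd.DataFrame, x_col: str, taxa: list[str],
              config: TitanConfig, extent: float | str = "",
              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """TITAN for every taxon on one gradient; one result row per taxon."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = samples[x_col].to_numpy(dtype=float)
    rows = []
    for taxon in taxa:
        a = samples[taxon].to_numpy(dtype=float)
        obs = _scan(x, a, config, rng)
        boot = bootstrap_diagnostics(x, a, config, rng, observed=obs)
        rows.append(ChangePointResult(
            taxon=taxon, variable=x_col, extent=extent,
            change_point=obs["change_point"],
            direction="z-" if obs["side"] == 0 else "z+",
            z=obs["z"], p_value=obs["p_value"], indval=obs["indval"],
            purity=boot["purity"], reliability=boot["reliability"],
            cp05=boot["cp05"], cp50=boot["cp50"], cp95=boot["cp95"],
            degenerate=obs["degenerate"],
        ).__dict__)
    return pd.DataFrame(rows)


def classify_indicators(results: pd.DataFrame,
                        config: TitanConfig) -> pd.DataFrame:
    """Keep pure and reliable indicator taxa, ordered by change point.

    Adds an ``is_indicator`` flag to all rows and returns the filtered,
    plot-ready table (taxon, variable, extent, cp with quantiles, z,
    direction).
    """
    out = results.copy()
    out["is_indicator"] = ((out["purity"] >= config.purity_threshold)
                           & (out["reliability"] >= config.reliability_threshold))
    kept = out[out["is_indicator"]].sort_values(
        ["change_point", "taxon"]).reset_index(drop=True)
    return kept


# ---------------------------------------------------------------------------
# loess screening


def loess_fit(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray,
              span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Locally weighted polynomial regression (tricube weights).

    For each evaluation point the nearest ``span`` fraction of samples is
    fit with a weighted polynomial of ``degree``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    q = max(degree + 1, int(np.ceil(span * n)))
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(np.asarray(x_eval, float)):
        d = np.abs(x - x0)
        cutoff = np.partition(d, q - 1)[q - 1]
        w = np.clip(1 - (d / max(cutoff, 1e-300)) ** 3, 0, 1) ** 3
        use = w > 0
        X = np.vander(x[use] - x0, degree + 1, increasing=True)
        Wh = np.sqrt(w[use])
        beta, *_ = np.linalg.lstsq(X * Wh[:, None], y[use] * Wh, rcond=None)
        out[i] = beta[0]
    return out


def loess_screen(x: np.ndarray, y: np.ndarray, span: float = 0.75,
                 degree: int = 2, cutoff: float = 0.1,
                 n_grid: int = 50) -> dict:
    """Nonlinearity screen: loess fit vs. straight line.

    The score is ``1 - SSE(loess) / SSE(linear)`` (clipped at 0), i.e. the
    share of linear-fit residual variation the loess curve removes; the
    flag trips when the score exceeds ``cutoff``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 10:
        raise ValueError("need at least 10 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate gradient: all x equal")
    yhat = loess_fit(x, y, x, span=span, degree=degree)
    sse_loess = float(np.sum((y - yhat) ** 2))
    slope, icept = np.polyfit(x, y, 1)
    sse_lin = float(np.sum((y - (slope * x + icept)) ** 2))
    score = 0.0 if sse_lin == 0 else max(0.0, 1.0 - sse_loess / sse_lin)
    grid = np.linspace(x.min(), x.max(), n_grid)
    return {
        "score": score,
        "nonlinear": score > cutoff,
        "grid_x": grid,
        "grid_fit": loess_fit(x, y, grid, span=span, degree=degree),
    }
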