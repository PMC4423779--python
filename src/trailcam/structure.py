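"""Rank abundance distributions, model fitting and rank-shift statistics.

Five classical RAD models are fitted to survey-level relative abundances by
least squares, and compared on the deviance criterion — the sum of squared
deviations between observed and predicted abundances (smaller is better).
Dominance/diversity curves are conventionally drawn and fitted on the log
abundance scale, so the default deviance is computed on log abundances;
``scale="identity"`` switches to the raw abundance scale.  With ``J`` the
total abundance, ``S`` the number of species and ``r`` the rank:

    null (broken stick):  a_r = (J/S) * sum_{k=r}^{S} 1/k
    preemption:           a_r = J * alpha (1-alpha)^(r-1) / (1 - (1-alpha)^S)
    lognormal:            a_r = exp(mu + sigma * z_r),  z_r = Phi^-1((S-r+0.5)/S)
    Zipf:                 a_r = J * p1 * r^gamma            (gamma < 0)
    Zipf-Mandelbrot:      a_r = J * c * (r + beta)^gamma    (beta > 0, gamma < 0)

The mean absolute rank shift (MARS) between two surveys of the same species
set is the mean over species of |rank in survey A - rank in survey B|, with
average ranks for tied abundances.  Its departure from zero is assessed with
a one-sample Wilcoxon signed rank test on the absolute shifts (exact null
distribution by sign-pattern enumeration for n <= 15, normal approximation
with tie and continuity corrections otherwise).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

RAD_MODELS = ("null", "preemption", "lognormal", "zipf", "zipf_mandelbrot")

_N_PARAMS = {"null": 0, "preemption": 1, "lognormal": 2, "zipf": 2,
             "zipf_mandelbrot": 3}


@dataclass
class RAD:
    """A ranked abundance vector (nonincreasing) with its species labels."""

    species_ids: list[str]
    abundances: np.ndarray

    def __post_init__(self):
        self.abundances = np.asarray(self.abundances, dtype=float)
        if np.any(np.diff(self.abundances) > 0):
            raise ValueError("abundances must be sorted nonincreasing")
        if np.any(self.abundances <= 0):
            raise ValueError("abundances must be positive")

    @property
    def n(self) -> int:
        return len(self.abundances)

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, self.n + 1)

    @property
    def total(self) -> float:
        """J: total abundance."""
        return float(self.abundances.sum())


@dataclass
class RADFit:
    model: str
    params: dict
    predicted: np.ndarray
    deviance: float
    success: bool = True

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.model]


@dataclass
class RankShiftResult:
    n: int
    abs_shifts: pd.Series
    mars: float
    v: float
    p_value: float


def build_rad(survey_rai, species_subset=None) -> RAD:
    """Build a RAD from survey-level RAIs, optionally restricted to a subset.

    ``survey_rai`` is either a Series mapping species_id -> RAI or a frame
    with ``species_id`` and ``rai`` columns (one survey).  Subset species with
    zero RAI are dropped with a warning.  Ties keep stable input order.
    """
    if isinstance(survey_rai, pd.DataFrame):
        ser = survey_rai.set_index("species_id")["rai"]
    else:
        ser = pd.Series(survey_rai)
    if species_subset is not None:
        missing = set(species_subset) - set(ser.index)
        if missing:
            raise ValueError(f"subset species absent from table: {sorted(missing)}")
        ser = ser.loc[list(species_subset)]
    zero = ser[ser <= 0]
    if len(zero):
        warnings.warn(f"excluding {len(zero)} zero-abundance species from RAD: "
                      f"{sorted(zero.index)[:5]}")
        ser = ser[ser > 0]
    order = np.argsort(-ser.to_numpy(), kind="stable")
    return RAD([ser.index[i] for i in order], ser.to_numpy()[order])


def select_structure_species(survey_rai_table: pd.DataFrame, season: str | None = None,
                             min_events: int = 5,
                             detected_rule: str = "common") -> list[str]:
    """Species entering the structure analyses.

    A species qualifies when it was detected by both placement types and has
    at least ``min_events`` independent events.  ``detected_rule`` fixes how
    those conditions are evaluated:

    - ``"common"`` (default): detected by both placements within *every*
      season, with at least ``min_events`` events in each season — one common
      species set so ranks are comparable across seasons and placements.
    - ``"season"``: detected by both placements within ``season``; the event
      threshold applies to the species' overall (all-survey) total.
    - ``"overall"``: detection and the event threshold both pooled over all
      seasons.
    """
    t = survey_rai_table

    def both_detected(sub):
        det = sub[sub["n_events"] > 0].groupby("species_id")["placement"].nunique()
        return set(det[det >= 2].index)

    overall = t.groupby("species_id")["n_events"].sum()
    if detected_rule == "common":
        keep = None
        for s, sub in t.groupby("season"):
            season_total = sub.groupby("species_id")["n_events"].sum()
            ok = both_detected(sub) & set(season_total[season_total >= min_events].index)
            keep = ok if keep is None else keep & ok
        return sorted(keep or set())
    if detected_rule == "season":
        if season is None:
            raise ValueError("season is required under the 'season' rule")
        sub = t[t["season"] == season]
    elif detected_rule == "overall":
        sub = t
    else:
        raise ValueError(f"unknown detected_rule {detected_rule!r}")
    keep = both_detected(sub) & set(overall[overall >= min_events].index)
    return sorted(keep)


# ---------------------------------------------------------------------------
# model forms

def broken_stick(ranks: np.ndarray, J: float, S: int) -> np.ndarray:
    tail = np.cumsum(1.0 / np.arange(S, 0, -1))[::-1]  # sum_{k=r}^S 1/k
    return (J / S) * tail[ranks - 1]


def preemption_abund(ranks, J, S, alpha):
    return J * alpha * (1 - alpha) ** (ranks - 1) / (1 - (1 - alpha) ** S)


def lognormal_quantiles(S: int) -> np.ndarray:
    """z_r = Phi^-1((S - r + 0.5)/S), the rank-quantile surrogate."""
    r = np.arange(1, S + 1)
    return stats.norm.ppf((S - r + 0.5) / S)


def lognormal_abund(ranks, S, mu, sigma):
    z = lognormal_quantiles(S)
    return np.exp(mu + sigma * z[ranks - 1])


def zipf_abund(ranks, J, p1, gamma):
    return J * p1 * np.power(ranks, gamma, dtype=float)


def zipf_mandelbrot_abund(ranks, J, c, beta, gamma):
    return J * c * np.power(ranks + beta, gamma)


def _fit_ls(residual_fn, starts, bounds):
    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(residual_fn, x0, bounds=bounds,
                                         method="trf", max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    return best


def fit_rad(rad: RAD, model: str, scale: str = "log") -> RADFit:
    """Least-squares fit of one RAD model; deviance = sum of squared residuals.

    ``scale`` chooses the residual scale: ``"log"`` (default, the scale on
    which dominance/diversity curves are conventionally fitted and plotted)
    or ``"identity"`` (raw abundances).  Multi-start bounded optimisation
    guards the ill-conditioned Zipf forms; a fit that fails every start is
    returned flagged (``success=False``) with infinite deviance rather than
    raising.
    """
    if model not in RAD_MODELS:
        raise ValueError(f"unknown RAD model {model!r}")
    if scale not in ("log", "identity"):
        raise ValueError(f"unknown scale {scale!r}")
    obs = rad.abundances
    S, J, r = rad.n, rad.total, rad.ranks
    if S < _N_PARAMS[model] + 1:
        raise ValueError(f"{model}: need at least {_N_PARAMS[model] + 1} species")
    tr = np.log if scale == "log" else (lambda a: a)
    tobs = tr(obs)

    def deviance(pred):
        return float(np.sum((tobs - tr(pred)) ** 2))

    if model == "null":
        pred = broken_stick(r, J, S)
        return RADFit(model, {}, pred, deviance(pred))

    if model == "preemption":
        fn = lambda x: tr(preemption_abund(r, J, S, x[0])) - tobs
        best = _fit_ls(fn, [[a] for a in (0.05, 0.1, 0.3, 0.5, 0.7, 0.9)],
                       ([1e-9], [1 - 1e-9]))
        if best is None:
            return RADFit(model, {}, np.full(S, np.nan), np.inf, success=False)
        pred = preemption_abund(r, J, S, best.x[0])
        return RADFit(model, {"alpha": float(best.x[0])}, pred, deviance(pred))

    if model == "lognormal":
        z = lognormal_quantiles(S)
        slope, intercept = np.polyfit(z, np.log(obs), 1)
        fn = lambda x: tr(lognormal_abund(r, S, x[0], x[1])) - tobs
        starts = [[intercept, max(slope, 1e-3)],
                  [np.log(obs.mean()), 1.0], [np.log(obs.mean()), 2.0]]
        best = _fit_ls(fn, starts, ([-np.inf, 0.0], [np.inf, np.inf]))
        if best is None:
            return RADFit(model, {}, np.full(S, np.nan), np.inf, success=False)
        pred = lognormal_abund(r, S, *best.x)
        return RADFit(model, {"mu": float(best.x[0]), "sigma": float(best.x[1])},
                      pred, deviance(pred))

    if model == "zipf":
        g0, logp0 = np.polyfit(np.log(r), np.log(obs / J), 1)
        fn = lambda x: tr(zipf_abund(r, J, x[0], x[1])) - tobs
        starts = [[min(max(np.exp(logp0), 1e-6), 5.0), max(min(g0, -1e-3), -4.9)],
                  [obs[0] / J, -1.0], [obs[0] / J, -0.5], [obs[0] / J, -2.0]]
        best = _fit_ls(fn, starts, ([1e-12, -5.0], [10.0, -1e-9]))
        if best is None:
            return RADFit(model, {}, np.full(S, np.nan), np.inf, success=False)
        pred = zipf_abund(r, J, *best.x)
        return RADFit(model, {"p1": float(best.x[0]), "gamma": float(best.x[1])},
                      pred, deviance(pred))

    # zipf_mandelbrot
    zf = fit_rad(rad, "zipf", scale=scale)
    p1 = zf.params.get("p1", obs[0] / J)
    g = zf.params.get("gamma", -1.0)
    fn = lambda x: tr(zipf_mandelbrot_abund(r, J, x[0], x[1], x[2])) - tobs
    starts = [[p1 * (1 + b) ** (-g), b, g]
              for b in (0.01, 0.1, 1.0, 5.0, 10.0, 30.0, 80.0)]
    best = _fit_ls(fn, starts, ([1e-12, 1e-9, -5.0], [1e6, 100.0, -1e-9]))
    if best is None:
        return RADFit(model, {}, np.full(S, np.nan), np.inf, success=False)
    pred = zipf_mandelbrot_abund(r, J, *best.x)
    return RADFit(model, {"c": float(best.x[0]), "beta": float(best.x[1]),
                          "gamma": float(best.x[2])},
                  pred, deviance(pred))


def fit_all_rad(rad: RAD, models=RAD_MODELS, scale: str = "log") -> list[RADFit]:
    return [fit_rad(rad, m, scale=scale) for m in models]


def select_rad_model(fits: list[RADFit]) -> RADFit:
    """The fit with minimal deviance; ties broken in favour of fewer parameters."""
    ok = [f for f in fits if f.success and np.isfinite(f.deviance)]
    if not ok:
        raise ValueError("no successful RAD fit to select from")
    return min(ok, key=lambda f: (f.deviance, f.n_params))


# ---------------------------------------------------------------------------
# rank shifts

def ranks_from_rai(rai: pd.Series) -> pd.Series:
    """Abundance ranks (1 = most abundant), average ranks for ties."""
    return pd.Series(stats.rankdata(-rai.to_numpy(), method="average"),
                     index=rai.index)


def mars(ranks_a: pd.Series, ranks_b: pd.Series) -> RankShiftResult:
    """Mean absolute rank shift between two rankings of the same species set.

    The attached Wilcoxon signed rank test treats the absolute shifts as a
    one-sample location problem against zero; because the shifts are
    nonnegative by construction, V equals the full rank sum of the nonzero
    shifts and the test is one-sided in nature.
    """
    a, b = pd.Series(ranks_a), pd.Series(ranks_b)
    if set(a.index) != set(b.index):
        raise ValueError("rankings must cover the same species set")
    b = b.loc[a.index]
    shifts = (a - b).abs()
    v, p = signed_rank_test(shifts.to_numpy())
    return RankShiftResult(n=len(shifts), abs_shifts=shifts,
                           mars=float(shifts.mean()), v=v, p_value=p)


def _signed_rank_exact_cdf(doubled_ranks: np.ndarray) -> np.ndarray:
    """PMF of 2*W+ under the null, by polynomial convolution over sign patterns.

    Ranks are doubled so average (half-integer) ranks convolve on an integer
    lattice; the returned array has mass at 0..2*sum(ranks) and total 2^n.
    """
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r2 in doubled_ranks:
        r2 = int(r2)
        new = dist.copy()
        new[r2:] += dist[:len(dist) - r2]
        dist = new
    return dist


def signed_rank_test(x, mu: float = 0.0, exact_limit: int = 15) -> tuple[float, float]:
    """One-sample Wilcoxon signed rank test of symmetry about ``mu``.

    Zero differences are dropped; absolute differences receive average ranks;
    ``V`` is the sum of ranks of positive differences.  The two-sided p-value
    uses the exact null distribution (enumeration of sign patterns, handling
    ties) when the nonzero count is at most ``exact_limit``, else a normal
    approximation with tie and continuity corrections.

    Returns ``(V, p_value)``; an all-zero sample is degenerate (V=0, p=1).
    """
    d = np.asarray(x, dtype=float) - mu
    if d.size == 0:
        raise ValueError("empty sample")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d), method="average")
    v = float(ranks[d > 0].sum())
    if n <= exact_limit:
        r2 = np.round(ranks * 2).astype(int)
        dist = _signed_rank_exact_cdf(r2)
        total = dist.sum()
        v2 = int(round(v * 2))
        p_le = dist[: v2 + 1].sum() / total
        p_ge = dist[v2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return v, float(p)
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_corr = np.sum(counts ** 3 - counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    if var <= 0:
        return v, 1.0
    diff = v - mean
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(var)
    return v, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def signed_rank_null_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and PMF of W+ for an untied sample of size ``n`` (exact null)."""
    dist = _signed_rank_exact_cdf(2 * np.arange(1, n + 1))
    support = np.arange(len(dist)) / 2.0
    keep = dist > 0
    return support[keep], dist[keep] / dist.sum()
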