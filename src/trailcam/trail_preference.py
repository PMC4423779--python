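"""Species-level trail preference: paired location shifts and trait models.

For each species, station-level RAIs at random and trail placements are
compared within sampling pairs (one random and one trail camera per grid
cell).  The paired differences d = RAI(random) - RAI(trail) are summarised
by a Wilcoxon signed rank test, the Hodges-Lehmann pseudomedian of d (the
"location shift") and its 95% signed-rank confidence interval.  A species
whose interval lies entirely below zero — trail RAI significantly higher —
scores 1, all others 0.

The binary scores are then modelled as a function of species traits
(trophic category, log body mass, sociality) with a binomial GLM (logit
link); candidate predictor subsets are compared by AIC.  For a single
categorical predictor the back-transformed fitted probabilities equal the
per-category score proportions exactly (the saturated one-factor identity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .structure import _signed_rank_exact_cdf, signed_rank_test

GLM_CANDIDATES = {
    "intercept_only": "score ~ 1",
    "trophic": "score ~ trophic_category",
    "log_mass": "score ~ log_mass",
    "social": "score ~ social",
    "trophic+log_mass": "score ~ trophic_category + log_mass",
    "trophic*log_mass": "score ~ trophic_category * log_mass",
    "trophic+social": "score ~ trophic_category + social",
    "log_mass+social": "score ~ log_mass + social",
    "trophic+log_mass+social": "score ~ trophic_category + log_mass + social",
}


@dataclass
class PairedTestResult:
    species_id: str
    n_pairs: int                 # pairs remaining after zero-difference removal
    location_shift: float        # Hodges-Lehmann pseudomedian of random - trail
    ci_low: float
    ci_high: float
    v: float
    p_value: float
    score: int
    low_power: bool = False


@dataclass
class GLMFit:
    name: str
    formula: str
    coefficients: pd.Series
    se: pd.Series
    log_likelihood: float
    aic: float
    fitted_probabilities: pd.DataFrame
    n_params: int
    separation: bool = False
    result: object = field(default=None, repr=False)


def hodges_lehmann(d: np.ndarray) -> float:
    """Pseudomedian: median of the Walsh averages (d_i + d_j)/2, i <= j."""
    d = np.asarray(d, dtype=float)
    w = _walsh_averages(d)
    return float(np.median(w))


def _walsh_averages(d: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(len(d))
    return np.sort((d[i] + d[j]) / 2.0)


def _signed_rank_ci(d: np.ndarray, alpha: float = 0.05,
                    exact_limit: int = 25) -> tuple[float, float]:
    """Signed-rank confidence interval for the pseudomedian.

    The interval is formed from order statistics of the sorted Walsh
    averages: with M = n(n+1)/2 averages and k the largest integer such that
    P(W+ <= k) <= alpha/2 under the untied exact null (normal approximation
    beyond ``exact_limit``), the interval is (W_(k+1), W_(M-k)).
    """
    n = len(d)
    w = _walsh_averages(d)
    M = len(w)
    if n <= exact_limit:
        dist = _signed_rank_exact_cdf(2 * np.arange(1, n + 1))
        cdf = np.cumsum(dist) / dist.sum()        # index = 2 * W+
        probs = cdf[::2]                          # integer W+ values 0..M
        k = int(np.searchsorted(probs, alpha / 2.0, side="right") - 1)
        k = max(k, -1)
    else:
        mean = n * (n + 1) / 4.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        from scipy.stats import norm
        k = int(np.floor(mean + norm.ppf(alpha / 2.0) * sd))
        k = max(k, -1)
    lo = w[k + 1] if k + 1 < M else w[0]
    hi = w[M - k - 2] if M - k - 2 >= 0 else w[-1]
    return float(lo), float(hi)


def paired_location_shift(rai_random, rai_trail, alpha: float = 0.05,
                          species_id: str = "", min_pairs: int = 5) -> PairedTestResult:
    """Paired comparison of one species' station RAIs across placement types.

    Inputs are aligned by sampling pair (cell).  Zero differences are dropped
    before ranking, per signed-rank convention.  With fewer than
    ``min_pairs`` informative pairs the result is flagged low-power and
    scored 0 regardless of the interval.
    """
    r = np.asarray(rai_random, dtype=float)
    t = np.asarray(rai_trail, dtype=float)
    if r.shape != t.shape:
        raise ValueError("paired RAI vectors differ in length")
    d = r - t
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return PairedTestResult(species_id, 0, 0.0, 0.0, 0.0, 0.0, 1.0,
                                score=0, low_power=True)
    v, p = signed_rank_test(d)
    shift = hodges_lehmann(d)
    lo, hi = _signed_rank_ci(d, alpha=alpha)
    low_power = n < min_pairs
    score = int(hi < 0 and not low_power)
    return PairedTestResult(species_id, n, shift, lo, hi, v, p, score,
                            low_power=low_power)


def score_species(results: list[PairedTestResult]) -> pd.DataFrame:
    """Assemble per-species scores; reports the trail-bias direction check.

    The returned frame carries one row per species; its ``attrs`` record the
    number of species scored 1 and whether any species was significantly
    *more* abundant at random placements (interval entirely above zero).
    """
    df = pd.DataFrame([{
        "species_id": r.species_id, "n_pairs": r.n_pairs,
        "location_shift": r.location_shift, "ci_low": r.ci_low,
        "ci_high": r.ci_high, "p_value": r.p_value, "score": r.score,
        "low_power": r.low_power,
    } for r in results])
    df.attrs["n_scored_1"] = int(df["score"].sum()) if len(df) else 0
    df.attrs["any_random_preference"] = bool(
        ((df["ci_low"] > 0) & ~df["low_power"]).any()) if len(df) else False
    return df


def _prepare_glm_frame(scores, traits: pd.DataFrame) -> pd.DataFrame:
    data = traits.copy()
    if isinstance(scores, pd.Series):
        data = data.set_index("species_id")
        data["score"] = scores
        data = data.reset_index()
    else:
        data["score"] = np.asarray(scores, dtype=float)
    data["log_mass"] = np.log(data["body_mass_kg"].astype(float))
    return data.dropna(subset=["score"])


def fit_binomial_glm(scores, traits: pd.DataFrame, formula: str = "trophic") -> GLMFit:
    """Binomial (logit) GLM of trail-preference scores on species traits.

    ``formula`` names one of the candidate predictor subsets (see
    ``GLM_CANDIDATES``) or gives a patsy formula directly.  Treatment coding
    with the first category as reference.  Complete separation is flagged
    when any |coefficient| exceeds 15 on the logit scale.
    """
    fstr = GLM_CANDIDATES.get(formula, formula)
    data = _prepare_glm_frame(scores, traits)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.glm(fstr, data=data, family=sm.families.Binomial())
        res = model.fit(maxiter=100)
    sep = bool(np.any(np.abs(res.params.to_numpy()) > 15))
    fitted = _category_probabilities(res, data, fstr)
    return GLMFit(name=formula, formula=fstr,
                  coefficients=res.params, se=res.bse,
                  log_likelihood=float(res.llf), aic=float(res.aic),
                  fitted_probabilities=fitted, n_params=len(res.params),
                  separation=sep, result=res)


def _category_probabilities(res, data: pd.DataFrame, fstr: str) -> pd.DataFrame:
    """Back-transformed fitted probabilities with Wald 95% CIs (link scale)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = res.get_prediction(data)
    link = res.model.family.link
    eta = link(pred.predicted_mean)
    # delta-method SE on the probability scale back to link scale
    with np.errstate(divide="ignore", invalid="ignore"):
        se_eta = pred.se_mean / np.abs(link.inverse_deriv(eta))
    lo = link.inverse(eta - 1.96 * se_eta)
    hi = link.inverse(eta + 1.96 * se_eta)
    out = data[["species_id"]].copy() if "species_id" in data else pd.DataFrame(
        index=data.index)
    if "trophic_category" in fstr:
        out["trophic_category"] = data["trophic_category"].to_numpy()
    out["fitted_probability"] = pred.predicted_mean
    out["ci_low"] = lo
    out["ci_high"] = hi
    return out


def select_glm(scores, traits: pd.DataFrame,
               candidates: dict[str, str] | None = None) -> tuple[GLMFit, pd.DataFrame]:
    """Fit every candidate trait model and select the lowest AIC.

    Returns ``(best_fit, aic_table)``; ties in AIC go to the model with
    fewer parameters.
    """
    cands = candidates or GLM_CANDIDATES
    fits = []
    for name in cands:
        try:
            fits.append(fit_binomial_glm(scores, traits, name))
        except Exception as exc:        # singular design etc.
            warnings.warn(f"GLM candidate {name!r} failed: {exc}")
    if not fits:
        raise ValueError("all GLM candidates failed")
    table = pd.DataFrame({
        "model": [f.name for f in fits],
        "n_params": [f.n_params for f in fits],
        "log_likelihood": [f.log_likelihood for f in fits],
        "aic": [f.aic for f in fits],
        "separation": [f.separation for f in fits],
    }).sort_values(["aic", "n_params"]).reset_index(drop=True)
    best = min(fits, key=lambda f: (round(f.aic, 10), f.n_params))
    return best, table
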