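"""Richness accumulation, richness estimation and compositional comparison.

Sample-based rarefaction treats the camera station as the sampling unit: the
expected number of species detected in ``t`` of the ``T`` stations, averaged
over orderings, is the classical hypergeometric form

    E[S(t)] = S_obs - sum_i C(T - Y_i, t) / C(T, t)

with ``Y_i`` the number of stations at which species ``i`` was detected.
Confidence bands follow a station bootstrap: stations are resampled with
replacement and distinct species accumulated along each resampled ordering;
the across-replicate mean and variance at each ``t`` give mean ± 1.96 sd
bands.  Chao2 provides an incidence-based floor-corrected estimate of total
assemblage richness from the counts of species seen at exactly one and two
stations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class IncidenceMatrix:
    """Binary species × station detection matrix for one survey stratum."""

    species: list[str]
    stations: list[str]
    cells: np.ndarray                   # shape (S_obs, T), dtype bool
    effort_per_station: np.ndarray      # camera-days, shape (T,)

    @property
    def s_obs(self) -> int:
        return len(self.species)

    @property
    def n_stations(self) -> int:
        return len(self.stations)

    @property
    def total_effort(self) -> float:
        return float(self.effort_per_station.sum())

    @property
    def incidence_freq(self) -> np.ndarray:
        """Y_i: number of stations detecting each species."""
        return self.cells.sum(axis=1)


@dataclass
class AccumulationCurve:
    t_values: np.ndarray
    effort_days: np.ndarray
    mean_richness: np.ndarray
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t_values, "effort_days": self.effort_days,
            "mean_richness": self.mean_richness, "variance": self.variance,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


def build_incidence(events: pd.DataFrame, deployments: pd.DataFrame,
                    placement: str, season: str) -> IncidenceMatrix:
    """Detection matrix over the stations of one (placement, season) survey.

    Species never detected in the survey are omitted from the rows; observed
    richness is the number of rows.
    """
    from .events import effort_days

    dep = deployments[(deployments["placement"] == placement)
                      & (deployments["season"] == season)]
    if len(dep) == 0:
        raise ValueError(f"no stations match placement={placement!r}, season={season!r}")
    stations = dep["station_id"].tolist()
    ev = events[events["station_id"].isin(stations)]
    species = sorted(ev["species_id"].unique())
    cells = np.zeros((len(species), len(stations)), dtype=bool)
    st_idx = {s: j for j, s in enumerate(stations)}
    sp_idx = {s: i for i, s in enumerate(species)}
    for st, sp in ev[["station_id", "species_id"]].itertuples(index=False):
        cells[sp_idx[sp], st_idx[st]] = True
    eff = effort_days(dep).loc[stations].to_numpy()
    return IncidenceMatrix(species, stations, cells, eff)


def expected_richness(inc: IncidenceMatrix, t: int) -> float:
    """Analytic sample-based rarefaction E[S(t)] (sampling without replacement)."""
    T = inc.n_stations
    if not 0 <= t <= T:
        raise ValueError(f"t must lie in [0, {T}]")
    if t == 0:
        return 0.0
    y = inc.incidence_freq
    denom = math.comb(T, t)
    miss = sum(math.comb(T - int(yi), t) for yi in y if T - yi >= t)
    return inc.s_obs - miss / denom


def bootstrap_accumulation(inc: IncidenceMatrix, B: int = 200,
                           seed: int | None = None) -> AccumulationCurve:
    """Station bootstrap accumulation curve with 95% bands (mean ± 1.96 sd).

    Each of the ``B`` replicates draws ``T`` stations with replacement and
    accumulates the number of distinct species along the drawn order.
    Deterministic for a fixed seed.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    rng = np.random.default_rng(seed)
    T, S = inc.n_stations, inc.s_obs
    rich = np.empty((B, T))
    cells = inc.cells
    for b in range(B):
        draw = rng.integers(0, T, size=T)
        acc = np.logical_or.accumulate(cells[:, draw], axis=1)
        rich[b] = acc.sum(axis=0)
    mean = rich.mean(axis=0)
    var = rich.var(axis=0, ddof=1)
    sd = np.sqrt(var)
    t_values = np.arange(1, T + 1)
    eff = np.array([effort_axis(inc, int(t)) for t in t_values])
    return AccumulationCurve(t_values, eff, mean, var,
                             mean - 1.96 * sd, mean + 1.96 * sd,
                             meta={"B": B, "seed": seed, "s_obs": S})


def chao2(inc: IncidenceMatrix) -> float:
    """Bias-corrected Chao2 richness estimate from incidence frequencies."""
    T = inc.n_stations
    if T < 2:
        raise ValueError("Chao2 requires at least two stations")
    y = inc.incidence_freq
    q1 = int((y == 1).sum())
    q2 = int((y == 2).sum())
    return inc.s_obs + ((T - 1) / T) * q1 * (q1 - 1) / (2 * (q2 + 1))


def effort_axis(inc: IncidenceMatrix, t: int) -> float:
    """Convert a station count to camera-days via the survey's mean station effort."""
    return t * inc.total_effort / inc.n_stations


def min_overlap_effort(curve_a: AccumulationCurve, curve_b: AccumulationCurve,
                       compare_at: float | None = None) -> float | None:
    """Smallest effort beyond which the two 95% bands overlap continuously.

    Both curves are linearly interpolated onto a common effort grid spanning
    the shared effort range, up to ``compare_at`` (default: the lower of the
    two maximal efforts, the standard comparison point).  Returns ``None``
    when the bands never overlap on that grid.
    """
    lo = max(curve_a.effort_days[0], curve_b.effort_days[0])
    hi = min(curve_a.effort_days[-1], curve_b.effort_days[-1])
    if compare_at is not None:
        hi = min(hi, compare_at)
    if hi < lo:
        raise ValueError("curves have disjoint effort ranges")
    grid = np.union1d(curve_a.effort_days, curve_b.effort_days)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if compare_at is not None and compare_at not in grid:
        grid = np.append(grid, compare_at)

    def bands(c):
        return (np.interp(grid, c.effort_days, c.ci_low),
                np.interp(grid, c.effort_days, c.ci_high))

    alo, ahi = bands(curve_a)
    blo, bhi = bands(curve_b)
    overlap = (np.maximum(alo, blo) <= np.minimum(ahi, bhi))
    if not overlap[-1]:
        return None
    # walk back from the comparison point while the bands still overlap
    k = len(overlap) - 1
    while k > 0 and overlap[k - 1]:
        k -= 1
    return float(grid[k])


def jaccard_dissimilarity(species_a, species_b) -> float:
    """1 - |A ∩ B| / |A ∪ B| over two detection sets."""
    a, b = set(species_a), set(species_b)
    if not a and not b:
        raise ValueError("both species sets are empty")
    return 1.0 - len(a & b) / len(a | b)


def exclusive_species_pct(species_a, species_b,
                          denominator_species_count: int) -> float:
    """Percentage of species detected by only one of two surveys.

    ``100 * |A Δ B| / denominator``; the denominator is typically the overall
    species total across all surveys, which may exceed ``|A ∪ B|``.
    """
    if denominator_species_count <= 0:
        raise ValueError("denominator must be positive")
    a, b = set(species_a), set(species_b)
    return 100.0 * len(a ^ b) / denominator_species_count
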