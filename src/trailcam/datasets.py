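"""Bundled example dataset and helpers.

``load_ruaha_survey`` returns the survey-level capture summary of a paired
random/trail camera-trap survey of medium-to-large terrestrial mammals
(> 0.5 kg) in Ruaha National Park, Tanzania: 41 species, two seasons (dry,
wet) × two placement strategies, with the number of independent events and
the survey-level RAI for each species × survey.  Station-level records are
not part of the summary, so analyses that need them (accumulation curves,
paired tests) use the synthetic generator instead; composition and
structure analyses run directly from this table.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

SEASONS = ("dry", "wet")
PLACEMENTS = ("random", "trail")
SURVEYS = [(p, s) for s in SEASONS for p in PLACEMENTS]


def load_ruaha_survey() -> pd.DataFrame:
    """The bundled wide-format survey summary (one row per species)."""
    with resources.files("trailcam.data").joinpath("ruaha_survey.csv").open() as fh:
        return pd.read_csv(fh)


def survey_rai_long(wide: pd.DataFrame | None = None) -> pd.DataFrame:
    """Reshape the bundled table to one row per (placement, season, species).

    Columns: placement, season, species_id, n_events, rai.
    """
    if wide is None:
        wide = load_ruaha_survey()
    rows = []
    for _, r in wide.iterrows():
        for p, s in SURVEYS:
            rows.append({
                "placement": p, "season": s, "species_id": r["species_id"],
                "n_events": int(r[f"ev_{s}_{p}"]), "rai": float(r[f"rai_{s}_{p}"]),
            })
    return pd.DataFrame(rows)


def presence_set(table: pd.DataFrame, placement: str, season: str) -> set[str]:
    """Species detected (>= 1 event) by one survey."""
    sub = table[(table["placement"] == placement) & (table["season"] == season)]
    return set(sub.loc[sub["n_events"] > 0, "species_id"])


def infer_survey_efforts(table: pd.DataFrame, min_events: int = 20) -> dict:
    """Per-survey camera-day efforts recovered by inverting the RAI definition.

    For each (placement, season), effort = median of 100 * n_events / rai
    over species with at least ``min_events`` events (high counts keep the
    printed two-decimal RAIs informative); rounded to the nearest day.
    """
    from .events import infer_effort

    out = {}
    for (p, s), g in table.groupby(["placement", "season"]):
        g = g[g["rai"] > 0]
        high = g[g["n_events"] >= min_events]
        if len(high):
            g = high
        if len(g) == 0:
            raise ValueError(f"no detected species to infer effort from in {p}/{s}")
        est = np.median([infer_effort(n, r)
                         for n, r in zip(g["n_events"], g["rai"])])
        out[(p, s)] = int(round(est))
    return out
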