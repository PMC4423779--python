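"""Photo-record ingestion, temporal-independence filtering and relative abundance indices.

A *photographic event* is a run of photographs of one species at one camera
station in which no gap between consecutive photographs exceeds the
independence threshold (one hour by default).  The relative abundance index
(RAI) of a species is the number of independent events divided by the number
of days the camera was active, multiplied by 100 — i.e. events per 100
camera-trap days.  RAIs are computed per station or per survey (a
placement × season stratum), the survey value pooling events and effort
across the survey's stations.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

PHOTO_COLUMNS = ["station_id", "species_id", "timestamp"]
DEPLOYMENT_COLUMNS = [
    "station_id", "cell_id", "placement", "season", "start", "end", "downtime_days",
]
TRAIT_COLUMNS = ["species_id", "trophic_category", "body_mass_kg", "social"]

PLACEMENTS = ("random", "trail")


class FormatError(ValueError):
    """A required column is missing or a file is structurally malformed."""


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{name}: missing required column(s) {missing}")


def read_photos(path: str | Path) -> pd.DataFrame:
    """Read a photo-record CSV (station_id, species_id, timestamp).

    Timestamps are parsed to timezone-naive instants at second resolution.
    Rows whose timestamp cannot be parsed are dropped with a warning that
    names their line numbers.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, PHOTO_COLUMNS, "photos")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # header is line 1
        warnings.warn(f"photos: dropped {bad.sum()} row(s) with unparseable timestamps "
                      f"(lines {lines[:10]}{'...' if len(lines) > 10 else ''})")
    out = df.loc[~bad, ["station_id", "species_id"]].copy()
    out["timestamp"] = ts[~bad].dt.tz_localize(None) if ts.dt.tz is not None else ts[~bad]
    unknown = out["species_id"].str.lower() == "unknown"
    if unknown.any():
        warnings.warn(f"photos: dropped {int(unknown.sum())} row(s) with "
                      "unidentified species")
        out = out[~unknown]
    return out.reset_index(drop=True)


def read_deployments(path: str | Path) -> pd.DataFrame:
    """Read a deployment CSV and normalise the placement labels to lower case."""
    df = pd.read_csv(path, dtype={"station_id": str, "cell_id": str,
                                  "placement": str, "season": str})
    _require_columns(df, DEPLOYMENT_COLUMNS, "deployments")
    df = df.copy()
    df["placement"] = df["placement"].str.strip().str.lower()
    unknown = set(df["placement"].unique()) - set(PLACEMENTS)
    if unknown:
        raise FormatError(f"deployments: unknown placement label(s) {sorted(unknown)}")
    df["start"] = pd.to_datetime(df["start"], format="ISO8601")
    df["end"] = pd.to_datetime(df["end"], format="ISO8601")
    df["downtime_days"] = df["downtime_days"].astype(float)
    return df


def read_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TRAIT_COLUMNS, "traits")
    df = df.copy()
    df["species_id"] = df["species_id"].astype(str)
    return df


def read_tables(photos_path, deployments_path, traits_path=None):
    """Read the photo, deployment and (optionally) trait tables.

    Returns ``(photos, deployments, traits)``; ``traits`` is ``None`` when no
    path is given.
    """
    photos = read_photos(photos_path)
    deployments = read_deployments(deployments_path)
    traits = read_traits(traits_path) if traits_path is not None else None
    return photos, deployments, traits


def effort_days(deployments: pd.DataFrame) -> pd.Series:
    """Active camera-days per station: deployment span minus downtime."""
    span = (deployments["end"] - deployments["start"]) / pd.Timedelta(days=1)
    eff = span - deployments["downtime_days"]
    bad = deployments.loc[eff <= 0, "station_id"].tolist()
    if bad:
        raise ValueError(f"non-positive active effort for station(s) {bad}")
    return pd.Series(eff.to_numpy(), index=deployments["station_id"].to_numpy(),
                     name="effort_days")


def filter_independent_events(photos: pd.DataFrame, gap_minutes: float = 60.0,
                              rule: str = "chained") -> pd.DataFrame:
    """Collapse photographs into temporally independent events.

    Within each station-species series sorted by time, a photograph starts a
    new event iff its gap to the reference photograph exceeds ``gap_minutes``
    (strictly).  Under the default ``"chained"`` rule the reference is the
    immediately preceding photograph of the series; under ``"anchored"`` it is
    the first photograph of the current event.

    Returns a frame with columns station_id, species_id, event_start, n_photos.
    """
    if gap_minutes <= 0:
        raise ValueError("gap_minutes must be positive")
    if rule not in ("chained", "anchored"):
        raise ValueError(f"unknown independence rule {rule!r}")
    cols = ["station_id", "species_id", "event_start", "n_photos"]
    if len(photos) == 0:
        return pd.DataFrame(columns=cols)
    df = photos.sort_values(["station_id", "species_id", "timestamp"],
                            kind="mergesort").reset_index(drop=True)
    gap = pd.Timedelta(minutes=gap_minutes)
    ts = df["timestamp"]
    new_series = (df["station_id"] != df["station_id"].shift()) | \
                 (df["species_id"] != df["species_id"].shift())
    if rule == "chained":
        breaks = new_series | ((ts - ts.shift()) > gap)
        event_id = breaks.cumsum()
    else:  # anchored: gap measured from the event's first photo; per-group scan
        event_id = np.empty(len(df), dtype=np.int64)
        eid = 0
        anchor = None
        for i in range(len(df)):
            if new_series.iloc[i] or (ts.iloc[i] - anchor) > gap:
                eid += 1
                anchor = ts.iloc[i]
            event_id[i] = eid
        event_id = pd.Series(event_id)
    out = (df.assign(_eid=np.asarray(event_id))
             .groupby("_eid", sort=True)
             .agg(station_id=("station_id", "first"),
                  species_id=("species_id", "first"),
                  event_start=("timestamp", "first"),
                  n_photos=("timestamp", "size"))
             .reset_index(drop=True))
    return out[cols]


def compute_rai(events: pd.DataFrame, deployments: pd.DataFrame,
                scope: str = "station",
                species: list[str] | None = None) -> pd.DataFrame:
    """Relative abundance indices at station or survey scope.

    ``rai = 100 * n_events / effort_days``.  At survey scope, stations are
    pooled by (placement, season): events and efforts are summed before the
    ratio is taken (this is *not* the mean of station RAIs).  Species with
    zero events are retained (RAI 0) for every key; the species universe is
    the union of species seen in ``events`` and the optional ``species`` list.
    """
    if scope not in ("station", "survey"):
        raise ValueError(f"unknown scope {scope!r}")
    eff = effort_days(deployments)
    ev_stations = set(events["station_id"].unique()) if len(events) else set()
    orphans = ev_stations - set(eff.index)
    if orphans:
        raise ValueError(f"events reference unknown station(s) {sorted(orphans)}")
    universe = sorted(set(events["species_id"].unique()) | set(species or []))

    counts = (events.groupby(["station_id", "species_id"]).size()
              if len(events) else pd.Series(dtype=int))
    dep = deployments.set_index("station_id")
    if scope == "station":
        idx = pd.MultiIndex.from_product([dep.index, universe],
                                         names=["station_id", "species_id"])
        n = counts.reindex(idx, fill_value=0).astype(int) if len(counts) else \
            pd.Series(0, index=idx, dtype=int)
        out = n.rename("n_events").reset_index()
        out["effort_days"] = eff.loc[out["station_id"]].to_numpy()
        out["placement"] = dep.loc[out["station_id"], "placement"].to_numpy()
        out["season"] = dep.loc[out["station_id"], "season"].to_numpy()
    else:
        stn = counts.rename("n_events").reset_index() if len(counts) else \
            pd.DataFrame(columns=["station_id", "species_id", "n_events"])
        stn["placement"] = dep.loc[stn["station_id"], "placement"].to_numpy() if len(stn) else []
        stn["season"] = dep.loc[stn["station_id"], "season"].to_numpy() if len(stn) else []
        surveys = deployments.groupby(["placement", "season"]).apply(
            lambda g: effort_days(g).sum(), include_groups=False).rename("effort_days")
        idx = pd.MultiIndex.from_tuples(
            [(p, s, sp) for (p, s) in surveys.index for sp in universe],
            names=["placement", "season", "species_id"])
        n = (stn.groupby(["placement", "season", "species_id"])["n_events"].sum()
             .reindex(idx, fill_value=0).astype(int))
        out = n.reset_index()
        out["effort_days"] = surveys.loc[
            pd.MultiIndex.from_frame(out[["placement", "season"]])].to_numpy()
    out["rai"] = 100.0 * out["n_events"] / out["effort_days"]
    return out


def infer_effort(n_events: float, rai: float) -> float:
    """Invert the RAI definition: effort_days = 100 * n_events / rai.

    Useful for reconstructing survey effort from a published (events, RAI)
    pair.  With ``n_events == 0`` the result is 0 and non-informative.
    """
    if rai <= 0:
        raise ValueError("rai must be positive to invert")
    return 100.0 * n_events / rai


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    out["event_start"] = out["event_start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
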