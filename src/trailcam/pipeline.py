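"""End-to-end orchestration of the paired-survey analysis.

Per season the pipeline runs: independence filtering -> RAIs -> richness
accumulation and composition -> rank-abundance structure -> species-level
trail preference, and emits per-stage CSV/JSON outputs plus a single
machine-readable ``summary.json``.  All tunables default to the standard
settings of the analysis: a 60-minute independence gap, 200 bootstrap
randomisations, a five-event inclusion threshold for structure analyses and
alpha = 0.05.

A second entry point, :func:`analyse_survey_table`, runs the composition and
structure stages directly from a survey-level RAI table (as published
capture summaries provide) when station-level records are unavailable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, events as ev, structure, trail_preference as tp

log = logging.getLogger("trailcam")


@dataclass
class AnalysisConfig:
    photos: object = None          # path or DataFrame
    deployments: object = None     # path or DataFrame
    traits: object = None          # path, DataFrame or None
    gap_minutes: float = 60.0
    bootstrap_B: int = 200
    min_events: int = 5
    alpha: float = 0.05
    seed: int = 0
    out_dir: object = None


def _as_frame(obj, reader):
    if obj is None or isinstance(obj, pd.DataFrame):
        return obj
    return reader(obj)


def validate_inputs(photos: pd.DataFrame, deployments: pd.DataFrame) -> list[dict]:
    """Schema and consistency diagnostics: orphan stations, out-of-window
    photos, duplicate rows.  Entries carry level 'error' or 'warning'."""
    findings = []
    known = set(deployments["station_id"])
    orphan = sorted(set(photos["station_id"]) - known)
    for st in orphan:
        findings.append({"level": "error",
                         "message": f"photo references unknown station {st!r}"})
    dep = deployments.set_index("station_id")
    merged = photos.merge(deployments[["station_id", "start", "end"]],
                          on="station_id", how="inner")
    early = merged["timestamp"] < merged["start"]
    late = merged["timestamp"] > merged["end"]
    if early.any():
        findings.append({"level": "warning",
                         "message": f"{int(early.sum())} photo(s) before deployment start"})
    if late.any():
        findings.append({"level": "warning",
                         "message": f"{int(late.sum())} photo(s) after deployment end"})
    ndup = int(photos.duplicated().sum())
    if ndup:
        findings.append({"level": "warning",
                         "message": f"{ndup} duplicate photo row(s)"})
    if dep.index.duplicated().any():
        findings.append({"level": "error", "message": "duplicate station_id in deployments"})
    return findings


def _composition_stage(events_df, deployments, season, all_species_count, B, seed):
    placements = sorted(deployments.loc[deployments["season"] == season,
                                        "placement"].unique())
    out = {"season": season, "surveys": {}}
    curves, presence = {}, {}
    for p in placements:
        inc = diversity.build_incidence(events_df, deployments, p, season)
        curve = diversity.bootstrap_accumulation(inc, B=B, seed=seed)
        curves[p] = curve
        presence[p] = set(inc.species)
        out["surveys"][p] = {
            "s_obs": inc.s_obs, "n_stations": inc.n_stations,
            "effort_days": inc.total_effort, "chao2": diversity.chao2(inc),
        }
    if len(placements) == 2:
        a, b = placements
        comparison = min(out["surveys"][a]["effort_days"],
                         out["surveys"][b]["effort_days"])
        out["comparison_effort_days"] = comparison
        out["min_overlap_effort_days"] = diversity.min_overlap_effort(
            curves[a], curves[b], compare_at=comparison)
        out["jaccard_dissimilarity"] = diversity.jaccard_dissimilarity(
            presence[a], presence[b])
        out["exclusive_species_pct"] = diversity.exclusive_species_pct(
            presence[a], presence[b], all_species_count)
        out["exclusive_species"] = sorted(presence[a] ^ presence[b])
    return out, curves


def _structure_stage(rai_survey, season, min_events):
    subset = structure.select_structure_species(rai_survey, season,
                                                min_events=min_events)
    sub = rai_survey[(rai_survey["season"] == season)
                     & rai_survey["species_id"].isin(subset)]
    out = {"season": season, "subset_size": len(subset), "species": subset,
           "fits": {}, "best_model": {}}
    rank_vectors = {}
    for p, g in sub.groupby("placement"):
        rad = structure.build_rad(g[["species_id", "rai"]])
        models = [m for m in structure.RAD_MODELS
                  if rad.n >= structure._N_PARAMS[m] + 1]
        fits = structure.fit_all_rad(rad, models=models)
        best = structure.select_rad_model(fits)
        out["fits"][p] = {f.model: f.deviance for f in fits}
        out["best_model"][p] = best.model
        rank_vectors[p] = structure.ranks_from_rai(
            g.set_index("species_id")["rai"])
    if len(rank_vectors) == 2:
        (pa, ra), (pb, rb) = sorted(rank_vectors.items())
        shift = structure.mars(ra, rb)
        out["rank_shift"] = {
            "n": shift.n, "mars": shift.mars, "V": shift.v,
            "p_value": shift.p_value,
            "abs_shifts": shift.abs_shifts.to_dict(),
        }
    return out


def _preference_stage(rai_station, deployments, traits, season, subset, alpha):
    dep = deployments[deployments["season"] == season].set_index("station_id")
    st = rai_station[rai_station["season"] == season].copy()
    st["cell_id"] = dep.loc[st["station_id"], "cell_id"].to_numpy()
    results = []
    for sp in subset:
        g = st[st["species_id"] == sp].pivot_table(
            index="cell_id", columns="placement", values="rai")
        g = g.dropna()
        if not {"random", "trail"} <= set(g.columns):
            continue
        results.append(tp.paired_location_shift(
            g["random"].to_numpy(), g["trail"].to_numpy(),
            alpha=alpha, species_id=sp))
    scores = tp.score_species(results)
    out = {"season": season, "scores": scores,
           "n_scored_1": scores.attrs["n_scored_1"],
           "any_random_preference": scores.attrs["any_random_preference"]}
    if traits is not None and len(scores):
        tsub = traits[traits["species_id"].isin(scores["species_id"])]
        svec = scores.set_index("species_id")["score"].astype(float)
        try:
            best, aic_table = tp.select_glm(svec, tsub)
            out["glm"] = {"selected": best.name, "aic": best.aic,
                          "aic_table": aic_table,
                          "coefficients": best.coefficients.to_dict()}
        except ValueError as exc:
            out["glm"] = {"error": str(exc)}
    return out


def run_all(config: AnalysisConfig) -> dict:
    """Run every stage per season; returns (and optionally writes) the report."""
    photos = _as_frame(config.photos, ev.read_photos)
    deployments = _as_frame(config.deployments, ev.read_deployments)
    traits = _as_frame(config.traits, ev.read_traits)
    findings = validate_inputs(photos, deployments)
    hard = [f for f in findings if f["level"] == "error"]
    if hard:
        raise ValueError("input validation failed: "
                         + "; ".join(f["message"] for f in hard))

    events_df = ev.filter_independent_events(photos, config.gap_minutes)
    log.info("filtered %d photos into %d independent events",
             len(photos), len(events_df))
    species_universe = (sorted(traits["species_id"]) if traits is not None
                        else None)
    rai_station = ev.compute_rai(events_df, deployments, "station",
                                 species=species_universe)
    rai_survey = ev.compute_rai(events_df, deployments, "survey",
                                species=species_universe)
    all_species = sorted(events_df["species_id"].unique())
    seasons = sorted(deployments["season"].unique())

    report = {"n_photos": len(photos), "n_events": len(events_df),
              "n_species_detected": len(all_species),
              "total_effort_days": float(ev.effort_days(deployments).sum()),
              "validation": findings, "seasons": {}}
    curves_all = {}
    for season in seasons:
        comp, curves = _composition_stage(events_df, deployments, season,
                                          len(all_species),
                                          config.bootstrap_B, config.seed)
        struct = _structure_stage(rai_survey, season, config.min_events)
        pref = _preference_stage(rai_station, deployments, traits, season,
                                 struct["species"], config.alpha)
        report["seasons"][season] = {"composition": comp, "structure": struct,
                                     "preference": pref}
        curves_all[season] = curves

    if config.out_dir is not None:
        _write_bundle(Path(config.out_dir), report, events_df,
                      rai_station, rai_survey, curves_all)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj) if isinstance(obj, set)] \
            if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_bundle(out_dir, report, events_df, rai_station, rai_survey, curves):
    out_dir.mkdir(parents=True, exist_ok=True)
    ev.write_events(events_df, out_dir / "events.csv")
    rai_station.to_csv(out_dir / "rai_station.csv", index=False)
    rai_survey.to_csv(out_dir / "rai_survey.csv", index=False)
    for season, by_placement in curves.items():
        for placement, curve in by_placement.items():
            curve.to_frame().to_csv(
                out_dir / f"accumulation_{placement}_{season}.csv", index=False)
    for season, block in report["seasons"].items():
        pref = block["preference"]
        if isinstance(pref.get("scores"), pd.DataFrame):
            pref["scores"].to_csv(
                out_dir / f"trail_preference_{season}.csv", index=False)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)


def analyse_survey_table(table: pd.DataFrame, min_events: int = 5,
                         overall_species_count: int | None = None) -> dict:
    """Composition and structure analyses from a survey-level RAI table.

    ``table`` has one row per (placement, season, species) with ``n_events``
    and ``rai`` columns — the shape published capture summaries take.  The
    per-survey efforts are recovered by RAI inversion; composition uses
    detection (n_events > 0) sets; structure applies the standard inclusion
    rule and fits the five RAD models per survey.
    """
    from .datasets import infer_survey_efforts, presence_set

    species_all = sorted(
        table.loc[table["n_events"] > 0, "species_id"].unique())
    denom = overall_species_count or len(species_all)
    efforts = infer_survey_efforts(table)
    report = {
        "n_species_total": len(species_all),
        "efforts_days": {f"{p}_{s}": e for (p, s), e in efforts.items()},
        "total_effort_days": int(sum(efforts.values())),
        "seasons": {},
    }
    for season in sorted(table["season"].unique()):
        pres = {p: presence_set(table, p, season)
                for p in sorted(table.loc[table["season"] == season,
                                          "placement"].unique())}
        comp = {f"s_obs_{p}": len(s) for p, s in pres.items()}
        if len(pres) == 2:
            (pa, sa), (pb, sb) = sorted(pres.items())
            comp["jaccard_dissimilarity"] = diversity.jaccard_dissimilarity(sa, sb)
            comp["exclusive_species_pct"] = diversity.exclusive_species_pct(
                sa, sb, denom)
            comp["exclusive_species"] = sorted(sa ^ sb)
            comp["comparison_effort_days"] = min(
                efforts[(pa, season)], efforts[(pb, season)])
        struct = _structure_stage(table, season, min_events)
        report["seasons"][season] = {"composition": comp, "structure": struct}
    return report
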