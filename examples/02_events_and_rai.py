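"""Collapse photographs into independent events and compute RAIs.

An event is a run of same-species photographs at one station with no gap
over one hour; the relative abundance index (RAI) is events per 100
camera-days.  Survey-level RAIs pool events and effort across stations.
"""

from trailcam import SurveyDesignParams, compute_rai, \
    filter_independent_events, generate_species_pool, simulate_paired_survey

design = SurveyDesignParams(n_cells=20, seasons={"dry": 56}, seed=7)
traits = generate_species_pool(15, seed=7)
deployments, photos = simulate_paired_survey(design, traits)

events = filter_independent_events(photos, gap_minutes=60)
print(f"{len(photos)} photographs -> {len(events)} independent events")

survey = compute_rai(events, deployments, scope="survey",
                     species=sorted(traits["species_id"]))
top = (survey.pivot_table(index="species_id", columns="placement",
                          values="rai")
       .sort_values("trail", ascending=False).head(5).round(2))
print("\nTop survey-level RAIs (events per 100 camera-days):")
print(top.to_string())
print("\nA trail:random RAI ratio near a species' trail multiplier shows the "
      "index recovering the simulated encounter rates.")
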