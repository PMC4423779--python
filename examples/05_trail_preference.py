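"""Which species are caught significantly more often on game trails?

Runs one synthetic survey in which carnivores use trails at four times
their off-trail rate, scores each species by whether the signed-rank 95%
confidence interval of the paired (random - trail) RAI differences lies
below zero, and selects the trait model of the binary scores by AIC.
"""

import warnings

from trailcam.experiments import reference_species_pool, run_recovery_replicate

warnings.simplefilter("ignore")

result = run_recovery_replicate(carnivore_multiplier=4.0, seed=11)
pool = reference_species_pool(4.0, seed=11)
counts = pool["trophic_category"].value_counts().to_dict()

print(f"community: {counts}, carnivore trail multiplier 4.0")
print(f"species scored trail-preferring: {result['n_scored_1']} of 30")
print(f"carnivores scored: {result['carnivore_score_rate']:.0%}, "
      f"other groups: {result['other_score_rate']:.0%}")
print(f"trait model with lowest AIC: {result['selected_model']}")
print("\nA 'trophic' selection with carnivores near 100% and others near the "
      "5% false-positive rate means the paired design recovered the "
      "simulated trail preference and its trait structure.")
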