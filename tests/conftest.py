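import numpy as np
import pandas as pd
import pytest

from trailcam import datasets, synthetic


@pytest.fixture(scope="session")
def ruaha_long():
    """Survey-level (placement, season, species) table of the bundled dataset."""
    return datasets.survey_rai_long()


@pytest.fixture(scope="session")
def small_survey():
    """A small two-season paired survey with ground truth attached."""
    design = synthetic.SurveyDesignParams(
        n_cells=15, seasons={"dry": 30, "wet": 30}, seed=42,
        downtime_fraction=0.1)
    traits = synthetic.generate_species_pool(10, seed=42)
    deployments, photos = synthetic.simulate_paired_survey(design, traits)
    return design, traits, deployments, photos


def make_photos(rows):
    """rows: (station, species, iso-timestamp) triples."""
    return pd.DataFrame(
        [{"station_id": st, "species_id": sp, "timestamp": pd.Timestamp(ts)}
         for st, sp, ts in rows])


def make_deployments(stations, start="2023-01-01", days=10.0, downtime=0.0,
                     placement="random", season="dry"):
    start = pd.Timestamp(start)
    rows = []
    for i, st in enumerate(np.atleast_1d(stations)):
        p = placement[i] if isinstance(placement, (list, tuple)) else placement
        d = days[i] if isinstance(days, (list, tuple)) else days
        rows.append({"station_id": st, "cell_id": f"cell{i}", "placement": p,
                     "season": season, "start": start,
                     "end": start + pd.Timedelta(days=float(d)),
                     "downtime_days": downtime})
    return pd.DataFrame(rows)
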