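import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("fixed", derandomize=True, deadline=None,
                          max_examples=25)
settings.load_profile("fixed")

from dungsight.survey_data import filter_middens, bin_distances
from dungsight.synthetic import SimulationScenario, simulate_survey


@pytest.fixture(scope="session")
def default_survey():
    """One synthetic survey under the default (study-structured) scenario."""
    return simulate_survey(SimulationScenario(seed=11))


@pytest.fixture(scope="session")
def default_binned(default_survey):
    retained, _ = filter_middens(default_survey.events)
    return bin_distances(retained, default_survey.transects,
                         default_survey.cutpoints)


@pytest.fixture()
def survey_csvs(tmp_path, default_survey):
    """The default survey written to CSV files."""
    paths = (tmp_path / "events.csv", tmp_path / "transects.csv",
             tmp_path / "quadrats.csv")
    default_survey.write(*paths)
    return paths


def make_bookkeeping_events(per_species):
    """Events with exact per-species recorded/midden totals, spread over
    transects; distances and pellet counts are arbitrary but valid."""
    rng = np.random.default_rng(5)
    rows = []
    for sp, (recorded, middens) in per_species.items():
        for i in range(recorded):
            rows.append({
                "transect_id": f"T{(i % 36) + 1:02d}",
                "species": sp,
                "distance_m": round(float(rng.uniform(0, 4)), 3),
                "n_pellets": 10 + int(rng.poisson(12)),
                "is_midden": 1 if i < middens else 0,
            })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def study_scale_events():
    """Pellet events with the worked example's recorded/midden totals."""
    return make_bookkeeping_events({"oryx": (640, 12), "gazelle": (185, 53)})
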