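import pandas as pd
import pytest

import projectome as pj


@pytest.fixture(scope="session")
def atlas():
    return pj.load_atlas()


@pytest.fixture(scope="session")
def toy_sim():
    """Tiny simulated cohort (3 source areas, 2 animals, 100 cells)."""
    gt = pj.toy_profile(seed=3)
    cohort, events = pj.simulate_cohort(gt)
    return gt, cohort, events


@pytest.fixture(scope="session")
def visp_sim():
    """Default study-scale VISp cohort (6 animals, 2e5 cells each)."""
    gt = pj.default_profile("VISp", seed=7)
    cohort, events = pj.simulate_cohort(gt)
    return gt, cohort, events


@pytest.fixture(scope="session")
def make_animal(atlas):
    """Factory for hand-constructed AnimalCounts from tidy row tuples."""

    def _make(rows, target="VISp", animal_id="m1", injection="left", **qc_kwargs):
        df = pd.DataFrame(rows, columns=["hemisphere", "area", "layer", "count"])
        qc = pj.InjectionQC(target, injection, **qc_kwargs)
        return pj.AnimalCounts.from_tidy(animal_id, qc, df, atlas)

    return _make
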