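import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from adiposize import synthcohort

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


def tiny_synthetic_config(n_subjects: int = 12) -> synthcohort.SyntheticConfig:
    """A scaled-down generator config for fast structural tests."""
    marginals = synthcohort._default_phenotype_marginals()
    scaled = {
        name: (mean, sd, lo, hi, max(3, round(n_obs * n_subjects / 188)))
        for name, (mean, sd, lo, hi, n_obs) in marginals.items()
    }
    return synthcohort.SyntheticConfig(
        n_subjects=n_subjects,
        n_histology={"sc": n_subjects - 2, "vc": n_subjects},
        n_collagenase={"sc": max(3, n_subjects // 2), "vc": max(3, n_subjects // 2)},
        n_respirometry={"sc": max(3, n_subjects // 3), "vc": max(3, n_subjects // 3)},
        phenotype_marginals=scaled,
        n_male=n_subjects // 3,
        n_t2d=n_subjects // 4,
        n_t2d_known=n_subjects - 1,
        cells_per_subject=(60, 80),
        n_collagenase_cells=30,
    )


@pytest.fixture(scope="session")
def tiny_config():
    return tiny_synthetic_config()


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return synthcohort.generate_cohort(tiny_config, seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at the default study conditions, shared read-only."""
    return synthcohort.generate_cohort(seed=11)


@pytest.fixture
def small_cells():
    """Hand-sized long-form cell table: 2 subjects x 2 depots, histology areas
    plus collagenase diameters for one subject."""
    rng = np.random.default_rng(42)
    frames = []
    for subject in ("A", "B"):
        for depot in ("sc", "vc"):
            areas = np.exp(rng.normal(7.8, 0.5, 40))
            frames.append(pd.DataFrame({
                "subject_id": subject, "depot": depot, "method": "histology",
                "size_parameter": "area", "value": areas, "unit": "um2",
            }))
    diam = rng.normal(100.0, 15.0, 25)
    frames.append(pd.DataFrame({
        "subject_id": "A", "depot": "sc", "method": "collagenase",
        "size_parameter": "diameter", "value": diam, "unit": "um",
    }))
    return pd.concat(frames, ignore_index=True)
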