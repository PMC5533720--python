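import numpy as np
import pytest

from ramanremodel import CohortDesign, gen_cohort, gen_pure_components


@pytest.fixture(scope="session")
def library():
    return gen_pure_components()


@pytest.fixture(scope="session")
def small_cohort(library):
    """Realistic small cohort: baseline, noise, planted QC and bad-fit spectra."""
    design = CohortDesign(mice_per_group=3, seed=11)
    return gen_cohort(design, library), design


@pytest.fixture(scope="session")
def clean_cohort(library):
    """Noiseless, baseline-free cohort (planted QC violations kept, no bad fits)."""
    design = CohortDesign(
        mice_per_group=2,
        seed=7,
        noise_scale=0.0,
        baseline_amp_counts=(0.0, 0.0),
        bad_fit_frac=0.0,
    )
    return gen_cohort(design, library), design
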