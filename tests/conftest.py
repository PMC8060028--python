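import numpy as np
import pytest

import zfassay as zf


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def no_drug():
    """Treatment applied far in the future: fish never sees a drug."""
    return zf.TreatmentSpec(application_time=1e9)


@pytest.fixture
def default_model():
    return zf.DrugModel()


def make_respiratory_design(seed=0, duration=480.0, sample_rate=20.0):
    """Antagonism design: control n=10, agonist n=9, agonist+antagonist n=7."""
    tr = lambda **kw: zf.TreatmentSpec(application_time=60.0, **kw)
    return zf.CohortDesign(
        groups=(
            zf.GroupSpec("control", tr(), 10),
            zf.GroupSpec("fentanyl", tr(agonist="fentanyl", agonist_um=1.0), 9),
            zf.GroupSpec(
                "fent_naloxone",
                tr(
                    agonist="fentanyl",
                    agonist_um=1.0,
                    antagonist="naloxone",
                    antagonist_um=20.0,
                ),
                7,
            ),
        ),
        duration=duration,
        sample_rate=sample_rate,
        seed=seed,
        assay="respiratory",
    )
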