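import hypothesis
import numpy as np
import pytest

from reftriage.cohort import Cohort, ReferralRecord

hypothesis.settings.register_profile(
    "det", derandomize=True, max_examples=40, deadline=None
)
hypothesis.settings.load_profile("det")


def make_record(i=0, **overrides) -> ReferralRecord:
    base = dict(
        id=f"r{i}", age=46.0, route="urgent", top_t=1, top_o=0, top_p=0,
        gravidity=1, previous_bc=0, menopause=0, breastfeeding=1,
        family_history="none_other", hrt=0, cancer=0,
    )
    base.update(overrides)
    return ReferralRecord(**base)


@pytest.fixture
def toy_cohort() -> Cohort:
    """Small deterministic cohort with a mix of outcomes and missingness."""
    rng = np.random.default_rng(42)
    records = []
    for i in range(60):
        records.append(make_record(
            i,
            age=float(rng.integers(20, 90)),
            route="urgent" if rng.random() < 0.6 else "cb",
            top_t=int(rng.random() < 0.6),
            top_o=int(rng.random() < 0.2),
            top_p=int(rng.random() < 0.3),
            gravidity=None if i % 15 == 0 else int(rng.random() < 0.8),
            breastfeeding=None if i % 20 == 0 else int(rng.random() < 0.5),
            family_history=None if i % 30 == 0 else "none_other",
            cancer=int(rng.random() < 0.3),
        ))
    return Cohort(records, provenance="toy")
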