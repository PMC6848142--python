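import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from coessence.screen_io import GuideLibrary

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def toy_library() -> GuideLibrary:
    """Two 2-guide genes plus 3 non-targeting controls."""
    rng = np.random.default_rng(1234)
    bases = np.array(list("ACGT"))
    seqs = ["".join(rng.choice(bases, 20)) for _ in range(7)]
    df = pd.DataFrame(
        {
            "guide_id": ["A_sg1", "A_sg2", "B_sg1", "B_sg2", "NTC_1", "NTC_2", "NTC_3"],
            "gene": ["GA", "GA", "GB", "GB", "NTC", "NTC", "NTC"],
            "sequence": seqs,
        }
    )
    return GuideLibrary(records=df)


@pytest.fixture
def toy_depletion(toy_library) -> pd.DataFrame:
    """Fixed 7-guide x 14-tumor depletion matrix."""
    rng = np.random.default_rng(77)
    dep = rng.normal(0.0, 1.0, size=(7, 14))
    return pd.DataFrame(
        dep,
        index=toy_library.guide_ids,
        columns=[f"tumor{t + 1:02d}" for t in range(14)],
    )
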