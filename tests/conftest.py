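import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_catalog_frame() -> pd.DataFrame:
    """One triad plus one ungrouped gene."""
    return pd.DataFrame(
        {
            "gene_id": ["A_g1", "B_g1", "C_g1", "A_g2"],
            "subgenome": ["A", "B", "C", "A"],
            "group_id": ["og1", "og1", "og1", ""],
        }
    )
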