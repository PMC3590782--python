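import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from itraqstat import SimDesign, generate_psm_table


@pytest.fixture(scope="session")
def small_sim_psms() -> pd.DataFrame:
    """One modest simulated experiment shared across read-only tests."""
    design = SimDesign(n_proteins=300, seed=42, sc_mean_log10_range=(0.5, 2.0))
    return generate_psm_table(design)
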