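"""Shared builders for hand-made PSM tables (independent of the simulator)."""

import numpy as np
import pandas as pd

from itraqstat.tables_io import PSM_COLUMNS


def make_psm_frame(rows):
    """Build a PSM DataFrame from dicts, filling boilerplate columns."""
    defaults = {
        "peptide": "PEPTIDEK",
        "workflow_rep": 1,
        "technical_rep": 1,
        "fraction": 1,
        "confidence": "high",
        "i114": 100.0,
        "i115": 100.0,
        "i116": 100.0,
        "i117": 100.0,
    }
    full = [{**defaults, **row} for row in rows]
    return pd.DataFrame(full, columns=list(PSM_COLUMNS))


def random_psm_frame(rng: np.random.Generator, n_proteins: int = 50) -> pd.DataFrame:
    """An irregular random PSM table with uneven replicate coverage."""
    rows = []
    for i in range(n_proteins):
        pid = f"R{i:04d}"
        for wr in (1, 2, 3):
            for tr in (1, 2, 3):
                for _ in range(int(rng.integers(0, 5))):
                    rows.append(
                        {
                            "protein_id": pid,
                            "peptide": f"PEP{rng.integers(0, 5)}K",
                            "workflow_rep": wr,
                            "technical_rep": tr,
                            "fraction": int(rng.integers(1, 14)),
                            "confidence": "high" if rng.random() < 0.7 else "medium",
                            "i114": float(rng.uniform(10, 1e5)),
                            "i115": float(rng.uniform(10, 1e5)),
                            "i116": float(rng.uniform(10, 1e5)),
                            "i117": float(rng.uniform(10, 1e5)),
                        }
                    )
    return make_psm_frame(rows)
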