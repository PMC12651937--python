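import numpy as np
import pandas as pd
import pytest

from sleepmr.instruments import harmonize, select_instruments
from sleepmr.simulate import MRSimConfig, simulate_mr_pair


def simulate_harmonized(**kwargs) -> pd.DataFrame:
    """Simulate an MR pair and return the harmonized instrument table."""
    cfg = MRSimConfig(**kwargs)
    exposure, outcome, _ = simulate_mr_pair(cfg)
    harmonized, _ = harmonize(select_instruments(exposure), outcome)
    return harmonized


@pytest.fixture
def three_snp_instruments() -> pd.DataFrame:
    """Small hand-checkable harmonized table."""
    return pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3"],
            "beta_exp": [0.10, 0.20, 0.15],
            "se_exp": [0.01, 0.01, 0.01],
            "beta_out": [0.022, 0.038, 0.031],
            "se_out": [0.005, 0.004, 0.006],
            "eaf_exp": [0.3, 0.4, 0.25],
            "flipped": [False, False, False],
        }
    )


def make_instruments(bx, by, sy, sx=None) -> pd.DataFrame:
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    return pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(len(bx))],
            "beta_exp": bx,
            "se_exp": sx,
            "beta_out": by,
            "se_out": sy,
            "eaf_exp": 0.3,
            "flipped": False,
        }
    )
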