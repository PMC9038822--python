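import numpy as np
import pandas as pd
import pytest

from foreprep import DesignSpec, GenerativeParams, generate_design, simulate_rts


@pytest.fixture
def tiny_spec() -> DesignSpec:
    """Small but structurally complete design: 2 Acquisition + 1 Transfer
    block, 20-trial Acquisition blocks (per-FP counts 4/3/2/1 for the
    exponential type), 16-trial Transfer blocks."""
    return DesignSpec(
        n_acquisition_blocks=2,
        n_transfer_blocks=1,
        exp_counts_per_block=(4, 3, 2, 1),
        uniform_count_per_fp=2,
    )


@pytest.fixture
def small_trials(tiny_spec) -> pd.DataFrame:
    """Six simulated participants on the tiny design, clean enough for
    model fits (no contamination)."""
    params = GenerativeParams(error_rate=0.0, outlier_rate=0.0)
    skeletons = generate_design(tiny_spec, 6, seed=101)
    return simulate_rts(skeletons, params, seed=202)


def make_trials(rows: list[dict]) -> pd.DataFrame:
    """Toy trial table builder: fills design columns with defaults so
    tests only state what matters."""
    defaults = {
        "participant": 1,
        "block": 1,
        "phase": "Acquisition",
        "s1_category": "face",
        "s1_type": "E",
        "fp_ms": 600,
        "s2_side": "left",
        "response": "left",
        "rt_ms": 400.0,
        "correct": True,
    }
    filled = []
    for i, row in enumerate(rows):
        r = dict(defaults, trial_index=i + 1)
        r.update(row)
        filled.append(r)
    return pd.DataFrame(filled)
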