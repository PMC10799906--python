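import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from advicebandit import AgentParams, TaskConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> TaskConfig:
    """Scaled-down task: 1 session x 2 blocks x 40 trials."""
    return TaskConfig(n_sessions=1, n_blocks_per_session=2, n_trials_per_block=40)


@pytest.fixture(scope="session")
def default_cfg() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def model5_params() -> AgentParams:
    return AgentParams(alpha=0.3, beta=6.0, omega=0.7, phi=0.2)


@pytest.fixture(scope="session")
def small_dataset(small_cfg, model5_params) -> pd.DataFrame:
    """Three model-5 agents on the scaled-down task."""
    return simulate_dataset(5, [model5_params] * 3, small_cfg, seed=11)


def random_trial_sequence(rng: np.random.Generator, n_trials: int = 20,
                          n_blocks: int = 2, subject: int = 0) -> pd.DataFrame:
    """Random (not model-generated) trial sequence for likelihood checks."""
    rows = []
    for blk in range(n_blocks):
        for t in range(n_trials):
            a = int(rng.integers(0, 4))
            b = int((a + rng.integers(1, 4)) % 4)
            a, b = min(a, b), max(a, b)
            adv = a if rng.random() < 0.5 else b
            rows.append(
                dict(
                    subject=subject,
                    session=0,
                    block=blk,
                    trial=t,
                    offer_a=a,
                    offer_b=b,
                    advised_card=adv,
                    revealed=int(rng.random() < 0.6),
                    choice=a if rng.random() < 0.5 else b,
                    reward=float(rng.integers(0, 2)),
                    rt=np.nan,
                )
            )
    return pd.DataFrame(rows)
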