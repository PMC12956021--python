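import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from clonefluct import AssayProtocol, SwitchingModel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_model() -> SwitchingModel:
    """The study parameterization: f_eq from the 0.9/24h/100h survival balance,
    memory 10.5 generations."""
    return SwitchingModel.from_survival_balance()


@pytest.fixture
def default_protocol() -> AssayProtocol:
    return AssayProtocol()


@pytest.fixture
def small_protocol() -> AssayProtocol:
    """Desk-scale instance where exact and aggregate modes both run."""
    return AssayProtocol(T=24.0, N0=16, G=4, n_clones=300)


def make_table(survival_by_passage: dict, n_plated: int = 1000) -> pd.DataFrame:
    """Build a schema-valid clone-survival table from per-passage fractions."""
    frames = []
    for passage, surv in survival_by_passage.items():
        surv = np.asarray(surv, dtype=float)
        n_live = np.rint(surv * n_plated).astype(np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "clone_id": [f"c{i + 1}" for i in range(surv.size)],
                    "passage": passage,
                    "n_plated": n_plated,
                    "n_live": n_live,
                    "survival_fraction": n_live / n_plated,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def toy_table() -> pd.DataFrame:
    return make_table({"P1": [0.8, 0.9, 1.0], "P3": [0.9, 0.85, 0.95]})
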