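import pytest

from coopamr.environment import EnvParams
from coopamr.model import ModelParams


@pytest.fixture(scope="session")
def params_main() -> ModelParams:
    """Reference strain parameters (s=0.1, a=0.25, Nth=80)."""
    return ModelParams(s=0.1, a=0.25, nth=80)


@pytest.fixture(scope="session")
def env_main() -> EnvParams:
    """Reference harsh/mild environment (K-=120, K+=1000)."""
    return EnvParams(Kplus=1000, Kminus=120, nu=0.1, delta=0.0)


@pytest.fixture(scope="session")
def params_strong() -> ModelParams:
    """Stronger selection variant (s=0.2, a=0.5, Nth=30)."""
    return ModelParams(s=0.2, a=0.5, nth=30)


def static_env(K0: float, nu: float = 1.0) -> EnvParams:
    """Degenerate environment with a constant carrying capacity."""
    return EnvParams(Kplus=K0, Kminus=K0, nu=nu, delta=0.0)
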