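import pytest
from hypothesis import settings

from thvnorm import default_config, paper_model

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    """The pinned published reference model."""
    return paper_model()


def zero_shift_config(n: int, seed: int, delta: float = 0.0, **overrides):
    """Default generator config with a uniform risk shift (0 = null cohort)."""
    cfg = default_config(n=n, seed=seed)
    shift = {
        s: {c: {"low": delta, "high": delta} for c in ("normal", "overweight", "obese")}
        for s in ("F", "M")
    }
    cfg = cfg.model_copy(update={"risk_shift": shift, **overrides})
    return type(cfg).model_validate(cfg.model_dump())
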