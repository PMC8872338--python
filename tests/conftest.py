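import json
from importlib.resources import files

import numpy as np
import pytest

from survcea import ModelParams


@pytest.fixture(scope="session")
def base_params() -> ModelParams:
    return ModelParams.default()


@pytest.fixture(scope="session")
def reference() -> dict:
    """Published per-strategy (cost, effect) means for both outcome metrics."""
    return json.loads(
        files("survcea.data").joinpath("reference_basecase.json").read_text()
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def reference_points(reference: dict, metric: str) -> list[tuple[str, float, float]]:
    return [
        (name, vals["cost"], vals["effect"]) for name, vals in reference[metric].items()
    ]
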