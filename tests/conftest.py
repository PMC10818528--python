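import pathlib

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from toxra.registry import load_chemicals, packaged_registry_path
from toxra.simulate import SyntheticConfig, generate


@pytest.fixture(scope="session")
def registry():
    return load_chemicals(packaged_registry_path())


@pytest.fixture()
def synthetic_paths(tmp_path):
    """Write a small synthetic dataset to disk; returns (chem, tox, truth) paths."""

    def _write(config: SyntheticConfig) -> tuple[pathlib.Path, pathlib.Path, pathlib.Path]:
        chem, tox, truth = generate(config)
        paths = tmp_path / "chem.csv", tmp_path / "tox.csv", tmp_path / "truth.csv"
        chem.to_csv(paths[0], index=False)
        tox.to_csv(paths[1], index=False)
        truth.to_csv(paths[2], index=False)
        return paths

    return _write
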