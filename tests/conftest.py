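import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mirpipe.synth import (  # noqa: E402
    SyntheticGenomeSpec,
    build_genome,
    default_profile,
    simulate_libraries,
)


@pytest.fixture(scope="session")
def bundle():
    """Small synthetic genome bundle shared across tests."""
    return build_genome(SyntheticGenomeSpec(seed=7))


@pytest.fixture(scope="session")
def simulated(bundle, tmp_path_factory):
    """Simulated libraries (20k reads each) plus their count table."""
    out = tmp_path_factory.mktemp("sim")
    profile = default_profile(bundle, seed=7, depth=20_000)
    table = simulate_libraries(bundle, profile, out / "ctl.fastq", out / "def.fastq")
    return {"profile": profile, "table": table,
            "fastq_ctl": out / "ctl.fastq", "fastq_def": out / "def.fastq"}
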