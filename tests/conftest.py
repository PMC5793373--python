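import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from claimsforge.codebook import builtin_registry
from claimsforge.synthetic_claims import GeneratorConfig, generate


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def small_repo():
    """One mid-sized generated repository with planted truth (seed fixed)."""
    return generate(GeneratorConfig(n_persons=300, seed=42))
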