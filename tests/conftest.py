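import warnings

import pytest

from mircurate.fixtures import FixtureConfig, generate_bundle
from mircurate.pipeline import evaluate_candidates


@pytest.fixture(scope="session")
def default_bundle():
    """The default study conditions: 50 planted hairpins + 50 decoys,
    depth 50, precision 0.95, 4 samples, single fixed seed."""
    return generate_bundle(FixtureConfig(seed=42))


@pytest.fixture(scope="session")
def evaluated_default(default_bundle):
    """Folded/criteria-evaluated candidates for the default bundle (shared
    across tests because folding 100 precursors dominates runtime)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return evaluate_candidates(default_bundle.records(), default_bundle.reads)
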