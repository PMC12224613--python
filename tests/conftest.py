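from __future__ import annotations

import pytest

from strpopgen.reported_variants import REPORTED_VARIANTS
from strpopgen.simulate import make_panel_fixture, population_with_injected_counts


@pytest.fixture(scope="session")
def injected_population():
    """50M/50F cohort in which every reported variant allele appears exactly
    its printed number of times."""
    return population_with_injected_counts(REPORTED_VARIANTS)


@pytest.fixture(scope="session")
def panel_bundle():
    """Full-panel synthetic cohort (306-marker shape, 50M/50F)."""
    return make_panel_fixture(seed=7)
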