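import warnings

import pytest

from trioburden import synth


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Tiny deterministic cohort (3 trios, 20 genes) with planted violations."""
    out = tmp_path_factory.mktemp("fixture_suite")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        synth.emit_fixture_suite(out)
    return out


@pytest.fixture(scope="session")
def small_universe():
    """60-gene universe for mutability/stratification checks."""
    spec = synth.SyntheticCohortSpec(seed=101, n_genes=60, n_trios=12,
                                     target_total_expected_dnvs=20.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synth.simulate_gene_universe(spec)


@pytest.fixture(scope="session")
def study_scale_universe():
    """Desk-scale 2,000-gene universe calibrated to the study's DNV scale."""
    spec = synth.SyntheticCohortSpec(seed=2024)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synth.simulate_gene_universe(spec)
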