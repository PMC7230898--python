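import pytest

from vdtargets import default_strategies, reference_fixture, run_analysis


@pytest.fixture(scope="session")
def bundle():
    return reference_fixture()


@pytest.fixture(scope="session")
def analysis(bundle):
    return run_analysis(
        bundle.anchors,
        bundle.peaks,
        bundle.timecourse,
        bundle.curation,
        bundle.de_tables,
        default_strategies(bundle.de_tables, bundle.config),
        bundle.config,
    )


@pytest.fixture(scope="session")
def reports_by_gene(analysis):
    return {r.gene_id: r for r in analysis.reports}
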