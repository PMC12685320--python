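import pytest

from triagedca import (
    ConfusionCounts,
    packaged_fixture_path,
    parse_performance_table,
    reconstruct_counts,
)


@pytest.fixture(scope="session")
def fixture_records():
    """All rows of the packaged study-summary fixture."""
    return parse_performance_table(packaged_fixture_path())


@pytest.fixture(scope="session")
def overall_summary(fixture_records):
    return next(r for r in fixture_records if r.pathway_label == "overall")


@pytest.fixture(scope="session")
def overall_counts(overall_summary) -> ConfusionCounts:
    """Confusion matrix reconstructed from the pooled-cohort printed summary."""
    return reconstruct_counts(overall_summary)
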