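import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from boseq.report import simulate_study  # noqa: E402


@pytest.fixture(scope="session")
def small_study():
    """Shared modest-size simulated study (10k reads/condition)."""
    return simulate_study(seed=11, n_reads=10_000, pretrna_fraction=0.05)


@pytest.fixture(scope="session")
def small_counts(small_study):
    from boseq.counts import align_and_count

    tables, filtered, removed = align_and_count(
        small_study["reads"], small_study["ref"]
    )
    return {"tables": tables, "filtered": filtered, "removed": removed}
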