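import pytest
from hypothesis import HealthCheck, settings

from phylocount.fixtures import FixtureSpec, generate_fixtures

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ranked_fixture_trees():
    """Random ranked constraint trees, small enough for oracle enumeration."""
    return generate_fixtures(
        FixtureSpec(seed=20240601, count=60, kind="ranked", max_leaves=6, max_interior=4)
    )


@pytest.fixture(scope="session")
def fr_fixture_trees():
    """Random fully ranked constraint trees, oracle-enumerable."""
    return generate_fixtures(
        FixtureSpec(
            seed=20240602, count=40, kind="fully-ranked",
            max_leaves=6, max_interior=3, max_levels=5,
        )
    )
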