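import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def community1():
    """Default synthetic community, seed 1 (shared — generation is pure)."""
    from symbiocheck.community import default_community

    return default_community(seed=1)


@pytest.fixture(scope="session")
def binned1(community1):
    """Filtered scaffolds, hits, assignments and bins for the seed-1 community."""
    from symbiocheck import binning

    params = binning.BinningParams()
    kept, dropped = binning.filter_scaffolds(community1.scaffolds, params)
    hits = [
        h for sc in kept for h in binning.translated_search(sc, community1.protein_db, params)
    ]
    assignments = binning.assign_bins(hits, kept)
    bins, summaries = binning.finalize_bins(assignments, kept, params)
    return dict(
        params=params, kept=kept, dropped=dropped, hits=hits,
        assignments=assignments, bins=bins, summaries=summaries,
    )


@pytest.fixture(scope="session")
def reports1(community1, binned1):
    """Gene census reports for the seed-1 community."""
    from symbiocheck.census import CensusParams, run_census
    from symbiocheck.community import TG_CONTAMINANT

    params = CensusParams(contaminants=(TG_CONTAMINANT,))
    return run_census(
        community1.panel, binned1["bins"]["buchnera"], binned1["kept"], params
    )
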