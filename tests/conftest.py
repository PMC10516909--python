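import pytest

import fluxscan as fs
from fluxscan.toyfixtures import ToySpec, build_random_toy, build_toy1

#: Seeds of the random-fixture test matrix.
FIXTURE_SEEDS = tuple(range(1, 21))


def random_fixture(seed: int):
    """Seeded random toy with maintenance on even seeds."""
    return build_random_toy(ToySpec(seed=seed, include_maintenance=(seed % 2 == 0)))


@pytest.fixture
def toy1():
    return build_toy1()


@pytest.fixture(scope="session")
def toy1_pipeline():
    """TOY1 run end-to-end once; read-only results shared across tests."""
    model = build_toy1()
    init = fs.initialize_scan(model, "R2", "EX_P")
    schedule = fs.build_step_schedule(init.target_max)
    table = fs.run_scan(model, "R2", "EX_P", schedule)
    filtered = fs.filter_valid_profiles(table)
    classifications = fs.classify_reactions(filtered)
    from fluxscan.scoring import score_profiles

    swf = score_profiles({p.reaction_id: p.flux_values for p in filtered.profiles})
    up = fs.rank_candidates(classifications, swf, "upregulation")
    down = fs.rank_candidates(classifications, swf, "downregulation")
    essentiality = fs.screen_essentiality(model, None, "R2")
    return {
        "model": model,
        "init": init,
        "schedule": schedule,
        "table": table,
        "filtered": filtered,
        "classifications": classifications,
        "swf": swf,
        "upregulation": up,
        "downregulation": down,
        "essentiality": essentiality,
    }


@pytest.fixture(scope="session")
def fixture_scans():
    """Scan + classification for every seeded random fixture (computed once)."""
    results = {}
    for seed in FIXTURE_SEEDS:
        model = random_fixture(seed)
        init = fs.initialize_scan(model, "BIOMASS", "DM_T")
        schedule = fs.build_step_schedule(init.target_max)
        table = fs.run_scan(model, "BIOMASS", "DM_T", schedule)
        filtered = fs.filter_valid_profiles(table)
        classified = {
            c.reaction_id: (c.reaction_type, c.proportionality)
            for c in fs.classify_reactions(filtered)
        }
        results[seed] = {
            "model": model,
            "schedule": schedule,
            "table": table,
            "classified": classified,
        }
    return results
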