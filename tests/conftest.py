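import numpy as np
import pytest

import sigdecon as sd
from sigdecon.hierarchy import CellHierarchy

SEED = 7


@pytest.fixture(scope="session")
def default_hierarchy():
    return sd.load_default_hierarchy()


@pytest.fixture(scope="session")
def flat2():
    """Two leaves directly under the root (level-1 comparisons only)."""
    return CellHierarchy.from_mapping({"root": {"alpha": {}, "beta": {}}})


@pytest.fixture(scope="session")
def deep8():
    """Eight leaves, all at level 3 (selection budget k=20 > markers/type)."""
    return CellHierarchy.from_mapping(
        {
            "root": {
                "lineage_a": {
                    "sub_a1": {"a1x": {}, "a1y": {}},
                    "sub_a2": {"a2x": {}, "a2y": {}},
                },
                "lineage_b": {
                    "sub_b1": {"b1x": {}, "b1y": {}},
                    "sub_b2": {"b2x": {}, "b2y": {}},
                },
            }
        }
    )


@pytest.fixture(scope="session")
def ref_default(default_hierarchy):
    """Planted-marker reference at the generator's default conditions."""
    return sd.generate_reference(sd.GenerativeSpec(seed=SEED), default_hierarchy)


@pytest.fixture(scope="session")
def posterior_default(ref_default):
    return sd.fit_abundance_model(ref_default, nodes="all")


@pytest.fixture(scope="session")
def markers_default(posterior_default, default_hierarchy):
    return sd.select_markers(posterior_default, default_hierarchy)


@pytest.fixture(scope="session")
def signature_default(posterior_default, markers_default, default_hierarchy):
    return sd.build_signature_matrix(
        posterior_default, markers_default, default_hierarchy
    )


@pytest.fixture(scope="session")
def clinical_pool():
    return sd.generate_clinical(400, event_rate=0.7, scale=1000.0, seed=11)


@pytest.fixture(scope="session")
def bench_condition(ref_default, signature_default, clinical_pool, default_hierarchy):
    """Cached 63-run benchmark results keyed by (S, P), paired seeds."""
    cache: dict[tuple[float, float], sd.BenchmarkResult] = {}
    foreign = sd.generate_foreign_profile(
        sd.GenerativeSpec(seed=SEED), default_hierarchy
    )

    def run(slope: float, foreign_prop: float) -> sd.BenchmarkResult:
        key = (slope, foreign_prop)
        if key not in cache:
            cfg = sd.SimulationConfig(
                n_samples=250,
                slope=slope,
                foreign_prop=foreign_prop,
                runs_per_condition=63,
                seed=SEED,
            )
            cache[key] = sd.run_benchmark(
                cfg,
                ref_default,
                signature_default,
                clinical_pool,
                foreign_profile=foreign if foreign_prop > 0 else None,
            )
        return cache[key]

    return run


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
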