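import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mirenrich as mr

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def toy_preds():
    """miRNA a targets {g1, g2}; b targets {g2, g3}."""
    return mr.TargetPredictionSet({("a", "g1"): 1, ("a", "g2"): 1, ("b", "g2"): 1, ("b", "g3"): 1})


@pytest.fixture
def toy_ann():
    """Universe {g1..g6}; T1 = {g1,g2,g3}, T2 = {g4}."""
    return mr.AnnotationSet(
        {"T1": {"g1", "g2", "g3"}, "T2": {"g4"}},
        universe={"g1", "g2", "g3", "g4", "g5", "g6"},
    )


@pytest.fixture
def multihit_preds():
    """a → g1 x2, g2 x1; b → g2 x3."""
    return mr.TargetPredictionSet({("a", "g1"): 2, ("a", "g2"): 1, ("b", "g2"): 3})


@pytest.fixture
def multihit_ann():
    return mr.AnnotationSet({"TA": {"g2"}, "TB": {"g1", "g3"}})


def _random_toy(seed: int, n_mirnas: int = 8, n_genes: int = 30, n_terms: int = 6):
    """Small random universe for enumeration-oracle comparisons."""
    rng = np.random.default_rng(seed)
    mirnas = [f"m{i}" for i in range(n_mirnas)]
    genes = [f"g{j:02d}" for j in range(n_genes)]
    sites = {}
    for m in mirnas:
        for g in genes:
            if rng.random() < 0.25:
                sites[(m, g)] = int(rng.integers(1, 4))
    preds = mr.TargetPredictionSet(sites)
    terms = {
        f"T{t}": frozenset(rng.choice(genes, size=int(rng.integers(4, 12)), replace=False))
        for t in range(n_terms)
    }
    ann = mr.AnnotationSet(terms, universe=genes)
    return preds, ann


@pytest.fixture
def small_random_toy():
    return _random_toy(seed=7)


@pytest.fixture(scope="session")
def small_synthetic():
    """Reduced-scale synthetic dataset for fast distribution checks."""
    cfg = mr.SyntheticConfig(
        n_genes=600, n_mirnas=60, n_terms=30, term_size_max=80, seed=17,
        term_bias_spec=((0, 2.0), (1, 2.0), (2, -2.0), (3, -2.0)),
    )
    preds, ann, cov = mr.generate_dataset(cfg)
    return cfg, preds, ann, cov


@pytest.fixture(scope="session")
def small_unbiased_synthetic():
    cfg = mr.SyntheticConfig.unbiased(
        n_genes=600, n_mirnas=60, n_terms=30, term_size_max=80, seed=17
    )
    preds, ann, cov = mr.generate_dataset(cfg)
    return cfg, preds, ann, cov
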