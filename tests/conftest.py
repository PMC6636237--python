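import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scanassist import EntityKind, KnowledgeBase, demo_kb, fig5_kb

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fig5():
    return fig5_kb()


@pytest.fixture(scope="session")
def demo():
    return demo_kb()


def random_kb(rng: np.random.Generator) -> KnowledgeBase:
    """A random valid KB: every sign has a view, every disorder a sign."""
    n_signs = int(rng.integers(1, 8))
    n_disorders = int(rng.integers(1, 6))
    n_views = int(rng.integers(1, 5))
    kb = KnowledgeBase()
    signs = [f"epo:s{i}" for i in range(n_signs)]
    disorders = [f"epo:d{i}" for i in range(n_disorders)]
    views = [f"epo:v{i}" for i in range(n_views)]
    for iri in signs:
        kb.declare(iri, EntityKind.SIGN, iri.split(":")[1].upper())
    for iri in disorders:
        kb.declare(iri, EntityKind.DISORDER, iri.split(":")[1].upper())
    for iri in views:
        kb.declare(iri, EntityKind.ECHOGRAPHIC_VIEW, iri.split(":")[1].upper())
    for sign in signs:
        for view in rng.choice(views, size=int(rng.integers(1, n_views + 1)), replace=False):
            kb.add(sign, "epo:requires_view", str(view))
    for disorder in disorders:
        for sign in rng.choice(signs, size=int(rng.integers(1, n_signs + 1)), replace=False):
            kb.add(disorder, "epo:has_sign", str(sign))
    return kb


def brute_force_pairs(kb: KnowledgeBase, predicate: str) -> set[tuple[str, str]]:
    """Linear scan over all triples — the oracle the indexes must match."""
    return {
        (t.subject, t.object)
        for t in kb.triples()
        if t.predicate == predicate
    }
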