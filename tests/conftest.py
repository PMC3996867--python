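import random

import pytest

from tstcnet import (
    GeneratorConfig,
    SRDAG,
    classify,
    random_srdag,
    read_enewick,
)


@pytest.fixture
def diamond():
    """Root r with two elementary children u, w meeting in a hybrid leaf h labeled 1."""
    return SRDAG.from_arcs([("r", "u"), ("r", "w"), ("u", "h"), ("w", "h")], {"h": "1"})


@pytest.fixture
def tree12():
    """The two-leaf phylogenetic tree (1,2);"""
    return read_enewick("(1,2);")


@pytest.fixture
def inconsistent_triangle():
    """Both parents of hybrid h connected by a tree arc: never time consistent."""
    return SRDAG.from_arcs([("r", "h"), ("r", "x"), ("x", "h")], {"h": "1"})


def srdag_batch(count, seed0, min_nodes=3, max_nodes=12):
    """Seeded, size-varied random S-rDAGs (hybrid-rich at the higher probs)."""
    rng = random.Random(seed0)
    out = []
    while len(out) < count:
        n = rng.randint(min_nodes, max_nodes)
        cfg = GeneratorConfig(
            n_nodes=n,
            n_labels=rng.randint(1, max(1, n // 2)),
            extra_arc_prob=rng.choice([0.0, 0.1, 0.25, 0.4]),
            seed=rng.randrange(2**31),
        )
        try:
            out.append(random_srdag(cfg))
        except ValueError:
            continue
    return out


def non_tree_batch(count, seed0, **kw):
    """Random S-rDAGs that are not phylogenetic trees (hybrid or elementary node)."""
    rng = random.Random(seed0)
    out = []
    while len(out) < count:
        for g in srdag_batch(count, rng.randrange(2**31), **kw):
            cls = classify(g.graph)
            if any(c.is_hybrid or c.is_elementary for c in cls.nodes.values()):
                out.append(g)
                if len(out) == count:
                    break
    return out
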