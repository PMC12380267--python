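"""Shared fixtures and randomized-model helpers."""

from __future__ import annotations

import numpy as np
import pytest

from odegraph import ModelGraph
from odegraph.expression import Call, Leaf
from odegraph.fixtures import (
    build_extended_sir,
    build_immune_model,
    build_predator_prey,
    build_sir,
)
from odegraph.simulation import SimulationConfig

LISTING2_SOURCE = '''\
import math

@node
def sin(x):
    return math.sin(x)

@node(format="$1 ^ $2")
def pow(x, y):
    return x ** y
'''


@pytest.fixture
def sir_graph():
    return build_sir()


@pytest.fixture
def extended_sir_graph():
    return build_extended_sir()


@pytest.fixture
def immune_graph():
    return build_immune_model()


@pytest.fixture
def predator_prey_graph():
    return build_predator_prey()


@pytest.fixture(params=["sir", "extended-sir", "immune", "predator-prey"])
def any_fixture_graph(request):
    from odegraph.fixtures import ALL_FIXTURES

    return ALL_FIXTURES[request.param]()


@pytest.fixture
def listing2_file(tmp_path):
    """A plugin file defining sin (arity 1) and pow (arity 2, custom format)."""
    path = tmp_path / "trig_ext.py"
    path.write_text(LISTING2_SOURCE, encoding="utf-8")
    return path


def build_decay(k: float = 1.0, x0: float = 1.0) -> ModelGraph:
    """dX/dt = -k*X via the subtraction-fold negation idiom."""
    g = ModelGraph("decay")
    X = g.add_term("X", x0)
    kk = g.add_term("k", k)
    kx = g.add_expression("*", "kX", 2)
    g.connect(kk, kx, 0)
    g.connect(X, kx, 1)
    neg = g.add_expression("-", "X eq", 3)
    for pin in range(3):
        g.connect(kx, neg, pin)
    g.connect(neg, g.add_assigner(X), 0)
    g.sim_config = SimulationConfig(0.0, 0.1, 5.0)
    return g


def random_valid_graph(rng: np.random.Generator) -> ModelGraph:
    """A small random graph that passes validation.

    Expressions only ever connect from already-created nodes, so the result
    is acyclic by construction; every expression pin is filled and at least
    one term gets an assigner.
    """
    g = ModelGraph(name=f"random-{rng.integers(1 << 30)}",
                   notes="randomized test model")
    n_terms = int(rng.integers(2, 7))
    terms = []
    for i in range(n_terms):
        pos = ((float(rng.uniform(-100, 100)), float(rng.uniform(-100, 100)))
               if rng.random() < 0.5 else None)
        terms.append(g.add_term(f"T{i}", float(rng.normal()), position=pos))
    sources = list(terms)
    for i in range(int(rng.integers(0, 5))):
        op = rng.choice(["+", "-", "*", "/"])
        arity = int(rng.integers(2, 5))
        e = g.add_expression(str(op), f"expr {i}", arity)
        for pin in range(arity):
            g.connect(str(rng.choice(sources)), e, pin)
        sources.append(e)
    n_assigned = int(rng.integers(1, n_terms + 1))
    for t in rng.choice(terms, size=n_assigned, replace=False):
        a = g.add_assigner(str(t))
        g.connect(str(rng.choice(sources)), a, 0)
    g.sim_config = SimulationConfig(
        start_time=float(rng.uniform(0, 5)),
        time_step=float(rng.uniform(0.01, 1.0)),
        end_time=float(rng.uniform(5, 50)),
        x_label="t", y_label="value",
        rel_tol=1e-6, abs_tol=1e-9,
    )
    if rng.random() < 0.3:
        g.extension_refs = ["some_extension.py"]
    return g


def random_tree(rng: np.random.Generator, names: list[str],
                depth: int = 3):
    """A random arithmetic expression tree over the given leaf names."""
    if depth == 0 or rng.random() < 0.35:
        name = str(rng.choice(names))
        return Leaf(term_id=name, name=name)
    op = str(rng.choice(["+", "-", "*", "/"]))
    arity = int(rng.integers(2, 4))
    children = tuple(random_tree(rng, names, depth - 1)
                     for _ in range(arity))
    return Call(op, children)
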