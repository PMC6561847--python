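import numpy as np
import pytest

from pobds import PobdsModel, parse_rules


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def toy3_net():
    """A 3-gene network with non-trivial dynamics."""
    return parse_rules("A = B OR C\nB = NOT A\nC = A AND B\n")


@pytest.fixture
def toy3_model(toy3_net):
    return PobdsModel(toy3_net, p=0.12, lam=10.0, delta=30.0, sigma=20.0)


@pytest.fixture
def unit_model():
    """The 1-gene constant-OFF model behind the worked filter example."""
    return PobdsModel(parse_rules("A = 0\n"), p=0.1, lam=10.0, delta=30.0, sigma=20.0)


def random_model(rng, n, T_unused=None, p=None):
    """A random n-gene POBDS: random truth-table-free rules built from
    random pairwise AND/OR/NOT combinations."""
    genes = [f"g{j}" for j in range(n)]
    lines = []
    for g in genes:
        a, b = rng.choice(genes, size=2)
        op = rng.choice(["AND", "OR"])
        neg_a = "NOT " if rng.random() < 0.5 else ""
        neg_b = "NOT " if rng.random() < 0.5 else ""
        lines.append(f"{g} = {neg_a}{a} {op} {neg_b}{b}")
    net = parse_rules("\n".join(lines))
    return PobdsModel(
        net,
        p=float(rng.uniform(0.01, 0.3)) if p is None else p,
        lam=rng.uniform(5, 15, n),
        delta=rng.uniform(20, 40, n),
        sigma=float(rng.uniform(10, 30)),
    )
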