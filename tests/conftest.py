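import numpy as np
import pytest

import geolot as gl


@pytest.fixture(scope="session")
def og():
    """Original grammar: 12 geometric atomic productions."""
    return gl.build_grammar()


@pytest.fixture(scope="session")
def eg():
    """Extended grammar: original plus 11 ad-hoc atomic productions."""
    return gl.build_grammar(include_adhoc=True)


@pytest.fixture(scope="session")
def adult_theta(og):
    return gl.adult_like_theta(og)


@pytest.fixture(scope="session")
def adult_dataset(og):
    """300 synthetic eight-point trials generated under the default theta."""
    return gl.generate_dataset(gl.GeneratorConfig(n_trials=300, length=8, seed=11), og)


@pytest.fixture(scope="session")
def adult_posterior(og, adult_dataset):
    """Shared Gibbs run on the 300-trial synthetic dataset (4 chains x 50)."""
    return gl.gibbs_infer(adult_dataset, og, gl.InferenceConfig(seed=23))


def random_program(rng, symbols, max_depth=4, rep_range=(2, 8)):
    """A random derivation tree over the given atomic symbols."""
    if max_depth == 0 or rng.random() < 0.4:
        return gl.atomic(symbols[rng.integers(len(symbols))])
    r = rng.random()
    n = int(rng.integers(rep_range[0], rep_range[1] + 1))
    sub = lambda: random_program(rng, symbols, max_depth - 1, rep_range)
    if r < 0.5:
        return gl.concat(sub(), sub())
    if r < 0.7:
        return gl.rep0(sub(), n)
    if r < 0.85:
        return gl.rep1(sub(), n, symbols[rng.integers(len(symbols))])
    return gl.rep2(sub(), n, symbols[rng.integers(len(symbols))])


def random_inputs(rng, n, lengths, anchors=range(8)):
    """Random (anchor, sequence) pairs with lengths drawn from ``lengths``."""
    anchors = list(anchors)
    out = []
    for _ in range(n):
        L = int(rng.choice(lengths))
        out.append(
            (
                int(rng.choice(anchors)),
                tuple(int(x) for x in rng.integers(0, 8, size=L)),
            )
        )
    return out
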