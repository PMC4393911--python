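import numpy as np
import pandas as pd
import pytest

from bmsf.morphometry import parse_swc
from bmsf.synthetic import TreeSpec, generate_toy_swc


def swc_text(rows):
    """Build SWC text from (id, type, x, y, z, radius, parent) tuples."""
    return "\n".join(" ".join(str(v) for v in row) for row in rows) + "\n"


@pytest.fixture
def two_stem_tree():
    """Soma with two stems; one stem bifurcates once into two tips.

    Hand-countable: N_s=2, N_bi=1, N_t=3, N_br=4, BO=1, Fr=6.
    """
    return parse_swc(swc_text([
        (1, 1, 0, 0, 0, 5, -1),
        (2, 3, 10, 0, 0, 1, 1),
        (3, 3, 20, 0, 0, 1, 2),
        (4, 3, 30, 10, 0, 0.5, 3),
        (5, 3, 30, -10, 0, 0.5, 3),
        (6, 3, 0, 10, 0, 1, 1),
    ]))


@pytest.fixture
def symmetric_y():
    """Bifurcation with dp=2, d1=d2=1, daughters at +/-60 deg from the
    parent axis (so 120 deg between them); both daughters are tips."""
    s = np.sqrt(3) / 2 * 10  # 8.660254
    return parse_swc(swc_text([
        (1, 1, 0, 0, 0, 2, -1),
        (2, 3, 10, 0, 0, 1, 1),
        (3, 3, 15, s, 0, 0.5, 2),
        (4, 3, 15, -s, 0, 0.5, 2),
    ]))


def random_tree(seed, **overrides):
    kwargs = dict(branch_prob=0.6, max_depth=4, stem_count=2, seed=seed)
    kwargs.update(overrides)
    return parse_swc(generate_toy_swc(TreeSpec(**kwargs)))


def make_table(features: dict, labels) -> pd.DataFrame:
    table = pd.DataFrame(features)
    table["label"] = list(labels)
    return table


def two_gaussians(n_per_class=30, sep=4.0, n_noise=0, seed=0):
    """Well-separated two-class table: one informative feature shifted
    by ``sep`` SD, plus optional pure-noise features."""
    rng = np.random.default_rng(seed)
    y = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    x = rng.standard_normal(2 * n_per_class)
    x[n_per_class:] += sep
    cols = {"inf": x}
    for j in range(n_noise):
        cols[f"noise{j}"] = rng.standard_normal(2 * n_per_class)
    return make_table(cols, y)
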