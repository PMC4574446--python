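import numpy as np
import pytest

from biocad.model_core import make_toy_mitochondrion


@pytest.fixture(scope="session")
def toy_model():
    """The seed-42 toy mitochondrion used across the suite."""
    return make_toy_mitochondrion(42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


SMALL_NETWORK = """\
EX_A\tA ->\t-5\t0
EX_O\tO ->\t-3\t0
R1\tA -> 2 B\t0\t10
R2\tB + 0.5 O -> C\t0\t10
R3\tB -> C\t0\t1
EX_C\tC ->\t0\t100
"""


@pytest.fixture(scope="session")
def small_model(tmp_path_factory):
    """Six-reaction network, small enough for exhaustive vertex enumeration.

    Max export of C is 7: R2 is limited to 6 by the O supply (0.5 per unit)
    and the bypass R3 adds one more.
    """
    from biocad.model_core import read_model

    p = tmp_path_factory.mktemp("models") / "small.tsv"
    p.write_text(SMALL_NETWORK)
    return read_model(p, "tabular")


def lp_max_by_vertex_enumeration(S, lb, ub, c):
    """Independent LP oracle: enumerate all basic feasible solutions of
    ``{S v = 0, lb <= v <= ub}`` and return the best objective value.

    Exponential; only for fixtures with a handful of reactions.
    """
    from itertools import combinations, product

    S = np.asarray(S, float)
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    c = np.asarray(c, float)
    m, n = S.shape
    best = None
    for basic in combinations(range(n), m):
        SB = S[:, basic]
        if abs(np.linalg.det(SB)) < 1e-10:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        for vals in product(*[(lb[j], ub[j]) for j in nonbasic]):
            v = np.zeros(n)
            v[nonbasic] = vals
            v[list(basic)] = np.linalg.solve(SB, -S[:, nonbasic] @ np.array(vals))
            if np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9):
                val = float(c @ v)
                if best is None or val > best:
                    best = val
    return best
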