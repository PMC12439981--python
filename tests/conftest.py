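import numpy as np
import pandas as pd
import pytest

from histkit.refs import H4_REFERENCE, H4_TAIL, H4_TAIL_REFERENCE
from histkit.screen import ScreenCountTable
from histkit.variants import ReferenceHistone


@pytest.fixture(scope="session")
def h4_ref():
    return H4_REFERENCE


@pytest.fixture(scope="session")
def tail_ref():
    return H4_TAIL_REFERENCE


@pytest.fixture(scope="session")
def wt_tail():
    return H4_TAIL


@pytest.fixture
def toy_ref():
    return ReferenceHistone(family="toy", sequence="SGRG")


class FractionOfResidueScorer:
    """Toy design objective: fraction of positions equal to a marker residue."""

    def __init__(self, residue="D"):
        self.residue = residue

    def predict(self, seqs):
        return np.array([s.count(self.residue) / len(s) for s in seqs])


@pytest.fixture
def d_scorer():
    return FractionOfResidueScorer("D")


def make_table(counts, conditions, replicates=None, controls=()):
    """Assemble a ScreenCountTable from a counts DataFrame and condition list."""
    samples = list(counts.columns)
    if replicates is None:
        replicates = list(range(1, len(samples) + 1))
    meta = pd.DataFrame(
        {"replicate": replicates, "condition": conditions}, index=samples
    )
    return ScreenCountTable(counts, meta, list(controls))


@pytest.fixture
def small_nb_table():
    """40 constructs + 4 controls, 2x2 design, NB counts, a few planted effects."""
    rng = np.random.default_rng(11)
    n = 40
    mu = rng.lognormal(5.5, 0.6, n)
    lfc = np.zeros(n)
    lfc[:6] = np.array([2.5, -2.5, 3.0, -3.0, 2.0, -2.0])
    cols = {}
    for name, cond in [
        ("r1_high", "high_bin"),
        ("r2_high", "high_bin"),
        ("r1_low", "low_bin"),
        ("r2_low", "low_bin"),
    ]:
        m = mu * np.where(cond == "high_bin", 2.0**lfc, 1.0)
        r = 1 / 0.05
        cols[name] = rng.negative_binomial(r, r / (r + m))
    counts = pd.DataFrame(cols, index=[f"c{i:02d}" for i in range(n)])
    ctrl = pd.DataFrame(
        {k: rng.poisson(300, 4) for k in cols}, index=[f"ctrl{i}" for i in range(4)]
    )
    counts = pd.concat([counts, ctrl])
    return make_table(
        counts,
        conditions=["high_bin", "high_bin", "low_bin", "low_bin"],
        replicates=[1, 2, 1, 2],
        controls=[f"ctrl{i}" for i in range(4)],
    ), lfc
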