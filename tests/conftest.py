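import numpy as np
import pandas as pd
import pytest

from diallelkit import phenio, synthdata


def make_table(cell_values: dict, blocks: int = 2, trait: str = "y", noise=None, rng=None):
    """Build a complete half-diallel table from {(a, b): genotype value}.

    Every block gets the genotype value (plus optional per-plot noise drawn
    from ``rng`` with sd ``noise``), so genotype means equal the inputs when
    noise is None.
    """
    parents = sorted({p for pair in cell_values for p in pair})
    rows = []
    for (a, b), v in cell_values.items():
        for blk in range(1, blocks + 1):
            eps = rng.normal(0, noise) if noise else 0.0
            rows.append(
                {"parent_a": a, "parent_b": b, "block": blk, "trait": trait, "value": v + eps}
            )
    df = pd.DataFrame(rows)
    return phenio.from_dataframe(df, phenio.ParentSet(tuple(parents)))


def full_diallel_values(p: int, fn):
    """{(a, b): fn(i, j)} over all unordered pairs of p parents."""
    ids = [f"P{k + 1:02d}" for k in range(p)]
    return {(ids[i], ids[j]): fn(i, j) for i in range(p) for j in range(i, p)}


@pytest.fixture
def toy3_table():
    """3 parents, 2 blocks, hand-enumerable values."""
    cells = {
        ("A", "A"): 10.0,
        ("A", "B"): 12.0,
        ("A", "C"): 14.0,
        ("B", "B"): 8.0,
        ("B", "C"): 11.0,
        ("C", "C"): 9.0,
    }
    return make_table(cells, blocks=2)


@pytest.fixture(scope="session")
def sim10_table():
    """Seeded 10-parent, 3-block simulated diallel with truth record."""
    cfg = synthdata.DiallelSimConfig(p=10, b=3, traits=("t1", "t2"), seed=20240901)
    return synthdata.simulate_diallel(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
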