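"""Shared fixtures and hypothesis settings."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rgselect.tables_io import CtMatrix, Sample

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_ct(gene_rows: dict[str, list[float]], stages=("IM", "MG", "B", "MR"),
            n_bio: int | None = None) -> CtMatrix:
    """Ct matrix from per-gene value lists laid out stage-major.

    Each gene's list has one value per (stage, bio_rep) cell; the number
    of biological replicates is inferred from the list length.
    """
    genes = list(gene_rows)
    n_vals = len(next(iter(gene_rows.values())))
    n_bio = n_bio or n_vals // len(stages)
    assert n_bio * len(stages) == n_vals
    samples = [
        Sample(f"{st}.b{b}", st, b, 1)
        for st in stages
        for b in range(1, n_bio + 1)
    ]
    return CtMatrix(genes, samples, np.array([gene_rows[g] for g in genes], float))


@pytest.fixture
def three_gene_ct() -> CtMatrix:
    """Two proportional genes plus one flat gene over four samples."""
    samples = [Sample(f"s{i}", "IM", i, 1) for i in range(1, 5)]
    return CtMatrix(
        ["G1", "G2", "G3"],
        samples,
        np.array([[20.0, 21.0, 22.0, 23.0],
                  [25.0, 26.0, 27.0, 28.0],
                  [20.0, 20.0, 20.0, 20.0]]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
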