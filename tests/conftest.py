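import numpy as np
import pytest
from scipy import sparse

from profmat import Outcome, TernaryMatrix


def matrix_from_codes(codes) -> TernaryMatrix:
    """Build a matrix from a dense int grid: 0 untested, 1 active, 2 inactive."""
    codes = np.asarray(codes, dtype=np.int8)
    n_r, n_c = codes.shape
    return TernaryMatrix(
        [f"r{i}" for i in range(n_r)],
        [f"c{j}" for j in range(n_c)],
        sparse.csr_matrix(codes),
    )


def random_matrix(
    rng: np.random.Generator,
    n_rows: int | None = None,
    n_cols: int | None = None,
    p_tested: float | None = None,
    p_active: float = 0.3,
    max_dim: int = 8,
) -> TernaryMatrix:
    """Random ternary matrix for test batteries (seeded rng in, matrix out)."""
    if n_rows is None:
        n_rows = int(rng.integers(1, max_dim + 1))
    if n_cols is None:
        n_cols = int(rng.integers(1, max_dim + 1))
    if p_tested is None:
        p_tested = float(rng.uniform(0.2, 0.9))
    codes = rng.choice(
        [0, 1, 2],
        size=(n_rows, n_cols),
        p=[1 - p_tested, p_tested * p_active, p_tested * (1 - p_active)],
    )
    return matrix_from_codes(codes)


@pytest.fixture
def toy3x3() -> TernaryMatrix:
    """Staircase matrix: rows tested in 3, 2 and 1 cells of 3 columns.

    Greedy complete-matrix extraction should delete r3 then c3 and keep the
    fully tested 2x2 block {r1, r2} x {c1, c2}.
    """
    return TernaryMatrix.from_cells(
        ["r1", "r2", "r3"],
        ["c1", "c2", "c3"],
        {
            ("r1", "c1"): Outcome.INACTIVE,
            ("r1", "c2"): Outcome.ACTIVE,
            ("r1", "c3"): Outcome.INACTIVE,
            ("r2", "c1"): Outcome.INACTIVE,
            ("r2", "c2"): Outcome.INACTIVE,
            ("r3", "c1"): Outcome.ACTIVE,
        },
    )
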