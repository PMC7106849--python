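import itertools
from fractions import Fraction

import numpy as np
import pytest

from isopanel import GeneModel, Probe, SimulationConfig, build_incidence_matrix


@pytest.fixture
def fli1_gene():
    """A four-isoform gene modeled on the FLI1 worked design: three isoforms
    measured by singleton probes, the fourth derived from the max probe."""
    return GeneModel(
        "FLI1", ("NM_001271012", "NM_001167681", "NM_001271010", "NM_002017")
    )


@pytest.fixture
def fli1_probes(fli1_gene):
    return [
        Probe("FLI1_max", "FLI1", fli1_gene.isoform_ids),
        Probe("FLI1_p1", "FLI1", ("NM_001271012",)),
        Probe("FLI1_p2", "FLI1", ("NM_001167681",)),
        Probe("FLI1_p3", "FLI1", ("NM_001271010",)),
    ]


@pytest.fixture
def fli1_matrix(fli1_gene, fli1_probes):
    return build_incidence_matrix(fli1_gene, fli1_probes)


@pytest.fixture
def small_cfg():
    """A desk-scale study configuration: 20 genes, 6 samples, 3 tissues."""
    return SimulationConfig(
        n_genes=20, n_samples=6, tissue_weights=(2, 2, 2), seed=11
    )


# ---------------------------------------------------------------- oracles


def minor_rank(A) -> int:
    """Matrix rank by brute-force minor expansion with exact arithmetic:
    the largest k for which some k-by-k submatrix has nonzero determinant."""

    def det(M):
        n = len(M)
        if n == 1:
            return M[0][0]
        total = Fraction(0)
        for j in range(n):
            if M[0][j] == 0:
                continue
            sub = [row[:j] + row[j + 1:] for row in M[1:]]
            total += (-1) ** j * M[0][j] * det(sub)
        return total

    A = [[Fraction(int(v)) for v in row] for row in np.asarray(A)]
    m, n = len(A), len(A[0]) if A else 0
    for k in range(min(m, n), 0, -1):
        for rows in itertools.combinations(range(m), k):
            for cols in itertools.combinations(range(n), k):
                sub = [[A[r][c] for c in cols] for r in rows]
                if det(sub) != 0:
                    return k
    return 0


def nnls_enumeration_oracle(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Global non-negative least squares by support enumeration.

    The NNLS optimum solves the unconstrained problem restricted to its own
    support, so minimising the objective over every support subset whose
    restricted least-squares solution is non-negative finds the global
    optimum exactly.  Exponential in the column count; for oracle use only.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    n = A.shape[1]
    best_x = np.zeros(n)
    best_obj = float(y @ y)
    for r in range(1, n + 1):
        for support in itertools.combinations(range(n), r):
            sub = A[:, support]
            xs, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if (xs < -1e-12).any():
                continue
            x = np.zeros(n)
            x[list(support)] = np.clip(xs, 0.0, None)
            obj = float(np.sum((y - A @ x) ** 2))
            if obj < best_obj:
                best_obj, best_x = obj, x
    return best_x, best_obj
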