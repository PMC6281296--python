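import numpy as np
import pytest

from regulonatlas.activity import AUCParameters, score_all
from regulonatlas.synthetic import default_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """The standard planted fixture: 500 cells x 2,000 genes, 12 regulons."""
    return default_benchmark()


@pytest.fixture(scope="session")
def benchmark_ras(benchmark):
    expr, _, regulons, _ = benchmark
    return score_all(expr, regulons, AUCParameters(seed=1))


def auc_step_oracle(rank_order, regulon_indices, k):
    """Independent recovery-curve oracle: explicit step-sum over x = 1..k."""
    regulon = set(regulon_indices)
    total = 0
    for x in range(1, k + 1):
        total += sum(1 for g in rank_order[:x] if g in regulon)
    best = sum(min(x, len(regulon)) for x in range(1, k + 1))
    return total / best


def csi_triple_loop_oracle(pcc):
    """Exhaustive CSI: count qualifying third regulons pair by pair."""
    pcc = np.asarray(pcc, dtype=float)
    n = pcc.shape[0]
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            t = pcc[i, j]
            count = 0
            for c in range(n):
                if c in (i, j):
                    continue
                if pcc[i, c] < t and pcc[j, c] < t:
                    count += 1
            out[i, j] = count / (n - 2)
    return out
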