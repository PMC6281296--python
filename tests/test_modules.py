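import numpy as np
import pandas as pd
import pytest

from regulonatlas.datatypes import ActivityMatrix, CellAnnotation
from regulonatlas.modules import (
    csi,
    detect_modules,
    module_activity,
    module_activity_table,
    pairwise_pcc,
    regulon_association_network,
)

from conftest import csi_triple_loop_oracle


def _activity(values):
    values = np.asarray(values, dtype=float)
    return ActivityMatrix(
        values,
        [f"u{i}" for i in range(values.shape[0])],
        [f"r{j}" for j in range(values.shape[1])],
    )


def _random_pcc(rng, n):
    x = rng.normal(size=(n + 2, n))
    return pd.DataFrame(np.corrcoef(x, rowvar=False),
                        index=[f"r{j}" for j in range(n)],
                        columns=[f"r{j}" for j in range(n)])


def test_pairwise_pcc_identity_negation_and_formula():
    rng = np.random.default_rng(0)
    col = rng.random(4)
    other = rng.random(4)
    act = _activity(np.column_stack([col, 1 - col + 0.0, other]))
    # rescale the second column into [0,1]: perfect anti-correlation remains
    pcc = pairwise_pcc(act)
    assert pcc.iloc[0, 0] == pytest.approx(1.0)
    assert pcc.iloc[0, 1] == pytest.approx(-1.0)
    manual = np.cov(col, other, ddof=0)[0, 1] / (col.std() * other.std())
    assert pcc.iloc[0, 2] == pytest.approx(manual, abs=1e-12)


def test_pairwise_pcc_preconditions(caplog):
    with pytest.raises(ValueError, match="3 units"):
        pairwise_pcc(_activity(np.ones((2, 3))))
    act = _activity(np.column_stack([np.full(4, 0.5), [0.1, 0.2, 0.3, 0.4],
                                     [0.4, 0.1, 0.3, 0.2]]))
    with caplog.at_level("WARNING"):
        pcc = pairwise_pcc(act)
    assert list(pcc.index) == ["r1", "r2"]
    assert "zero-variance" in caplog.text


def test_csi_boundary_pairs():
    # r0-r1 have the strictly highest PCC involving either; r1-r2 the lowest
    P = pd.DataFrame(
        [[1.0, 0.9, 0.1, 0.3],
         [0.9, 1.0, 0.0, 0.2],
         [0.1, 0.0, 1.0, 0.5],
         [0.3, 0.2, 0.5, 1.0]],
        index=list("abcd"), columns=list("abcd"))
    C = csi(P)
    assert C.loc["a", "b"] == 1.0
    assert C.loc["b", "c"] == 0.0
    assert np.all(np.diag(C) == 1.0)


def test_csi_matches_triple_loop_oracle():
    rng = np.random.default_rng(1)
    for n in (4, 6, 8):
        P = _random_pcc(rng, n)
        np.testing.assert_array_equal(csi(P).to_numpy(),
                                      csi_triple_loop_oracle(P))


def test_csi_bounds_and_symmetry_random_inputs():
    rng = np.random.default_rng(2)
    for _ in range(20):
        C = csi(_random_pcc(rng, 7)).to_numpy()
        assert np.all((C >= 0) & (C <= 1))
        np.testing.assert_allclose(C, C.T, atol=1e-12)


def test_csi_preconditions():
    with pytest.raises(ValueError):
        csi(pd.DataFrame(np.eye(2)))
    bad = pd.DataFrame(np.array([[1.0, 0.5, 0.1],
                                 [0.4, 1.0, 0.2],
                                 [0.1, 0.2, 1.0]]))
    with pytest.raises(ValueError, match="symmetric"):
        csi(bad)


def _block_csi():
    names = [f"r{j}" for j in range(6)]
    C = np.full((6, 6), 0.05)
    C[:3, :3] = 0.9
    C[3:, 3:] = 0.9
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=names, columns=names)


def test_detect_modules_recovers_blocks_and_singletons():
    C = _block_csi()
    part = detect_modules(C, 2)
    members = part.members()
    assert sorted(map(sorted, members.values())) == [
        ["r0", "r1", "r2"], ["r3", "r4", "r5"]]
    singles = detect_modules(C, 6)
    assert all(len(v) == 1 for v in singles.members().values())
    with pytest.raises(ValueError):
        detect_modules(C, 0)
    with pytest.raises(ValueError):
        detect_modules(C, 7)


def test_detect_modules_order_invariant():
    """Clustering a module's CSI sub-matrix is input-order independent,
    so nested sub-module detection is just detect_modules on the
    restriction."""
    C = _block_csi()
    shuffled = C.iloc[[3, 1, 5, 0, 4, 2], [3, 1, 5, 0, 4, 2]]
    assert detect_modules(C, 2).module_of == detect_modules(shuffled, 2).module_of
    sub = C.loc[["r0", "r1", "r2"], ["r0", "r1", "r2"]]
    assert set(detect_modules(sub, 1).module_of) == {"r0", "r1", "r2"}


def test_module_activity_examples():
    values = np.array([[0.2, 0.4], [0.2, 0.4], [0.8, 0.1]])
    act = _activity(values)
    ann = CellAnnotation(pd.DataFrame(
        {"cell_id": act.unit_ids, "tissue": "t", "cell_type": ["C", "C", "D"]}))
    from regulonatlas.modules import ModulePartition

    part = ModulePartition({"r0": "M1", "r1": "M1"}, 1)
    assert module_activity(act, part, ann, "M1", "C") == pytest.approx(0.3)
    solo = ModulePartition({"r0": "M1", "r1": "M2"}, 2)
    assert module_activity(act, solo, ann, "M2", "D") == pytest.approx(0.1)
    with pytest.raises(ValueError, match="empty or unknown"):
        module_activity(act, part, ann, "M9", "C")
    table = module_activity_table(act, solo, ann)
    assert table.loc["M1", "C"] == pytest.approx(0.2)
    assert table.loc["M2", "C"] == pytest.approx(0.4)


def test_module_activity_equals_direct_double_mean():
    rng = np.random.default_rng(5)
    values = rng.random((10, 4))
    act = _activity(values)
    labels = ["C"] * 6 + ["D"] * 4
    ann = CellAnnotation(pd.DataFrame(
        {"cell_id": act.unit_ids, "tissue": "t", "cell_type": labels}))
    from regulonatlas.modules import ModulePartition

    part = ModulePartition({"r0": "M1", "r2": "M1", "r1": "M2", "r3": "M2"}, 2)
    direct = values[np.ix_(np.arange(6), [0, 2])].mean()
    assert module_activity(act, part, ann, "M1", "C") == pytest.approx(direct)


def test_regulon_association_network_strict_cutoff():
    names = list("abc")
    C = pd.DataFrame([[1.0, 0.7, 0.9],
                      [0.7, 1.0, 0.2],
                      [0.9, 0.2, 1.0]], index=names, columns=names)
    edges = regulon_association_network(C, cutoff=0.7)
    assert len(edges) == 1
    assert tuple(edges.iloc[0][["regulon_a", "regulon_b"]]) == ("a", "c")
    zero = C * 0 + np.eye(3)
    assert regulon_association_network(
        pd.DataFrame(zero.values, index=names, columns=names)).empty


def test_benchmark_modules_recovered(benchmark, benchmark_ras):
    _, _, regulons, truth = benchmark
    part = detect_modules(csi(pairwise_pcc(benchmark_ras)), 3)
    planted = {m: set(rs) for m, rs in _group(truth.module_of).items()}
    found = {m: set(rs) for m, rs in part.members().items()}
    assert sorted(map(sorted, planted.values())) == sorted(map(sorted, found.values()))


def _group(mapping):
    out = {}
    for k, v in mapping.items():
        out.setdefault(v, []).append(k)
    return out
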