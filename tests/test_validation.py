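import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.spatial.distance import squareform, pdist

from regulonatlas.validation import (
    compare_silhouettes,
    match_keywords,
    permutation_pvalue,
    replicate_ras_agreement,
    replicate_regulon_overlap,
    silhouette,
    top_rank_enrichment,
)


# ------------------------------------------------------------- silhouette

def test_silhouette_two_tight_distant_clusters():
    points = np.array([0.0, 0.1, 10.0, 10.1])
    d = np.abs(points[:, None] - points[None, :])
    scores, means = silhouette(d, ["A", "A", "B", "B"])
    # for point 0: a = 0.1, b = mean(10, 10.1) = 10.05
    assert scores[0] == pytest.approx((10.05 - 0.1) / 10.05)
    assert scores[3] == pytest.approx((10.05 - 0.1) / 10.05)
    assert set(means.index) == {"A", "B"}
    assert means["A"] == pytest.approx(scores[:2].mean())


def test_silhouette_equidistant_unit_is_zero():
    # unit 0 has a = b = 2
    d = np.array([
        [0.0, 2.0, 2.0, 2.0],
        [2.0, 0.0, 2.0, 2.0],
        [2.0, 2.0, 0.0, 1.0],
        [2.0, 2.0, 1.0, 0.0],
    ])
    scores, _ = silhouette(d, ["A", "A", "B", "B"])
    assert scores[0] == 0.0


def test_silhouette_mixed_labels_mean_near_zero():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(200, 3))
    d = squareform(pdist(x))
    labels = rng.choice(["A", "B"], size=200)
    scores, _ = silhouette(d, labels)
    assert abs(scores.mean()) < 0.05


def test_silhouette_matches_sklearn_exactly():
    from sklearn.metrics import silhouette_samples

    rng = np.random.default_rng(1)
    for _ in range(5):
        x = rng.normal(size=(30, 4))
        d = squareform(pdist(x))
        labels = rng.choice(["A", "B", "C"], size=30)
        ours, _ = silhouette(d, labels)
        ref = silhouette_samples(d, labels, metric="precomputed")
        np.testing.assert_allclose(ours, ref, atol=1e-12)


def test_silhouette_singleton_label_and_single_label():
    d = squareform(pdist(np.arange(3, dtype=float)[:, None]))
    scores, _ = silhouette(d, ["A", "A", "B"])
    assert scores[2] == 0.0
    with pytest.raises(ValueError, match="2 labels"):
        silhouette(d, ["A", "A", "A"])


def test_compare_silhouettes():
    rng = np.random.default_rng(2)
    a = rng.normal(size=30)
    t, p = compare_silhouettes(a, a.copy())
    assert t == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(0.5)
    b = rng.normal(size=30)
    _, p_shift = compare_silhouettes(b + 10 * b.std(), b)
    assert p_shift < 1e-6
    with pytest.raises(ValueError):
        compare_silhouettes([1.0], [0.0, 1.0])
    with pytest.raises(ValueError, match="degenerate"):
        compare_silhouettes([1.0, 1.0], [1.0, 1.0])


# ------------------------------------------------------------- enrichment

def test_enrichment_exact_hypergeometric_case():
    n_rel, n_unrel = 5, 95
    table = pd.DataFrame({
        "rank": np.arange(1, 101),
        "p_value": [0.001] * n_rel + [0.5] * n_unrel,
        "related": [True] * n_rel + [False] * n_unrel,
    })
    from math import comb

    assert top_rank_enrichment(table) == pytest.approx(1 / comb(100, 5), rel=1e-9)


def test_enrichment_no_significant_datasets_gives_one():
    table = pd.DataFrame({
        "rank": [1, 2, 3],
        "p_value": [0.5, 0.6, 0.7],
        "related": [True, False, False],
    })
    assert top_rank_enrichment(table) == pytest.approx(1.0)


def test_enrichment_input_validation():
    with pytest.raises(ValueError, match="columns"):
        top_rank_enrichment(pd.DataFrame({"p_value": [0.1]}))
    bad_rank = pd.DataFrame(
        {"rank": [1, 1], "p_value": [0.1, 0.2], "related": [True, False]})
    with pytest.raises(ValueError, match="unique"):
        top_rank_enrichment(bad_rank)
    all_related = pd.DataFrame(
        {"rank": [1, 2], "p_value": [0.1, 0.2], "related": [True, True]})
    with pytest.raises(ValueError, match="unrelated"):
        top_rank_enrichment(all_related)


def test_match_keywords_case_insensitive_substring():
    titles = ["Erythroblast differentiation", "Kidney atlas", "HEMATOPOIETIC stem"]
    flags = match_keywords(titles, ["erythroblast", "hematopoietic"])
    assert list(flags) == [True, False, True]


# ------------------------------------------------------------- permutation

def test_permutation_extremes_and_ties():
    universe = [f"g{i}" for i in range(50)]
    gene_set = universe[:5]
    top = permutation_pvalue(lambda gs: 1e9 if gs == gene_set else 0.0,
                             gene_set, universe, n_permutations=100, seed=0)
    assert top.p_value == 0.0
    assert top.formatted() == "p < 0.01"
    bottom = permutation_pvalue(lambda gs: 0.0 if gs == gene_set else 1.0,
                                gene_set, universe, n_permutations=100, seed=0)
    assert bottom.p_value == 1.0
    # constant score: strict > never fires
    const = permutation_pvalue(len, gene_set, universe, n_permutations=100, seed=0)
    assert const.p_value == 0.0


def test_permutation_seeded_and_draws_without_replacement():
    universe = [f"g{i}" for i in range(30)]
    seen = []

    def score(gs):
        assert len(set(gs)) == len(gs) == 4
        seen.append(tuple(sorted(gs)))
        return 0.0

    a = permutation_pvalue(score, universe[:4], universe, 50, seed=3)
    first = list(seen)
    seen.clear()
    b = permutation_pvalue(score, universe[:4], universe, 50, seed=3)
    assert first == seen
    assert a.p_value == b.p_value
    with pytest.raises(ValueError, match="universe"):
        permutation_pvalue(len, universe, universe, 10, seed=0)


def test_permutation_score_failure_is_contextualized():
    universe = [f"g{i}" for i in range(10)]

    def bad(gs):
        if sorted(gs) != sorted(universe[:2]):
            raise RuntimeError("boom")
        return 1.0

    with pytest.raises(RuntimeError, match="permutation"):
        permutation_pvalue(bad, universe[:2], universe, 10, seed=0)


# ------------------------------------------------------------- replicates

def test_replicate_overlap_identical_and_disjoint_sets():
    tfs = {f"T{i}" for i in range(10)}
    out = replicate_regulon_overlap({"r1": tfs, "r2": set(tfs)}, universe_size=100)
    assert out.loc[0, "overlap"] == 10
    expected = scipy.stats.hypergeom.sf(9, 100, 10, 10)
    assert out.loc[0, "fisher_p"] == pytest.approx(expected, rel=1e-9)
    disjoint = replicate_regulon_overlap(
        {"r1": {"A", "B"}, "r2": {"C", "D"}}, universe_size=100)
    assert disjoint.loc[0, "overlap"] == 0
    assert disjoint.loc[0, "fisher_p"] > 0.9


def test_replicate_overlap_requires_universe():
    with pytest.raises(ValueError):
        replicate_regulon_overlap({"r1": {"A"}, "r2": {"A"}}, universe_size=None)
    with pytest.raises(ValueError, match="smaller"):
        replicate_regulon_overlap({"r1": {"A", "B"}, "r2": {"C"}}, universe_size=2)


def test_replicate_ras_agreement_identity_and_shape():
    rng = np.random.default_rng(4)
    d = squareform(pdist(rng.random((8, 3))))
    out = replicate_ras_agreement({"r1": d, "r2": d.copy()})
    assert out.loc[0, "pcc"] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="shape"):
        replicate_ras_agreement({"r1": d, "r2": d[:4, :4]})
    with pytest.raises(ValueError):
        replicate_ras_agreement({"r1": d})
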