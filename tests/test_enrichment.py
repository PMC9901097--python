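"""GO enrichment (classic Fisher + elim) and PCA with loading sets."""

import math

import numpy as np
import pandas as pd
import pytest

from leafdeo._util import InputError
from leafdeo.enrichment import GODag, elim_go, fisher_go, pca_loadings, top_loading_sets


def _hypergeom_oracle(k, M, K, n):
    """P(X >= k) by direct combinatorial summation (exact fractions)."""
    total = 0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(M - K, n - x)
    return total / math.comb(M, n)


def _flat_dag(annotations):
    return GODag([], annotations)


def test_fisher_saturated_term_p_one():
    universe = {f"g{i}" for i in range(20)}
    dag = _flat_dag({g: ["T"] for g in universe})
    p = fisher_go(dag, set(list(universe)[:5]), universe)
    assert p["T"] == pytest.approx(1.0)


def test_fisher_empty_overlap_p_one():
    universe = {f"g{i}" for i in range(100)}
    term_genes = {f"g{i}" for i in range(10)}
    study = {f"g{i}" for i in range(90, 100)}
    dag = _flat_dag({g: ["T"] for g in term_genes})
    assert fisher_go(dag, study, universe)["T"] == pytest.approx(1.0)


def test_fisher_matches_enumeration_oracle(rng):
    for trial in range(30):
        M = int(rng.integers(20, 200))
        universe = [f"g{i}" for i in range(M)]
        K = int(rng.integers(1, M))
        n = int(rng.integers(1, M))
        term_genes = list(rng.choice(universe, size=K, replace=False))
        study = set(rng.choice(universe, size=n, replace=False))
        dag = _flat_dag({g: ["T"] for g in term_genes})
        k = len(set(term_genes) & study)
        assert fisher_go(dag, study, set(universe))["T"] == pytest.approx(
            _hypergeom_oracle(k, M, K, n), abs=1e-12
        )


def test_fisher_study_not_subset_errors():
    dag = _flat_dag({"g0": ["T"]})
    with pytest.raises(InputError):
        fisher_go(dag, {"zz"}, {"g0"})


def test_true_path_closure():
    dag = GODag([("child", "parent")], {"g0": ["child"]})
    genes = dag.term_genes()
    assert genes["parent"] == {"g0"}


def test_cyclic_dag_rejected():
    with pytest.raises(InputError):
        GODag([("a", "b"), ("b", "a")])


# --------------------------------------------------------------------- elim


def test_elim_flat_dag_equals_fisher(rng):
    universe = {f"g{i}" for i in range(50)}
    ann = {g: [f"T{int(rng.integers(0, 5))}"] for g in universe}
    dag = _flat_dag(ann)
    study = set(list(universe)[:10])
    pd.testing.assert_series_equal(
        elim_go(dag, study, universe), fisher_go(dag, study, universe)
    )


def _toy_two_level():
    """Parent with two children; child A carries all the study signal.

    30 background genes hang off an unrelated term so the parent's closed
    annotation (30 genes) does not saturate the 60-gene universe.
    """
    universe = [f"g{i}" for i in range(60)]
    ann = {}
    for g in universe[:10]:
        ann[g] = ["childA"]
    for g in universe[10:20]:
        ann[g] = ["childB"]
    for g in universe[20:30]:
        ann[g] = ["parent"]
    for g in universe[30:]:
        ann[g] = ["other"]
    dag = GODag([("childA", "parent"), ("childB", "parent")], ann)
    study = set(universe[:10])  # exactly childA's genes
    return dag, study, set(universe)


def test_elim_removes_child_signal_from_parent():
    dag, study, universe = _toy_two_level()
    classic = fisher_go(dag, study, universe)
    adjusted = elim_go(dag, study, universe, alpha=0.01)
    # hand check: childA has overlap 10/10 out of a 60-gene universe
    assert classic["childA"] == pytest.approx(
        _hypergeom_oracle(10, 60, 10, 10), abs=1e-12
    )
    assert adjusted["childA"] == classic["childA"]
    assert adjusted["childA"] < 0.01
    # classic parent: its closed 30 genes contain all 10 study genes
    assert classic["parent"] == pytest.approx(
        _hypergeom_oracle(10, 60, 30, 10), abs=1e-12
    )
    # the parent loses childA's genes: its elim p exceeds the classic p
    assert adjusted["parent"] > classic["parent"]
    # hand check: 20 remaining genes, 0 study overlap -> upper tail is 1
    assert adjusted["parent"] == pytest.approx(
        _hypergeom_oracle(0, 60, 20, 10), abs=1e-12
    )


def test_elim_no_trigger_leaves_parent_unchanged():
    dag, study, universe = _toy_two_level()
    # alpha below childA's p: no elimination happens anywhere
    classic = fisher_go(dag, study, universe)
    adjusted = elim_go(dag, study, universe, alpha=1e-30)
    pd.testing.assert_series_equal(adjusted, classic)


def test_elim_without_significant_terms_equals_fisher(rng):
    universe = [f"g{i}" for i in range(60)]
    ann = {g: [f"T{int(rng.integers(0, 3))}"] for g in universe}
    dag = GODag([("T0", "root"), ("T1", "root"), ("T2", "root")], ann)
    study = set(rng.choice(universe, size=12, replace=False))
    classic = fisher_go(dag, study, set(universe))
    if (classic < 0.01).any():
        pytest.skip("random draw produced a significant term")
    pd.testing.assert_series_equal(elim_go(dag, study, set(universe)), classic)


# ---------------------------------------------------------------------- PCA


def test_pca_rank_one_matrix(rng):
    x = np.ones((10, 6)) * 3.0
    x[4] = [1, 2, 3, 4, 5, 6]
    res = pca_loadings(pd.DataFrame(x), 2)
    assert res.variance_explained[0] == pytest.approx(1.0)
    assert abs(res.loadings.iloc[4, 0]) == pytest.approx(1.0)
    assert res.loadings.iloc[4, 0] > 0  # sign convention


def test_pca_duplicate_samples_equal_scores(rng):
    x = rng.uniform(size=(20, 4))
    x = np.hstack([x, x[:, [0]]])  # duplicate first sample
    res = pca_loadings(pd.DataFrame(x), 3)
    assert np.allclose(res.scores.iloc[0], res.scores.iloc[-1], atol=1e-10)


def test_pca_reconstruction_identity(rng):
    x = pd.DataFrame(rng.normal(size=(50, 12)))
    res = pca_loadings(x, 12)
    recon = res.loadings.to_numpy() @ res.scores.to_numpy().T
    centered = x.to_numpy() - x.to_numpy().mean(axis=1, keepdims=True)
    assert np.allclose(recon, centered, atol=1e-8)


def test_pca_variance_fractions_valid(rng):
    res = pca_loadings(pd.DataFrame(rng.normal(size=(30, 8))), 5)
    v = res.variance_explained
    assert (v >= 0).all() and (v <= 1).all()
    assert (np.diff(v) <= 1e-12).all()
    assert v.sum() <= 1 + 1e-12


def test_pca_sample_permutation_invariance(rng):
    x = pd.DataFrame(rng.normal(size=(30, 8)))
    perm = rng.permutation(8)
    a = pca_loadings(x, 4).variance_explained
    b = pca_loadings(x.iloc[:, perm], 4).variance_explained
    assert np.allclose(a, b, atol=1e-12)


def test_pca_too_many_components_errors(rng):
    with pytest.raises(InputError):
        pca_loadings(pd.DataFrame(rng.normal(size=(5, 3))), 4)


# ------------------------------------------------------------ loading sets


def test_loading_sets_five_percent_of_hundred(rng):
    loadings = pd.Series(rng.permutation(100).astype(float),
                         index=[f"f{i:03d}" for i in range(100)])
    top, bottom = top_loading_sets(loadings, 0.05)
    assert len(top) == 5 and len(bottom) == 5
    assert min(loadings[t] for t in top) > max(loadings[b] for b in bottom)


def test_loading_sets_all_equal_degenerate():
    loadings = pd.Series(np.ones(20), index=[f"f{i}" for i in range(20)])
    top, bottom = top_loading_sets(loadings, 0.05)
    assert len(top) >= 1 and len(bottom) >= 1
    assert not set(top) & set(bottom)


def test_loading_sets_disjoint_property(rng):
    for _ in range(20):
        n = int(rng.integers(3, 60))
        loadings = pd.Series(rng.normal(size=n), index=[f"f{i}" for i in range(n)])
        if n < 20:
            with pytest.warns(UserWarning):
                top, bottom = top_loading_sets(loadings, 0.05)
        else:
            top, bottom = top_loading_sets(loadings, 0.05)
        assert not set(top) & set(bottom)
        assert len(top) >= 1 and len(bottom) >= 1


def test_loading_sets_bad_fraction():
    with pytest.raises(InputError):
        top_loading_sets(pd.Series([1.0, 2.0]), 0.7)
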