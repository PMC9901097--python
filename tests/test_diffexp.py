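"""DE engine oracles: CPM, TMM, dispersion, exact test, BH, drivers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom, nbinom, rankdata

from leafdeo._util import ConfigurationError, InputError
from leafdeo.diffexp import (
    TFSummary,
    bh_fdr,
    cpm,
    deg_between_segments,
    deo_between_species,
    estimate_dispersion,
    exact_nb_test,
    tmm_factors,
    two_group_test,
)
from leafdeo.simulate import simulate_counts

# ------------------------------------------------------------------- cpm


def test_cpm_definition():
    counts = pd.DataFrame({"s1": [100.0], "s2": [100.0]})
    out = cpm(counts, np.array([1e6, 1e3]))
    assert out.iloc[0, 0] == 100.0
    assert out.iloc[0, 1] == 100_000.0


def test_cpm_column_sum_identity(rng):
    counts = pd.DataFrame(rng.poisson(50, size=(30, 3)).astype(float))
    libs = counts.sum(axis=0)
    assert np.allclose(cpm(counts, libs).sum(axis=0), 1e6)


def test_cpm_zero_library_errors():
    with pytest.raises(InputError):
        cpm(pd.DataFrame({"a": [1.0]}), np.array([0.0]))


# ------------------------------------------------------------------- TMM


def test_tmm_identical_samples_unity(rng):
    col = rng.poisson(40, size=200).astype(float) + 1
    counts = pd.DataFrame({"a": col, "b": col, "c": col})
    f = tmm_factors(counts).factors
    assert np.allclose(f, 1.0, atol=1e-12)


def test_tmm_pure_depth_scaling_unity(rng):
    col = rng.poisson(40, size=200).astype(float) + 1
    counts = pd.DataFrame({"a": col, "b": 2 * col})
    f = tmm_factors(counts).factors
    assert np.allclose(f, 1.0, atol=1e-12)


def test_tmm_geometric_mean_one(rng):
    counts = pd.DataFrame(rng.negative_binomial(5, 0.02, size=(400, 5)).astype(float))
    f = tmm_factors(counts).factors.to_numpy()
    assert abs(np.log(f).mean()) < 1e-12


def _tmm_oracle(counts, trim_m=0.30, trim_a=0.05):
    """Step-by-step TMM reimplementation used only as a test oracle."""
    y = np.asarray(counts, dtype=float)
    lib = y.sum(axis=0)
    f75 = np.array([np.percentile(y[:, j], 75) / lib[j] for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - np.mean(f75))))
    logf = []
    for j in range(y.shape[1]):
        obs, refc = y[:, j], y[:, ref]
        ok = (obs > 0) & (refc > 0)
        o, r = obs[ok], refc[ok]
        m = np.log2((o / lib[j]) / (r / lib[ref]))
        a = 0.5 * (np.log2(o / lib[j]) + np.log2(r / lib[ref]))
        v = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
        if np.max(np.abs(m)) < 1e-10:
            logf.append(0.0)
            continue
        n = len(m)
        keep = np.ones(n, bool)
        for vals, trim in ((m, trim_m), (a, trim_a)):
            lo = np.floor(n * trim) + 1
            hi = n + 1 - lo
            rk = rankdata(vals)
            keep &= (rk >= lo) & (rk <= hi)
        logf.append(np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))
    logf = np.array(logf)
    return 2.0 ** (logf - logf.mean())


def test_tmm_matches_stepwise_oracle(rng):
    counts = pd.DataFrame(rng.negative_binomial(5, 0.01, size=(500, 4)).astype(float))
    mine = tmm_factors(counts).factors.to_numpy()
    assert np.allclose(mine, _tmm_oracle(counts), atol=1e-10)


def test_tmm_matches_edger():
    """Independent cross-check against edgeR's calcNormFactors (via Rscript)."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(rng.negative_binomial(5, 0.01, size=(500, 4)).astype(float))
    r_code = (
        "suppressMessages(library(edgeR));"
        "y <- matrix(scan('stdin', quiet=TRUE), ncol=4, byrow=TRUE);"
        "cat(sprintf('%.12f\\n', calcNormFactors(y, method='TMM')))"
    )
    proc = subprocess.run(
        ["Rscript", "-e", r_code],
        input="\n".join(" ".join(map(str, row)) for row in counts.to_numpy()),
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        pytest.skip(f"edgeR unavailable: {proc.stderr[-200:]}")
    theirs = np.array([float(x) for x in proc.stdout.split()])
    mine = tmm_factors(counts).factors.to_numpy()
    assert np.allclose(mine, theirs, atol=1e-9)


def test_tmm_all_zero_sample_errors():
    counts = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0]})
    with pytest.raises(InputError):
        tmm_factors(counts)


# ------------------------------------------------------------- dispersion


def test_dispersion_poisson_near_zero(rng):
    counts = pd.DataFrame(rng.poisson(100, size=(50, 6)).astype(float))
    phi = estimate_dispersion(counts, [0, 0, 0, 1, 1, 1], np.full(6, 1.0))
    assert phi.median() <= 0.01


def test_dispersion_recovery_at_point_two(rng):
    counts = pd.DataFrame(simulate_counts(np.full((200, 6), 500.0), 0.2, rng))
    phi = estimate_dispersion(counts, [0, 0, 0, 1, 1, 1], np.full(6, 1.0))
    assert 0.1 <= phi.median() <= 0.4


def test_dispersion_constant_features_floored():
    counts = pd.DataFrame(np.full((10, 4), 7.0))
    phi = estimate_dispersion(counts, [0, 0, 1, 1])
    assert (phi == 1e-4).all()


def test_dispersion_bad_groups():
    counts = pd.DataFrame(np.ones((5, 4)))
    with pytest.raises(ConfigurationError):
        estimate_dispersion(counts, [0, 1])
    with pytest.raises(ConfigurationError):
        estimate_dispersion(pd.DataFrame(np.ones((5, 2))), [0, 1])  # singletons only


# ------------------------------------------------------------- exact test


def test_exact_test_mode_split_p_one():
    p, lfc = exact_nb_test([10, 10], [10, 10], 0.1, [1e6] * 4)
    assert p == 1.0
    assert lfc == 0.0


def test_exact_test_binomial_closed_form():
    # n=1 per group, equal libs, phi=0: conditional law is Binomial(10, 1/2)
    p, _ = exact_nb_test([10], [0], 0.0, [1e6, 1e6])
    assert p == pytest.approx(2 * 0.5**10, abs=1e-15)


def _oracle_exact_p(ya, yb, na, nb, phi):
    """Enumeration oracle via scipy pmfs, independent of the implementation."""
    s = ya + yb
    if s == 0:
        return 1.0
    y = np.arange(s + 1)
    if phi == 0:
        probs = binom.pmf(y, s, na / (na + nb))
    else:
        fa = nbinom.pmf(y, na / phi, 0.5)
        fb = nbinom.pmf(s - y, nb / phi, 0.5)
        probs = fa * fb
        probs = probs / probs.sum()
    probs = probs / probs.sum()
    return min(1.0, probs[probs <= probs[ya] * (1 + 1e-10)].sum())


@pytest.mark.parametrize("phi", [0.01, 0.1, 0.5])
@pytest.mark.parametrize("sizes", [(1, 1), (3, 3), (2, 3)])
def test_exact_test_matches_enumeration_oracle(phi, sizes):
    na, nb = sizes
    libs = [1e6] * (na + nb)
    for s in range(0, 51, 5):
        for ya in range(s + 1):
            counts_a = [ya] + [0] * (na - 1)
            counts_b = [s - ya] + [0] * (nb - 1)
            p, _ = exact_nb_test(counts_a, counts_b, phi, libs)
            assert p == pytest.approx(_oracle_exact_p(ya, s - ya, na, nb, phi), abs=1e-12)


def test_exact_test_group_swap_symmetry(rng):
    libs = rng.uniform(8e5, 1.6e6, size=6)
    for _ in range(20):
        a = rng.poisson(100, size=3).astype(float)
        b = rng.poisson(150, size=3).astype(float)
        p1, l1 = exact_nb_test(a, b, 0.1, libs)
        p2, l2 = exact_nb_test(b, a, 0.1, np.concatenate([libs[3:], libs[:3]]))
        assert p1 == pytest.approx(p2, abs=1e-14)
        assert l1 == pytest.approx(-l2, abs=1e-12)


def test_exact_test_library_scale_invariance(rng):
    libs = rng.uniform(8e5, 1.6e6, size=6)
    a = rng.poisson(80, size=3).astype(float)
    b = rng.poisson(120, size=3).astype(float)
    p1, _ = exact_nb_test(a, b, 0.1, libs)
    p2, _ = exact_nb_test(a, b, 0.1, libs * 3.7)
    assert p1 == p2


def test_exact_test_negative_inputs_error():
    with pytest.raises(InputError):
        exact_nb_test([-1], [0], 0.1, [1e6, 1e6])
    with pytest.raises(InputError):
        exact_nb_test([1], [0], -0.1, [1e6, 1e6])


# ------------------------------------------------------------------- BH


def test_bh_hand_example():
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_single_p():
    assert bh_fdr([0.3])[0] == pytest.approx(0.3)


def test_bh_domain_error():
    with pytest.raises(InputError):
        bh_fdr([0.5, 1.2])


def _bh_oracle(p):
    """Brute-force step-up: find largest k with p_(k) <= alpha k/m per alpha=q."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for i in range(m - 1, -1, -1):
        prev = min(prev, p[order[i]] * m / (i + 1))
        q[order[i]] = prev
    return q


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
def test_bh_matches_bruteforce_oracle(pvals):
    assert np.allclose(bh_fdr(pvals), _bh_oracle(pvals), atol=1e-14)


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(size=200)
    _, q_sm, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(bh_fdr(p), q_sm, atol=1e-12)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=40),
       st.integers(min_value=0, max_value=39))
def test_bh_rejections_monotone_when_p_shrinks(pvals, idx):
    alpha = 0.1
    idx = idx % len(pvals)
    before = (bh_fdr(pvals) < alpha).sum()
    shrunk = list(pvals)
    shrunk[idx] = shrunk[idx] / 2
    after = (bh_fdr(shrunk) < alpha).sum()
    assert after >= before


# ------------------------------------------------------------------- drivers


def _meta(species, segments, reps):
    rows = {}
    for sp in species:
        for seg in segments:
            for r in range(1, reps + 1):
                rows[f"{sp}_{seg}_r{r}"] = {"species": sp, "segment": seg, "replicate": r}
    return pd.DataFrame.from_dict(rows, orient="index")


def test_identical_groups_zero_deg(rng):
    meta = _meta(["A"], ["S1", "S3"], 3)
    block = rng.poisson(100, size=(80, 3)).astype(float)
    counts = pd.DataFrame(
        np.hstack([block, block]), columns=meta.index,
        index=[f"OG{i}" for i in range(80)],
    )
    res = deg_between_segments(counts, meta, "A", ("S1", "S3"))
    assert res["significant"].sum() == 0
    assert (res["p_value"] == 1.0).all()


def test_deg_unknown_segment_errors(rng):
    meta = _meta(["A"], ["S1", "S3"], 3)
    counts = pd.DataFrame(
        rng.poisson(50, size=(10, 6)).astype(float), columns=meta.index
    )
    with pytest.raises(InputError):
        deg_between_segments(counts, meta, "A", ("S1", "S9"))


def test_fold_change_threshold_is_strict(rng):
    meta = _meta(["A"], ["S1", "S3"], 3)
    mu = np.hstack([np.full((60, 3), 100.0), np.full((60, 3), 100.0)])
    mu[:10, 3:] *= 4.2  # only a subset shifts, so normalization keeps the rest null
    counts = pd.DataFrame(
        simulate_counts(mu, 0.01, rng), columns=meta.index,
        index=[f"OG{i}" for i in range(60)], dtype=float,
    )
    res = deg_between_segments(counts, meta, "A", ("S1", "S3"))
    target = res.index[res["q_value"] < 0.01][0]
    lfc = abs(res.loc[target, "log2fc"])
    strict = deg_between_segments(counts, meta, "A", ("S1", "S3"), fc_threshold=lfc)
    # significance requires |log2fc| strictly above the threshold
    assert not strict.loc[target, "significant"]


def test_deo_missing_segment_errors(rng):
    meta = _meta(["A", "B"], ["S1"], 3)
    counts = pd.DataFrame(
        rng.poisson(50, size=(10, 6)).astype(float), columns=meta.index
    )
    with pytest.raises(InputError):
        deo_between_species(counts, meta, ("A", "B"), "S7")


def test_deo_direction_and_tf_summary(rng):
    meta = _meta(["A", "B"], ["S1"], 3)
    mu = np.hstack([np.full((50, 3), 100.0), np.full((50, 3), 100.0)])
    mu[:10, 3:] *= 8  # up in species B
    counts = pd.DataFrame(
        simulate_counts(mu, 0.01, rng), columns=meta.index,
        index=[f"OG{i}" for i in range(50)], dtype=float,
    )
    tf = pd.Series(False, index=counts.index)
    tf[:5] = True
    res, summary = deo_between_species(counts, meta, ("A", "B"), "S1", tf_flags=tf)
    called = res[res["significant"]]
    assert set(called.index) <= {f"OG{i}" for i in range(10)}
    assert (called["direction"] == "up_in_B").all()
    assert summary.n_deo == len(called)
    assert summary.n_tf == sum(tf[c] for c in called.index)


def test_tf_summary_percentage_rounding():
    assert TFSummary(151, 2757).percent == 5.5
    assert TFSummary(0, 0).percent == 0.0
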