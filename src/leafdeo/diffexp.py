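"""Differential expression engine: CPM, TMM, dispersion, NB exact test, BH.

The engine implements the standard trimmed-mean-of-M-values (TMM)
between-sample normalization and the conditional negative-binomial exact
test for two-group count comparisons, with Benjamini-Hochberg FDR control.
Two drivers sit on top: within-species DEG between consecutive leaf
segments, and cross-species DEO (differentially expressed orthogroups) at
matched segments.  A feature is significant when q < alpha AND
|log2 fold change| > fc_threshold (strict inequalities).

Dispersion phi parameterizes the NB variance as mu + phi * mu^2.  The
conditional exact test equalizes library sizes into pseudo-counts (scale
then round half-to-even), conditions on the pseudo-count total s, and sums
the probabilities of all splits (y, s - y) whose conditional probability
does not exceed that of the observed split (two-sided "double tail").
Given proportional group means and sizes, the conditional law depends only
on the per-group NB shape parameters r = n / phi, not on the mean, and
degenerates to Binomial(s, nA / (nA + nB)) when phi = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata

from ._util import ConfigurationError, InputError, percentage1

#: log-probability slack treated as a tie when accumulating the double tail
_TIE_REL = 1e-10


@dataclass
class NormFactors:
    """Per-sample TMM factors, rescaled to geometric mean 1."""

    factors: pd.Series
    lib_sizes: pd.Series

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


@dataclass
class TFSummary:
    """Transcription-factor share of a DEO list, percentage to one decimal."""

    n_tf: int
    n_deo: int

    @property
    def percent(self) -> float:
        return percentage1(self.n_tf, self.n_deo)


def cpm(counts: pd.DataFrame, effective_lib_sizes: pd.Series | np.ndarray) -> pd.DataFrame:
    """Counts per million against (effective) library sizes."""
    libs = pd.Series(np.asarray(effective_lib_sizes, dtype=float), index=counts.columns)
    if (libs <= 0).any():
        raise InputError("effective library sizes must be positive")
    return counts.div(libs, axis=1) * 1e6


def tmm_factors(
    counts: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormFactors:
    """Trimmed mean of M-values normalization factors.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean across samples.  Per sample, M (log2 expression
    ratio vs the reference) and A (average log2 expression) are computed
    over genes nonzero in both samples; the top and bottom ``trim_m``
    fraction by M and ``trim_a`` by A are trimmed, and the remaining M are
    averaged with inverse approximate asymptotic variance weights.  Factors
    are rescaled so their geometric mean is 1.
    """
    if counts.shape[1] < 2:
        raise InputError("TMM needs at least two samples")
    y = counts.to_numpy(dtype=float)
    if lib_sizes is None:
        lib = y.sum(axis=0)
    else:
        lib = pd.Series(lib_sizes, index=counts.columns).to_numpy(dtype=float)
    if (y.sum(axis=0) == 0).any():
        raise InputError("a sample has all-zero counts")

    f75 = np.percentile(y, 75, axis=0) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(y.shape[1])
    for j in range(y.shape[1]):
        log_factors[j] = _tmm_pair(y[:, j], lib[j], y[:, ref], lib[ref], trim_m, trim_a)
    log_factors -= log_factors.mean()  # geometric mean 1
    return NormFactors(
        pd.Series(2.0 ** log_factors, index=counts.columns),
        pd.Series(lib, index=counts.columns),
    )


def _tmm_pair(obs, n_obs, ref, n_ref, trim_m, trim_a) -> float:
    """log2 TMM factor of ``obs`` against ``ref`` (edgeR-style trimming)."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 0.0
    lo = np.log2(obs / n_obs)
    lr = np.log2(ref / n_ref)
    m = lo - lr
    a = (lo + lr) / 2
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-10:  # identical relative profiles
        return 0.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    w = 1.0 / v[keep]
    return float(np.sum(w * m[keep]) / np.sum(w))


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: Sequence,
    effective_lib_sizes: pd.Series | np.ndarray | None = None,
    shrink_up: float = 0.5,
    floor: float = 1e-4,
) -> pd.Series:
    """Per-feature moment dispersion with one-sided shrinkage.

    Counts are scaled to a common library size.  Per feature and group the
    moment identities E[v] = m + phi m^2 and E[m_hat^2] = m^2 + v/n give the
    estimator phi = (v - m) / (m^2 - v/n), pooled over groups with
    degree-of-freedom weights.  A common dispersion is formed as the
    ratio of the pooled numerators to the pooled denominators across all
    features (a low-noise, nearly unbiased estimate).  Each feature's final
    dispersion adapts only *upward* from the common value,

        phi_i = max(common + shrink_up * max(raw_i - common, 0), floor),

    because with few replicates downward deviations of the per-feature
    estimate are dominated by sampling noise and would inflate the false
    discovery rate, while upward adaptation protects against genuinely
    hyper-variable features.
    """
    groups = np.asarray(groups)
    if counts.shape[1] != groups.size:
        raise ConfigurationError("groups length must match the number of samples")
    if counts.shape[1] < 2:
        raise ConfigurationError("dispersion estimation needs >= 2 samples in total")
    if effective_lib_sizes is None:
        libs = counts.to_numpy(dtype=float).sum(axis=0)
    else:
        libs = np.asarray(effective_lib_sizes, dtype=float)
    scaled = counts.to_numpy(dtype=float) * (libs.mean() / libs)

    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    df_total = 0
    for g in np.unique(groups):
        block = scaled[:, groups == g]
        if block.shape[1] < 2:
            continue
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        df = block.shape[1] - 1
        df_total += df
        num += df * (v - m)
        den += df * np.maximum(m**2 - v / block.shape[1], 1e-300)
    if df_total == 0:
        raise ConfigurationError("dispersion estimation needs >= 2 replicates in >= 1 group")
    raw = np.maximum(num / den, 0.0)
    common = max(float(num.sum() / den.sum()), 0.0)
    phi = np.maximum(common + shrink_up * np.maximum(raw - common, 0.0), floor)
    return pd.Series(phi, index=counts.index)


def _round_half_even(x: np.ndarray) -> np.ndarray:
    return np.rint(x)  # numpy rounds half to even


def _exact_nb_pvalue(sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p for group totals (sum_a, sum_b)."""
    s = sum_a + sum_b
    if s == 0:
        return 1.0
    y = np.arange(s + 1)
    if phi <= 0:  # Poisson limit: Binomial(s, n_a / (n_a + n_b))
        pa = n_a / (n_a + n_b)
        logp = (
            gammaln(s + 1)
            - gammaln(y + 1)
            - gammaln(s - y + 1)
            + y * np.log(pa)
            + (s - y) * np.log(1 - pa)
        )
    else:
        r_a = n_a / phi
        r_b = n_b / phi
        logp = (
            gammaln(y + r_a)
            - gammaln(y + 1)
            + gammaln(s - y + r_b)
            - gammaln(s - y + 1)
        )
    logp = logp - logsumexp(logp)
    cut = logp[sum_a] + _TIE_REL
    tail = logp <= cut
    if tail.all():  # observed split at the conditional mode
        return 1.0
    return float(min(1.0, np.exp(logsumexp(logp[tail]))))


def exact_nb_test(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    phi: float,
    effective_lib_sizes: Sequence[float],
    prior_count: float = 0.5,
) -> tuple[float, float]:
    """Conditional NB exact test for one feature.

    ``effective_lib_sizes`` concatenates group A then group B sizes.
    Counts are equalized to the geometric-mean library size (rounded half
    to even) before conditioning.  Returns (p_value, log2fc of B over A,
    computed from prior-augmented cpm means).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise InputError("negative counts in exact_nb_test")
    if phi < 0:
        raise InputError("negative dispersion in exact_nb_test")
    libs = np.asarray(effective_lib_sizes, dtype=float)
    if libs.size != a.size + b.size:
        raise InputError("effective_lib_sizes must cover both groups")
    common = np.exp(np.mean(np.log(libs)))
    pseudo = _round_half_even(np.concatenate([a, b]) * common / libs).astype(np.int64)
    p = _exact_nb_pvalue(int(pseudo[: a.size].sum()), int(pseudo[a.size :].sum()), a.size, b.size, phi)

    cpm_a = (a + prior_count) / libs[: a.size] * 1e6
    cpm_b = (b + prior_count) / libs[a.size :] * 1e6
    log2fc = float(np.log2(cpm_b.mean() / cpm_a.mean()))
    return p, log2fc


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def two_group_test(
    counts: pd.DataFrame,
    group_a_samples: Sequence[str],
    group_b_samples: Sequence[str],
    alpha: float = 0.01,
    fc_threshold: float = 1.0,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Full two-group pipeline: TMM on the comparison samples, dispersion,
    exact test per feature, BH correction, significance calls.

    Returns a DataFrame with columns feature_id, log2fc (B over A),
    avg_logcpm, p_value, q_value, direction, significant.
    """
    samples = list(group_a_samples) + list(group_b_samples)
    sub = counts[samples]
    if lib_sizes is not None:
        lib_sizes = pd.Series(lib_sizes)[samples]
    norm = tmm_factors(sub, lib_sizes=lib_sizes)
    eff = norm.effective_lib_sizes.to_numpy()
    n_a = len(group_a_samples)
    groups = np.array([0] * n_a + [1] * len(group_b_samples))
    phi = estimate_dispersion(sub, groups, effective_lib_sizes=eff)

    mat = sub.to_numpy(dtype=float)
    pvals = np.empty(mat.shape[0])
    lfcs = np.empty(mat.shape[0])
    for i in range(mat.shape[0]):
        pvals[i], lfcs[i] = exact_nb_test(mat[i, :n_a], mat[i, n_a:], float(phi.iloc[i]), eff)
    qvals = bh_fdr(pvals)
    avg_logcpm = np.log2(((mat + 0.5) / eff * 1e6).mean(axis=1))

    significant = (qvals < alpha) & (np.abs(lfcs) > fc_threshold)
    direction = np.where(~significant, "ns", np.where(lfcs > 0, "up_in_B", "up_in_A"))
    return pd.DataFrame(
        {
            "feature_id": sub.index,
            "log2fc": lfcs,
            "avg_logcpm": avg_logcpm,
            "p_value": pvals,
            "q_value": qvals,
            "direction": direction,
            "significant": significant,
        }
    ).set_index("feature_id")


def deg_between_segments(
    og_counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    species: str,
    segment_pair: tuple[str, str],
    alpha: float = 0.01,
    fc_threshold: float = 1.0,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Within-species DE between two (consecutive) leaf segments.

    Group A is the first segment, group B the second; ``direction``
    ``up_in_B`` therefore means up in the later segment.
    """
    seg_a, seg_b = segment_pair
    meta = sample_meta[sample_meta["species"] == species]
    a = list(meta.index[meta["segment"] == seg_a])
    b = list(meta.index[meta["segment"] == seg_b])
    for seg, grp in ((seg_a, a), (seg_b, b)):
        if len(grp) < 2:
            raise InputError(f"segment {seg!r} has fewer than 2 replicates for {species!r}")
    return two_group_test(og_counts, a, b, alpha, fc_threshold, lib_sizes)


def deo_between_species(
    og_counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    species_pair: tuple[str, str],
    segment: str,
    alpha: float = 0.01,
    fc_threshold: float = 1.0,
    tf_flags: pd.Series | None = None,
    lib_sizes: pd.Series | None = None,
) -> tuple[pd.DataFrame, TFSummary]:
    """Cross-species DE of orthogroups at one matched segment.

    Replicates are treated as unpaired; TMM is computed jointly over the
    two species' samples entering the comparison.  ``up_in_B`` means up in
    the second species of the pair.  ``tf_flags`` (og -> bool) yields the
    TF share of the DEO list.
    """
    sp_a, sp_b = species_pair
    a = list(sample_meta.index[(sample_meta["species"] == sp_a) & (sample_meta["segment"] == segment)])
    b = list(sample_meta.index[(sample_meta["species"] == sp_b) & (sample_meta["segment"] == segment)])
    if not a or not b:
        missing = sp_a if not a else sp_b
        raise InputError(f"segment {segment!r} missing for species {missing!r}")
    res = two_group_test(og_counts, a, b, alpha, fc_threshold, lib_sizes)
    deo = res.index[res["significant"]]
    n_tf = 0
    if tf_flags is not None:
        n_tf = int(tf_flags.reindex(deo).fillna(False).astype(bool).sum())
    return res, TFSummary(n_tf=n_tf, n_deo=int(len(deo)))
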