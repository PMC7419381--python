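"""Diversity and differentiation statistics for binary epigenetic markers.

Operates on the binarized MSL/NML matrices produced by
:func:`epimsap.state_calling.binarize` (samples x loci, entries 0/1/NaN).

Implemented here:

* Shannon's index of phenotypic diversity per locus,
  ``S_j = -(p_j log2 p_j + (1-p_j) log2(1-p_j))`` with band-presence
  frequency ``p_j`` (the classical one-term variant ``-p log2 p`` is
  available behind a flag);
* pairwise squared-Euclidean / simple-matching distance matrices;
* AMOVA variance components and the differentiation statistic
  ``phi_ST = sigma^2_among / (sigma^2_among + sigma^2_within)`` with a
  label-permutation test (the multi-group value over MSL is the overall
  epigenetic differentiation, beta_ST);
* Mantel matrix-correlation test;
* the rank/ANOVA battery (Kruskal-Wallis, Dunn post hoc, Wilcoxon rank-sum,
  one-way ANOVA with Tukey HSD).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DiversityResult",
    "DistanceMatrix",
    "AmovaResult",
    "shannon_index",
    "pairwise_distance",
    "amova_phist",
    "pairwise_phist_table",
    "mantel_test",
    "rank_tests",
    "dunn_posthoc",
]


# ---------------------------------------------------------------------------
# Shannon diversity


@dataclass
class DiversityResult:
    """Per-locus Shannon diversity (bits) with summary statistics."""

    per_locus: pd.Series
    mean: float
    sd: float
    percent_polymorphic: float
    variant: str = "two_term"


def shannon_index(
    binary: pd.DataFrame,
    variant: str = "two_term",
    polymorphic_min_freq: float = 0.0,
) -> DiversityResult:
    """Shannon's index of phenotypic diversity over a binary marker matrix.

    For locus ``j`` with band-presence frequency ``p_j`` over non-missing
    samples, the default two-term entropy is
    ``S_j = -(p_j log2 p_j + (1-p_j) log2(1-p_j))`` (in [0, 1] bits, with
    ``0 log 0 := 0``); ``variant='one_term'`` gives ``-p_j log2 p_j``.
    A locus counts as polymorphic when both band states occur with
    frequency strictly above ``polymorphic_min_freq``. All-missing loci
    are skipped with a warning.
    """
    if variant not in ("two_term", "one_term"):
        raise ValueError("variant must be 'two_term' or 'one_term'")
    X = np.asarray(binary, dtype=float)
    if X.shape[1] == 0:
        raise ValueError("need at least one locus")
    n = np.sum(~np.isnan(X), axis=0).astype(float)
    keep = n > 0
    if not keep.all():
        warnings.warn(f"skipped {int((~keep).sum())} all-missing loci", stacklevel=2)
    with np.errstate(invalid="ignore"):
        p = np.nansum(X, axis=0)[keep] / n[keep]

    def h(q: np.ndarray) -> np.ndarray:
        out = np.zeros_like(q)
        nz = q > 0
        out[nz] = -q[nz] * np.log2(q[nz])
        return out

    s = h(p) if variant == "one_term" else h(p) + h(1.0 - p)
    cols = np.asarray(binary.columns)[keep] if isinstance(binary, pd.DataFrame) else np.flatnonzero(keep)
    per_locus = pd.Series(s, index=cols)
    poly = (p > polymorphic_min_freq) & (1.0 - p > polymorphic_min_freq)
    return DiversityResult(
        per_locus=per_locus,
        mean=float(per_locus.mean()),
        sd=float(per_locus.std(ddof=1)) if len(per_locus) > 1 else 0.0,
        percent_polymorphic=100.0 * float(poly.mean()),
        variant=variant,
    )


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with sample ids."""

    ids: list[str]
    values: np.ndarray
    metric: str = "sqeuclidean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("negative dissimilarities")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_skbio(self):
        from skbio import DistanceMatrix as SkbioDM

        return SkbioDM(self.values, self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def pairwise_distance(binary: pd.DataFrame, metric: str = "sqeuclidean") -> DistanceMatrix:
    """Pairwise dissimilarities over shared non-missing loci.

    ``'sqeuclidean'`` (sum of squared differences; for 0/1 data the count
    of mismatching loci) is required by the AMOVA variance-component
    interpretation; ``'simple-matching'`` (mismatch fraction) is offered
    for exploration. Raises for any pair with zero shared non-missing loci.
    """
    if metric not in ("sqeuclidean", "simple-matching"):
        raise ValueError(f"unknown metric {metric!r}")
    X = np.asarray(binary, dtype=float)
    ids = [str(i) for i in binary.index]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    mask = ~np.isnan(X)
    Xz = np.where(mask, X, 0.0)
    m = mask.astype(float)
    shared = m @ m.T
    bad = np.argwhere((shared == 0) & ~np.eye(n, dtype=bool))
    if len(bad):
        i, j = bad[0]
        raise ValueError(f"samples {ids[i]!r} and {ids[j]!r} share no non-missing loci")
    # sum over shared loci of (x_i - x_j)^2, missing-aware
    sq = Xz**2
    cross = Xz @ Xz.T
    d = (sq * 1.0) @ m.T + m @ sq.T - 2.0 * cross
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    if metric == "simple-matching":
        d = d / shared
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d, metric)


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    """AMOVA variance components, phi_ST and permutation P-value."""

    phi_st: float
    sigma_among: float
    sigma_within: float
    p_value: float | None
    n_perm: int
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    degenerate: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "phi_st": self.phi_st,
                "sigma_among": self.sigma_among,
                "sigma_within": self.sigma_within,
                "p_value": self.p_value,
                "n_perm": self.n_perm,
            }
        )


def _group_structures(labels: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    groups = pd.unique(labels)
    members = [np.flatnonzero(labels == g) for g in groups]
    sizes = np.array([len(m) for m in members])
    return members, sizes


def _amova_components(D2: np.ndarray, members: Sequence[np.ndarray]) -> tuple[float, float, float, float]:
    """Excoffier sums of squares and variance components from squared
    dissimilarities. Returns (ss_among, ss_within, sigma_a, sigma_w)."""
    n_tot = sum(len(m) for m in members)
    k = len(members)
    ss_total = D2.sum() / (2.0 * n_tot)
    ss_within = 0.0
    for m in members:
        ss_within += D2[np.ix_(m, m)].sum() / (2.0 * len(m))
    ss_among = ss_total - ss_within
    df_among = k - 1
    df_within = n_tot - k
    sizes = np.array([len(m) for m in members], dtype=float)
    n0 = (n_tot - (sizes**2).sum() / n_tot) / df_among
    ms_within = ss_within / df_within
    ms_among = ss_among / df_among
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n0
    return ss_among, ss_within, sigma_a, sigma_w


def amova_phist(
    d: DistanceMatrix,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> AmovaResult:
    """AMOVA phi_ST for a grouping of a squared-dissimilarity matrix.

    Variance components follow the classical analysis of molecular
    variance: total and within-group sums of squares are computed from the
    pairwise squared dissimilarities, mean squares are converted to
    sigma^2_among and sigma^2_within, and
    ``phi_ST = sigma^2_among / (sigma^2_among + sigma^2_within)``
    (unconstrained: slightly negative values are reported as such).
    Significance is by permutation of the sample-to-group assignment:
    ``P = (1 + #{phi_perm >= phi_obs}) / (n_perm + 1)``.

    ``d`` is used as squared dissimilarities directly, so it should come
    from ``pairwise_distance(..., 'sqeuclidean')`` or be otherwise
    squared-Euclidean-compatible. Every group needs >= 2 samples. A matrix
    of all-zero distances yields phi_ST = 0 with ``degenerate=True``.
    """
    labels = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    labels = labels.reindex(d.ids)
    if labels.isna().any():
        raise ValueError("grouping does not cover all samples in the distance matrix")
    lab = labels.to_numpy()
    members, sizes = _group_structures(lab)
    if len(members) < 2:
        raise ValueError("need >= 2 groups")
    if (sizes < 2).any():
        small = [str(pd.unique(lab)[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"groups with a single sample: {small}")

    D2 = d.values
    n = d.n
    k = len(members)
    if np.allclose(D2, 0.0):
        return AmovaResult(0.0, 0.0, 0.0, None, 0, k - 1, n - k, 0.0, 0.0, degenerate=True)

    ss_a, ss_w, sigma_a, sigma_w = _amova_components(D2, members)
    phi = sigma_a / (sigma_a + sigma_w)

    p_value = None
    if n_perm > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        # vectorized within-group SS under label permutation: group sizes
        # are fixed, only memberships move
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        ss_total = D2.sum() / (2.0 * n)
        ss_w_perm = np.zeros(n_perm)
        start = 0
        for m in members:
            g = len(m)
            cols = perm_idx[:, start:start + g]  # permuted member indices
            start += g
            # sum of D2 over pairs within the permuted group, per permutation
            block = D2[cols[:, :, None], cols[:, None, :]].sum(axis=(1, 2))
            ss_w_perm += block / (2.0 * g)
        df_among, df_within = k - 1, n - k
        n0 = (n - (sizes.astype(float)**2).sum() / n) / df_among
        ms_w = ss_w_perm / df_within
        ms_a = (ss_total - ss_w_perm) / df_among
        sig_a = (ms_a - ms_w) / n0
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_perm = sig_a / (sig_a + ms_w)
        phi_perm = np.nan_to_num(phi_perm, nan=0.0)
        p_value = (1.0 + np.sum(phi_perm >= phi - 1e-12)) / (n_perm + 1.0)

    return AmovaResult(
        phi_st=float(phi),
        sigma_among=float(sigma_a),
        sigma_within=float(sigma_w),
        p_value=p_value,
        n_perm=n_perm,
        df_among=k - 1,
        df_within=n - k,
        ss_among=float(ss_a),
        ss_within=float(ss_w),
    )


def pairwise_phist_table(
    d: DistanceMatrix,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """phi_ST for every unordered pair of groups (one row per pair).

    P-values are raw permutation P's with no multiple-testing adjustment
    (flagged in the ``p_adjusted`` column as False).
    """
    labels = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    labels = labels.reindex(d.ids)
    if labels.isna().any():
        raise ValueError("grouping does not cover all samples")
    rng = np.random.default_rng(seed)
    rows = []
    for ga, gb in itertools.combinations(pd.unique(labels.to_numpy()), 2):
        keep = labels.isin([ga, gb]).to_numpy()
        ids = [s for s, k in zip(d.ids, keep) if k]
        sub = DistanceMatrix(ids, d.values[np.ix_(keep, keep)], d.metric)
        res = amova_phist(sub, labels[keep], n_perm=n_perm, seed=rng)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "phi_st": res.phi_st,
                "p_value": res.p_value,
                "n_perm": res.n_perm,
                "p_adjusted": False,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mantel


class MantelResult(NamedTuple):
    r: float
    p_value: float
    n_perm: int


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    ``r`` is the Pearson correlation of the off-diagonal entries;
    significance is by permuting the sample labels of the second matrix,
    ``P = (1 + #{|r_perm| >= |r|}) / (n_perm + 1)`` (two-sided). Matrices
    must share the same samples in the same order; a constant matrix has
    undefined r and raises.
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must share sample ids in the same order")
    x = d1.condensed()
    n = d1.n
    if np.allclose(x, x[0]) or np.allclose(d2.condensed(), d2.condensed()[0]):
        raise ValueError("Mantel r undefined for a constant distance matrix")
    y = d2.condensed()
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = d2.values[np.ix_(perm, perm)][iu]
        r_perm = np.corrcoef(x, y_perm)[0, 1]
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1.0 + hits) / (n_perm + 1.0)
    return MantelResult(r_obs, p, n_perm)


# ---------------------------------------------------------------------------
# Rank tests


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]],
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's multiple-comparison test after Kruskal-Wallis.

    Pairwise z statistics on mean ranks with tie correction; two-sided
    normal P-values adjusted by ``adjust`` in {'none', 'bonferroni',
    'holm', 'bh'}. The ``direction`` column uses the (+/-) convention: the
    first-named group has the larger mean rank.
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    sizes = np.array([len(v) for v in data])
    if (sizes == 0).any():
        raise ValueError("empty group")
    pooled = np.concatenate(data)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g, v in zip(names, data):
        mean_ranks[g] = ranks[start:start + len(v)].mean()
        start += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term

    rows = []
    for (ga, na), (gb, nb) in itertools.combinations(zip(names, sizes), 2):
        se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        diff = mean_ranks[ga] - mean_ranks[gb]
        z = diff / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "z": z,
                "p_value": min(p, 1.0),
                "direction": "(+/-)" if diff >= 0 else "(-/+)",
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = _adjust_pvalues(table["p_value"].to_numpy(), adjust)
    return table


def _adjust_pvalues(p: np.ndarray, method: str) -> np.ndarray:
    m = len(p)
    method = method.lower()
    if method == "none" or m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    order = np.argsort(p)
    out = np.empty(m)
    if method == "holm":
        adj = np.maximum.accumulate((m - np.arange(m)) * p[order])
        out[order] = np.minimum(adj, 1.0)
        return out
    if method == "bh":
        ranked = p[order] * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out[order] = np.minimum(adj, 1.0)
        return out
    raise ValueError(f"unknown adjustment {method!r}")


@dataclass
class RankTestResults:
    """Bundle of the group-comparison tests used throughout the analysis."""

    kruskal_statistic: float
    kruskal_df: int
    kruskal_p: float
    dunn: pd.DataFrame
    wilcoxon_statistic: float | None = None
    wilcoxon_p: float | None = None
    anova_f: float | None = None
    anova_p: float | None = None
    tukey: pd.DataFrame | None = None


def rank_tests(
    groups: Mapping[str, Sequence[float]],
    dunn_adjust: str = "bonferroni",
    anova: bool = True,
) -> RankTestResults:
    """Kruskal-Wallis with Dunn post hoc, plus Wilcoxon rank-sum (for two
    groups) and one-way ANOVA with Tukey HSD.

    Ties are corrected in both the Kruskal-Wallis statistic (scipy) and the
    Dunn z denominators. ``anova=True`` requires every group to hold >= 2
    values (variance-based test); set it False to skip. With identical
    pooled values the KW statistic is 0 and P is 1.
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(v) == 0 for v in data):
        raise ValueError("empty group")
    pooled = np.concatenate(data)
    if np.allclose(pooled, pooled[0]):
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw_stat, kw_p = sps.kruskal(*data)
    dunn = dunn_posthoc(groups, adjust=dunn_adjust)

    wstat = wp = None
    if len(names) == 2:
        res = sps.mannwhitneyu(data[0], data[1], use_continuity=True, alternative="two-sided")
        wstat, wp = float(res.statistic), float(res.pvalue)

    f = fp = None
    tukey_df = None
    if anova:
        if any(len(v) < 2 for v in data):
            raise ValueError("one-way ANOVA needs >= 2 values per group")
        if np.allclose(pooled, pooled[0]):
            f, fp = 0.0, 1.0
        else:
            f, fp = (float(v) for v in sps.f_oneway(*data))
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        labels = np.concatenate([[g] * len(v) for g, v in zip(names, data)])
        if np.allclose(pooled, pooled[0]):
            tukey_df = pd.DataFrame(
                [
                    {"group_a": a, "group_b": b, "meandiff": 0.0, "p_adj": 1.0}
                    for a, b in itertools.combinations(names, 2)
                ]
            )
        else:
            res = pairwise_tukeyhsd(pooled, labels)
            tukey_df = pd.DataFrame(
                res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
            ).rename(columns={"group1": "group_a", "group2": "group_b", "p-adj": "p_adj"})

    return RankTestResults(
        kruskal_statistic=float(kw_stat),
        kruskal_df=len(names) - 1,
        kruskal_p=float(kw_p),
        dunn=dunn,
        wilcoxon_statistic=wstat,
        wilcoxon_p=wp,
        anova_f=f,
        anova_p=fp,
        tukey=tukey_df,
    )
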