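"""Ordination, phylo-epigenetic trees, and cluster-number post-processing.

* :func:`pcoa` — classical metric scaling (principal coordinates) of a
  distance matrix, negative eigenvalues reported as-is (optional Cailliez
  correction).
* :func:`bpca` — between-group eigen analysis: ordination of the group
  centroids maximizing between-group variance, with the fraction of total
  inertia captured between groups and a label-randomization test.
* :func:`nj_tree` — neighbour-joining tree with newick output.
* :func:`evanno_delta_k` — the second-order-rate-of-change statistic
  ``delta K = |L''(K)| / SD(L(K))`` over external model-based clustering
  log-likelihoods (the clustering program itself is consumed, not run).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .popgen import DistanceMatrix

__all__ = [
    "PCoAResult",
    "BpcaResult",
    "NjTree",
    "DeltaKTable",
    "pcoa",
    "bpca",
    "nj_tree",
    "evanno_delta_k",
    "read_structure_runs",
]


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PCoAResult:
    """Principal-coordinate scores and eigenvalue spectrum.

    ``coords`` has one column per retained (positive-eigenvalue) axis;
    ``eigenvalues`` holds the full spectrum in decreasing order, negative
    values included; ``percent_inertia`` is computed over the positive
    eigenvalues only and refers to the retained axes.
    """

    coords: pd.DataFrame
    eigenvalues: np.ndarray
    percent_inertia: np.ndarray


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: per axis, the largest-magnitude
    coordinate is positive."""
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return coords


def pcoa(d: DistanceMatrix, cailliez: bool = False) -> PCoAResult:
    """Classical scaling (Torgerson / Gower) of a distance matrix.

    The Gower matrix ``-1/2 J D^2 J`` (J the centering projector) is
    eigendecomposed; coordinates are eigenvectors scaled by the square
    root of their (positive) eigenvalues. Non-Euclidean inputs yield
    negative eigenvalues, which are reported, not corrected, unless
    ``cailliez=True`` adds the smallest constant to the off-diagonal
    distances making them Euclidean.
    """
    D = d.values.copy()
    n = d.n
    if cailliez:
        D = _cailliez(D)
    G = _gower_center(D**2)
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    coords = _fix_signs(coords)
    pct = 100.0 * eigval[pos] / eigval[pos].sum()
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coords=pd.DataFrame(coords, index=d.ids, columns=cols),
        eigenvalues=eigval,
        percent_inertia=pct,
    )


def _gower_center(D2: np.ndarray) -> np.ndarray:
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ D2 @ J


def _cailliez(D: np.ndarray) -> np.ndarray:
    """Cailliez constant-addition correction to make D Euclidean."""
    n = D.shape[0]
    G1 = _gower_center(D**2)
    G2 = _gower_center(D)
    Z = np.zeros((n, n))
    B = np.block([[Z, 2.0 * G1], [-np.eye(n), -4.0 * G2]])
    c = float(np.max(np.real(np.linalg.eigvals(B))))
    if c <= 0:
        return D
    out = D + c
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# Between-group eigen analysis


@dataclass
class BpcaResult:
    """Between-group eigen-analysis result.

    ``between_inertia_pct`` is the percentage of the total inertia carried
    by the (size-weighted) group centroids; ``axis_pct`` splits the
    between-group inertia over the retained axes (sums to 100).
    """

    group_coords: pd.DataFrame
    sample_coords: pd.DataFrame
    between_inertia_pct: float
    axis_pct: np.ndarray
    p_value: float | None
    n_perm: int


def _between_inertia(Xc: np.ndarray, members: list[np.ndarray]) -> float:
    total = 0.0
    for m in members:
        mu = Xc[m].mean(axis=0)
        total += len(m) * float(mu @ mu)
    return total


def bpca(
    binary: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 10000,
    seed: int | None = None,
) -> BpcaResult:
    """Between-group eigen analysis of a binary marker matrix.

    Columns are centered; the size-weighted covariance of the group
    centroids is eigendecomposed, group centroids and samples are
    projected on its eigenvectors, and the between/total inertia ratio is
    tested by randomizing group labels ``n_perm`` times (one-sided: how
    often a random labelling concentrates at least as much inertia between
    groups).
    """
    labels = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    labels = labels.reindex(binary.index)
    if labels.isna().any():
        raise ValueError("grouping does not cover all samples")
    X = np.asarray(binary, dtype=float)
    X = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
    Xc = X - X.mean(axis=0, keepdims=True)
    lab = labels.to_numpy()
    group_names = list(pd.unique(lab))
    if len(group_names) < 2:
        raise ValueError("need >= 2 groups")
    members = [np.flatnonzero(lab == g) for g in group_names]

    n = Xc.shape[0]
    total_inertia = float((Xc**2).sum())
    if total_inertia == 0:
        raise ValueError("constant matrix: no inertia")
    between = _between_inertia(Xc, members)
    ratio = between / total_inertia

    # eigen-analysis of the size-weighted between-group covariance
    centroids = np.stack([Xc[m].mean(axis=0) for m in members])
    w = np.array([len(m) for m in members], dtype=float) / n
    B = (centroids * w[:, None]).T @ centroids
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10
    keep = eigval > tol
    axes = eigvec[:, keep]
    gcoords = centroids @ axes
    scoords = Xc @ axes
    # consistent sign convention with pcoa
    for j in range(gcoords.shape[1]):
        if gcoords[np.argmax(np.abs(gcoords[:, j])), j] < 0:
            gcoords[:, j] *= -1
            scoords[:, j] *= -1
    axis_pct = 100.0 * eigval[keep] / eigval[keep].sum()

    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            perm_members = [perm[m] for m in members]
            if _between_inertia(Xc, perm_members) >= between - 1e-12:
                hits += 1
        p_value = (1.0 + hits) / (n_perm + 1.0)

    cols = [f"Axis{i + 1}" for i in range(gcoords.shape[1])]
    return BpcaResult(
        group_coords=pd.DataFrame(gcoords, index=group_names, columns=cols),
        sample_coords=pd.DataFrame(scoords, index=list(binary.index), columns=cols),
        between_inertia_pct=100.0 * ratio,
        axis_pct=axis_pct,
        p_value=p_value,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Neighbour joining


@dataclass
class NjTree:
    """Neighbour-joining tree over sample labels.

    ``tree`` is a ``skbio.TreeNode``; ``negative_clamped`` records whether
    any branch length was negative before clamping to zero.
    """

    tree: object
    newick: str
    negative_clamped: bool

    def path_distance(self, a: str, b: str) -> float:
        ta = self.tree.find(a)
        return float(ta.distance(self.tree.find(b)))


def nj_tree(d: DistanceMatrix) -> NjTree:
    """Saitou-Nei neighbour joining on a distance matrix.

    Negative branch lengths (possible on non-additive inputs) are clamped
    to zero, with the event recorded in ``negative_clamped``. Fewer than
    three samples yields a trivial star tree with a warning.
    """
    from skbio import TreeNode
    from skbio.tree import nj as skbio_nj

    if d.n < 3:
        warnings.warn("fewer than 3 samples: returning trivial tree", stacklevel=2)
        if d.n == 2:
            half = d.values[0, 1] / 2.0
            nwk = f"({d.ids[0]}:{half:g},{d.ids[1]}:{half:g});"
        else:
            nwk = f"({d.ids[0]}:0);"
        tree = TreeNode.read([nwk])
        return NjTree(tree, nwk, False)

    sk = d.to_skbio()
    raw = skbio_nj(sk, neg_as_zero=False)
    clamped = any(
        n.length is not None and n.length < 0 for n in raw.traverse(include_self=False)
    )
    tree = skbio_nj(sk, neg_as_zero=True)
    nwk = str(tree).strip()
    return NjTree(tree, nwk, clamped)


# ---------------------------------------------------------------------------
# Evanno delta-K


@dataclass
class DeltaKTable:
    """Per-K summary of clustering log-likelihoods and the delta-K curve.

    ``table`` columns: mean_logL, sd_logL, d_logL (first difference
    L'(K)), dd_logL (second difference L''(K)), delta_k (defined for
    interior K only). ``best_k`` is the argmax of delta_k.
    """

    table: pd.DataFrame
    best_k: int


def evanno_delta_k(runs: pd.DataFrame) -> DeltaKTable:
    """Second-order rate-of-change statistic for choosing K.

    ``runs`` is a long table with columns ``K`` and ``logL`` (one row per
    replicate run). With mean log-likelihood L(K) over replicates:
    ``L'(K) = L(K) - L(K-1)``, ``L''(K) = L'(K+1) - L'(K)``, and
    ``delta_k(K) = |L''(K)| / SD(L(K))``, defined for interior K. Needs at
    least three consecutive K values and >= 2 replicates per K; a zero SD
    at an interior K leaves delta K undefined and raises.
    """
    if not {"K", "logL"}.issubset(runs.columns):
        raise ValueError("runs table must have columns 'K' and 'logL'")
    grouped = runs.groupby("K")["logL"]
    ks = np.array(sorted(grouped.groups))
    if len(ks) < 3:
        raise ValueError("need >= 3 K values")
    if not np.array_equal(np.diff(ks), np.ones(len(ks) - 1, dtype=ks.dtype)):
        raise ValueError("K values must be consecutive integers")
    counts = grouped.count()
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates per K for the SD")
    mean = grouped.mean().reindex(ks).to_numpy()
    sd = grouped.std(ddof=1).reindex(ks).to_numpy()

    d1 = np.full(len(ks), np.nan)
    d1[1:] = np.diff(mean)
    d2 = np.full(len(ks), np.nan)
    d2[1:-1] = mean[2:] - 2.0 * mean[1:-1] + mean[:-2]
    delta = np.full(len(ks), np.nan)
    interior = slice(1, len(ks) - 1)
    if np.any(sd[interior] == 0):
        raise ValueError("zero SD of logL at an interior K: delta K undefined")
    delta[interior] = np.abs(d2[interior]) / sd[interior]

    table = pd.DataFrame(
        {
            "mean_logL": mean,
            "sd_logL": sd,
            "d_logL": d1,
            "dd_logL": d2,
            "delta_k": delta,
        },
        index=pd.Index(ks, name="K"),
    )
    best_k = int(table["delta_k"].idxmax())
    return DeltaKTable(table, best_k)


_RE_K = re.compile(r"(\d+)\s+populations assumed")
_RE_LNP = re.compile(r"Estimated Ln Prob of Data\s*=\s*(-?\d+(?:\.\d+)?)")


def read_structure_runs(paths: Iterable[str | Path]) -> pd.DataFrame:
    """Convenience parser for model-based-clustering output files.

    Scans each file for the assumed number of populations and the
    estimated ln probability of the data, returning a long (K, logL)
    table suitable for :func:`evanno_delta_k`.
    """
    rows = []
    for path in paths:
        text = Path(path).read_text()
        mk = _RE_K.search(text)
        mp = _RE_LNP.search(text)
        if not (mk and mp):
            raise ValueError(f"could not find K / Ln Prob lines in {path}")
        rows.append({"K": int(mk.group(1)), "logL": float(mp.group(1)), "file": str(path)})
    return pd.DataFrame(rows)
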