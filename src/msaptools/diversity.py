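"""Dominant-marker diversity and structure statistics.

All operations act on binary (1/0/missing) recoded matrices.  Band
phenotype frequencies are used directly (no dominant-marker Hardy-Weinberg
back-correction), matching the standard binary-data treatment of
GenAlEx-style analyses.  Per-locus, with p the frequency of state 1 and
q = 1-p:

* effective allele number      Ne = 1/(p^2 + q^2)
* Shannon information index    I  = -p ln p - q ln q
* expected heterozygosity      He = 1 - p^2 - q^2  (so He = 1 - 1/Ne)
* percent polymorphic loci     PPL = % of loci with 0 < p < 1

Molecular variance is partitioned with the distance-based AMOVA on squared
Euclidean distances; PhiPT (the binary-data FST analogue) is the
among-group fraction of total molecular variance, tested by label
permutation.  Mantel correlation compares two distance matrices by
permuting one of them.  Permutation p-values use the inclusive
(+1)/(n+1) convention so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.ordination import OrdinationResults, pcoa as _skbio_pcoa

from .io import MISSING
from .states import BinaryRecodedMatrix

__all__ = [
    "sm_similarity",
    "similarity_to_distance",
    "upgma",
    "pcoa",
    "diversity_indices",
    "amova",
    "mantel",
    "AMOVAResult",
    "MantelResult",
]


# ---------------------------------------------------------------------------
# Simple-matching similarity
# ---------------------------------------------------------------------------

def sm_similarity(matrix: BinaryRecodedMatrix) -> pd.DataFrame:
    """Pairwise simple-matching similarity: matches / compared loci.

    For each sample pair, loci missing in either sample are excluded; the
    coefficient is (shared 1s + shared 0s) / compared loci.  A pair with no
    comparable loci gets NaN (flagged, not silently filled).
    """
    v = matrix.values
    n = matrix.n_samples
    if n < 2:
        raise ValueError("similarity needs at least two samples")
    valid = (v != MISSING).astype(np.int32)
    x = np.where(v == MISSING, 0, v).astype(np.int32)
    both = valid @ valid.T  # comparable loci per pair
    ones = x @ x.T  # shared 1s
    zeros = (valid - x) @ (valid - x).T  # shared 0s
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (ones + zeros) / both
    sim[both == 0] = np.nan
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=matrix.sample_ids, columns=matrix.sample_ids)


def similarity_to_distance(similarity: pd.DataFrame) -> pd.DataFrame:
    """Distance as 1 - similarity, validated square/symmetric."""
    _check_square(similarity.to_numpy(), list(similarity.index))
    return 1.0 - similarity


def _check_square(m: np.ndarray, ids: Sequence[str]) -> None:
    if m.shape != (len(ids), len(ids)):
        raise ValueError("matrix is not square over the sample set")
    if not np.allclose(m, m.T, equal_nan=True):
        raise ValueError("matrix is not symmetric")


# ---------------------------------------------------------------------------
# UPGMA clustering
# ---------------------------------------------------------------------------

def upgma(similarity: pd.DataFrame) -> str:
    """UPGMA dendrogram on 1 - similarity, returned as a newick string.

    Agglomerates the closest pair at each step (ties broken toward the
    lowest-index pair), placing the merge node at height d/2 so the tree is
    ultrametric; between-cluster distances are size-weighted arithmetic
    means over all member pairs.  Branch lengths are height differences.
    """
    ids = list(similarity.index)
    d = 1.0 - similarity.to_numpy(dtype=float)
    _check_square(d, ids)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains undefined entries")
    n = len(ids)
    if n == 1:
        return f"{ids[0]}:0;"
    # active clusters: newick fragment, height, size
    newick = {i: ids[i] for i in range(n)}
    height = dict.fromkeys(range(n), 0.0)
    size = dict.fromkeys(range(n), 1)
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        best = min(
            ((dist[(a, b)], a, b) for idx, a in enumerate(active) for b in active[idx + 1:]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        dmin, a, b = best
        h = dmin / 2.0
        newick[nxt] = (
            f"({newick[a]}:{h - height[a]:.10g},{newick[b]}:{h - height[b]:.10g})"
        )
        height[nxt] = h
        size[nxt] = size[a] + size[b]
        for c in active:
            if c in (a, b):
                continue
            dac = dist[tuple(sorted((a, c)))]
            dbc = dist[tuple(sorted((b, c)))]
            dist[(c, nxt)] = (size[a] * dac + size[b] * dbc) / (size[a] + size[b])
        active = [c for c in active if c not in (a, b)] + [nxt]
        nxt += 1
    return newick[active[0]] + ";"


def upgma_tree(similarity: pd.DataFrame):
    """UPGMA dendrogram as a scikit-bio ``TreeNode``."""
    from skbio import TreeNode

    return TreeNode.read(StringIO(upgma(similarity)))


# ---------------------------------------------------------------------------
# Principal coordinates
# ---------------------------------------------------------------------------

def pcoa(similarity: pd.DataFrame, n_axes: int | None = None) -> OrdinationResults:
    """Classical metric scaling on 1 - similarity (scikit-bio backend).

    Axes are ordered by eigenvalue; ``proportion_explained`` reports the
    explained-variance fractions and negative-eigenvalue mass is retained
    in ``eigvals`` rather than silently dropped.
    """
    from skbio import DistanceMatrix

    dm = DistanceMatrix(
        similarity_to_distance(similarity).to_numpy(), ids=list(similarity.index)
    )
    res = _skbio_pcoa(dm, number_of_dimensions=n_axes or 0)
    return res


# ---------------------------------------------------------------------------
# Diversity indices
# ---------------------------------------------------------------------------

def diversity_indices(
    matrix: BinaryRecodedMatrix,
    groups: Mapping[str, str],
    *,
    unbiased_he: bool = False,
) -> pd.DataFrame:
    """Per-group PPL, Ne, I and He, averaged over loci.

    Frequencies count non-missing samples within the group.  Monomorphic
    loci contribute Ne=1, I=0, He=0.  ``unbiased_he`` applies the
    n/(n-1) small-sample correction to He (off by default; the raw band
    frequency form is the reference behaviour).
    """
    rows = []
    glabels = pd.Series({s: groups[s] for s in matrix.sample_ids if s in groups})
    for grp in sorted(glabels.unique()):
        members = [i for i, s in enumerate(matrix.sample_ids) if glabels.get(s) == grp]
        if len(members) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 samples")
        v = matrix.values[members]
        scored = (v != MISSING).sum(axis=0)
        ones = (v == 1).sum(axis=0)
        keep = scored > 0
        p = ones[keep] / scored[keep]
        q = 1.0 - p
        ne = 1.0 / (p * p + q * q)
        he = 1.0 - p * p - q * q
        if unbiased_he:
            n_eff = scored[keep]
            he = he * n_eff / np.maximum(n_eff - 1, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            sh = -np.where(p > 0, p * np.log(p), 0.0) - np.where(q > 0, q * np.log(q), 0.0)
        rows.append(
            {
                "group": grp,
                "n_samples": len(members),
                "n_loci": int(keep.sum()),
                "ppl": 100.0 * float(((p > 0) & (p < 1)).sum()) / max(int(keep.sum()), 1),
                "ne": float(ne.mean()),
                "i": float(sh.mean()),
                "he": float(he.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AMOVAResult:
    """Distance-based AMOVA partition with PhiPT and its permutation test."""

    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    var_among: float
    var_within: float
    phi_pt: float
    pct_among: float
    pct_within: float
    p_value: float
    n_permutations: int


def _amova_components(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, float, float]:
    """SS/variance components and PhiPT from a squared-distance matrix."""
    n = len(labels)
    groups = np.unique(labels)
    g = len(groups)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    sizes = []
    for grp in groups:
        idx = np.flatnonzero(labels == grp)
        sizes.append(len(idx))
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    sizes = np.asarray(sizes, dtype=float)
    df_among, df_within = g - 1, n - g
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - (sizes**2).sum() / n) / df_among
    var_within = ms_within
    var_among = (ms_among - ms_within) / n0
    total = var_among + var_within
    phi = var_among / total if total > 0 else np.nan
    return ss_among, ss_within, var_among, var_within, phi


def amova(
    matrix: BinaryRecodedMatrix,
    groups: Mapping[str, str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> AMOVAResult:
    """AMOVA over groups on squared Euclidean distances between samples.

    Missing cells are mean-imputed per locus within their group (the SS
    identities need complete vectors).  The permutation test shuffles group
    labels; p = (#permuted PhiPT >= observed + 1)/(n_permutations + 1).
    """
    sample_ids = matrix.sample_ids
    labels = np.array([groups[s] for s in sample_ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("AMOVA needs >= 2 groups with >= 2 samples each")
    x = matrix.values.astype(float)
    x[x == MISSING] = np.nan
    for grp in uniq:
        idx = labels == grp
        block = x[idx]
        obs = ~np.isnan(block)
        n_obs = obs.sum(axis=0)
        col_sums = np.where(obs, block, 0.0).sum(axis=0)
        col_means = np.where(n_obs > 0, col_sums / np.maximum(n_obs, 1), 0.5)
        nan_r, nan_c = np.where(np.isnan(block))
        block[nan_r, nan_c] = col_means[nan_c]
        x[idx] = block
    diff = x[:, None, :] - x[None, :, :]
    d2 = (diff**2).sum(axis=2)
    ss_a, ss_w, va, vw, phi = _amova_components(d2, labels)
    total = va + vw
    if not np.isfinite(phi):
        pct_a = pct_w = np.nan
    else:
        pct_a, pct_w = 100.0 * va / total, 100.0 * vw / total
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        phi_p = _amova_components(d2, perm)[4]
        if phi_p >= phi:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    n = len(sample_ids)
    return AMOVAResult(
        df_among=len(uniq) - 1,
        df_within=n - len(uniq),
        ss_among=ss_a,
        ss_within=ss_w,
        var_among=va,
        var_within=vw,
        phi_pt=phi,
        pct_among=pct_a,
        pct_within=pct_w,
        p_value=p,
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel correlation of two distance matrices over the same samples.

    r is the Pearson correlation of upper-triangle entries; significance
    comes from jointly permuting rows/columns of the second matrix.  The
    test is one-sided for positive association (the conventional form),
    with the inclusive permutation p-value.
    """
    if list(d1.index) != list(d2.index):
        if set(d1.index) != set(d2.index):
            raise ValueError("distance matrices cover different sample sets")
        d2 = d2.loc[d1.index, d1.index]
    a = d1.to_numpy(dtype=float)
    b = d2.to_numpy(dtype=float)
    _check_square(a, list(d1.index))
    _check_square(b, list(d2.index))
    iu = np.triu_indices(len(a), 1)
    av, bv = a[iu], b[iu]
    if np.std(av) == 0 or np.std(bv) == 0:
        raise ValueError("a distance matrix is constant; Mantel r undefined")
    r_obs = float(stats.pearsonr(av, bv)[0])
    rng = np.random.default_rng(seed)
    exceed = 0
    n = len(a)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)][iu]
        if stats.pearsonr(av, bp)[0] >= r_obs:
            exceed += 1
    return MantelResult(
        r=r_obs, p_value=(exceed + 1) / (n_permutations + 1), n_permutations=n_permutations
    )
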