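"""Same-subject cross-tissue stemness correlation structure.

Builds a subject x tissue matrix of stemness scores (averaging the rare
cases where one subject contributed several samples of the same tissue),
then correlates tissues pairwise over the subjects present in both
(pairwise-complete Pearson).  Sex-specific tissues, which cannot share
subjects of both sexes, can be excluded up front.  An agglomerative
average-linkage ordering of the tissues is provided for display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "SEX_TISSUES",
    "TissueCorrelationMatrix",
    "subject_tissue_matrix",
    "pairwise_correlation",
    "average_linkage",
    "cluster_order",
]

#: Sex organs excluded by default from the cross-tissue matrix.
SEX_TISSUES = ("testis", "prostate", "vagina", "uterus", "ovary")


@dataclass
class TissueCorrelationMatrix:
    r: pd.DataFrame          # symmetric, diagonal 1, NaN where overlap < min_overlap
    n_overlap: pd.DataFrame  # symmetric integer overlap counts
    ordering: list[str] | None = None


def subject_tissue_matrix(scores: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Subject x tissue matrix of mean stemness; NaN where unobserved."""
    df = table[["sample_id", "subject_id", "tissue"]].copy()
    df["stemness"] = scores["stemness"].reindex(df["sample_id"]).to_numpy()
    df = df.dropna(subset=["stemness"])
    return df.pivot_table(
        index="subject_id", columns="tissue", values="stemness", aggfunc="mean"
    )


def pairwise_correlation(
    matrix: pd.DataFrame,
    min_overlap: int = 10,
    exclude: tuple[str, ...] = (),
) -> TissueCorrelationMatrix:
    """Pairwise-complete Pearson correlation between tissues.

    Pairs whose shared-subject count falls below ``min_overlap`` are
    masked (NaN) but their overlap count is still reported.
    """
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    mat = matrix.drop(columns=[t for t in exclude if t in matrix.columns])
    tissues = list(mat.columns)
    if len(tissues) < 2:
        raise ValueError("fewer than 2 tissues remain after exclusion")

    k = len(tissues)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(n, mat.notna().sum().to_numpy())
    vals = mat.to_numpy(dtype=np.float64)
    present = ~np.isnan(vals)
    for i in range(k):
        for j in range(i + 1, k):
            both = present[:, i] & present[:, j]
            n[i, j] = n[j, i] = int(both.sum())
            if n[i, j] >= min_overlap:
                r[i, j] = r[j, i] = float(
                    stats.pearsonr(vals[both, i], vals[both, j]).statistic
                )
    return TissueCorrelationMatrix(
        r=pd.DataFrame(r, index=tissues, columns=tissues),
        n_overlap=pd.DataFrame(n, index=tissues, columns=tissues),
    )


def average_linkage(dist: pd.DataFrame) -> list[tuple[frozenset, frozenset, float]]:
    """Unweighted average-linkage (UPGMA-on-dissimilarity) merge trace.

    Returns the merges as ``(members_a, members_b, height)`` triples.
    Ties are broken by the lexicographically smallest pair of cluster
    name tuples, so the trace is independent of input column order.
    """
    names = sorted(str(c) for c in dist.columns)
    d = {
        (a, b): float(dist.loc[a, b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    clusters: dict[tuple[str, ...], list[str]] = {(n,): [n] for n in names}
    cdist: dict[frozenset, float] = {
        frozenset(((a,), (b,))): v for (a, b), v in d.items()
    }
    merges: list[tuple[frozenset, frozenset, float]] = []

    def leaf_count(key: tuple[str, ...]) -> int:
        return len(key)

    while len(clusters) > 1:
        # smallest distance, then lexicographically smallest ordered pair
        best = min(
            (
                (cdist[frozenset((ka, kb))], tuple(sorted((ka, kb)))[0], tuple(sorted((ka, kb)))[1])
                for i, ka in enumerate(sorted(clusters))
                for kb in sorted(clusters)[i + 1 :]
            ),
        )
        height, ka, kb = best
        left, right = (ka, kb) if ka <= kb else (kb, ka)
        merges.append((frozenset(left), frozenset(right), height))
        new_key = tuple(sorted(left + right))
        new_order = clusters[left] + clusters[right]
        na, nb = leaf_count(left), leaf_count(right)
        for other in list(clusters):
            if other in (left, right):
                continue
            dl = cdist.pop(frozenset((left, other)))
            dr = cdist.pop(frozenset((right, other)))
            cdist[frozenset((new_key, other))] = (na * dl + nb * dr) / (na + nb)
        cdist.pop(frozenset((left, right)))
        del clusters[left], clusters[right]
        clusters[new_key] = new_order
    return merges


def cluster_order(r: pd.DataFrame) -> list[str]:
    """Leaf order of tissues under average-linkage clustering of 1 - r.

    Requires a complete (NaN-free) correlation matrix; raise otherwise
    and let the caller drop sparse tissues or lower ``min_overlap``
    masking first.
    """
    if r.isna().to_numpy().any():
        raise ValueError(
            "correlation matrix has masked entries; drop sparse tissues or "
            "relax the overlap mask before clustering"
        )
    dist = 1.0 - r
    names = sorted(str(c) for c in r.columns)
    orders: dict[tuple[str, ...], list[str]] = {(n,): [n] for n in names}
    for left, right, _height in average_linkage(dist):
        lkey = tuple(sorted(left))
        rkey = tuple(sorted(right))
        orders[tuple(sorted(lkey + rkey))] = orders.pop(lkey) + orders.pop(rkey)
    (final,) = orders.values()
    return final
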