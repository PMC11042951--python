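"""Correlation and group-comparison battery for stemness scores.

Per-tissue Pearson correlations of the stemness score against a numeric
covariate (age, a marker gene's expression, a gene-set mean signal), with
Benjamini-Hochberg FDR applied across the tissues reported in one
analysis family; plus two-group (t-test) and multi-group
(Kruskal-Wallis) comparisons for cohorts with discrete designs.

Gene-set signals follow the mean-expression convention: the signal of a
set in a sample is the arithmetic mean of the TPM values of the set's
genes present in the matrix (used here for proliferation and senescence
gene lists).
"""

from __future__ import annotations

import difflib
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "pearson",
    "bh_adjust",
    "correlate_within_groups",
    "gene_set_signal",
    "marker_signal",
    "compare_groups",
    "derive_proliferation_set",
]


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[str, ...]
    statistic: float
    p: float
    test: str  # "t" or "kruskal-wallis"


def _check_vector(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p from the exact t transform (n-2 df)."""
    xa, ya = _check_vector(x, "x"), _check_vector(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0:
        raise ValueError("x has zero variance")
    if np.ptp(ya) == 0:
        raise ValueError("y has zero variance")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError("p must be 1-D")
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def correlate_within_groups(
    scores: pd.DataFrame,
    table: pd.DataFrame,
    x: str | pd.Series,
    group_var: str = "tissue",
    min_n: int = 50,
    score_col: str = "stemness",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group Pearson correlation of the score against ``x``.

    ``x`` is either the name of a numeric column of ``table`` (e.g.
    ``"age_years"``) or a Series of per-sample values indexed by sample
    id (e.g. a marker or gene-set signal).  Groups with fewer than
    ``min_n`` complete samples are not tested; they come back in the
    second returned frame.  BH correction is applied across the tested
    groups only — one correction per analysis family.

    Returns ``(results, skipped)`` where ``results`` has columns
    ``group, n, r, p, fdr`` and ``skipped`` has ``group, n``.
    """
    df = table[["sample_id", group_var]].copy()
    df["y"] = scores[score_col].reindex(df["sample_id"]).to_numpy()
    if isinstance(x, str):
        df["x"] = pd.to_numeric(table[x], errors="raise").to_numpy()
    else:
        df["x"] = x.reindex(df["sample_id"]).to_numpy()
    df = df.dropna(subset=["x", "y", group_var])

    rows, skipped = [], []
    for group, sub in df.groupby(group_var, sort=True):
        if len(sub) < min_n:
            skipped.append({"group": group, "n": len(sub)})
            continue
        r, p = pearson(sub["x"], sub["y"])
        rows.append({"group": group, "n": len(sub), "r": r, "p": p})
    if not rows:
        raise ValueError(f"no group reaches min_n={min_n}")
    res = pd.DataFrame(rows)
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    return res, pd.DataFrame(skipped, columns=["group", "n"])


def gene_set_signal(X: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Per-sample mean TPM of the set's genes present in the matrix."""
    present = [g for g in X.index if g in gene_set.genes]
    if not present:
        raise KeyError(f"no gene of set {gene_set.name!r} present in the matrix")
    coverage = len(present) / len(gene_set.genes)
    if coverage < 0.5:
        warnings.warn(
            f"set {gene_set.name!r}: only {coverage:.1%} of genes present"
        )
    return X.loc[present].mean(axis=0).rename(gene_set.name)


def marker_signal(X: pd.DataFrame, gene_id: str) -> pd.Series:
    """A single marker gene's expression row, as a per-sample signal."""
    if gene_id not in X.index:
        near = difflib.get_close_matches(gene_id, [str(g) for g in X.index], n=3)
        hint = f"; close matches: {near}" if near else ""
        raise KeyError(f"gene {gene_id!r} not in the matrix{hint}")
    return X.loc[gene_id].rename(gene_id)


def compare_groups(
    values: pd.Series, groups: pd.Series, pooled: bool = False
) -> GroupComparison:
    """Compare score distributions across groups.

    Two groups: two-sided two-sample t-test, Welch (unequal variances) by
    default, classic pooled-variance form with ``pooled=True``.  Three or
    more groups: Kruskal-Wallis with tie correction.
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    by_group = {str(g): sub["value"].to_numpy() for g, sub in df.groupby("group", sort=True)}
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    small = [g for g, v in by_group.items() if v.size < 2]
    if small:
        raise ValueError(f"group(s) with < 2 samples: {small}")
    samples = list(by_group.values())
    if len(by_group) == 2:
        res = stats.ttest_ind(samples[0], samples[1], equal_var=pooled)
        return GroupComparison(tuple(by_group), float(res.statistic), float(res.pvalue), "t")
    if np.ptp(np.concatenate(samples)) == 0:
        raise ValueError("all values identical; Kruskal-Wallis undefined")
    res = stats.kruskal(*samples)
    return GroupComparison(tuple(by_group), float(res.statistic), float(res.pvalue), "kruskal-wallis")


def derive_proliferation_set(
    X: pd.DataFrame, marker: str = "PCNA", top_frac: float = 0.01
) -> GeneSet:
    """Build a proliferation gene list from correlation with a marker.

    Takes the top ``top_frac`` of genes most positively Pearson-correlated
    with the marker's expression across samples (the marker itself is
    excluded from the ranking).  A supplied curated list is the normal
    input for the proliferation signal; this helper reconstructs one from
    the data when no list is available.
    """
    if not 0 < top_frac < 1:
        raise ValueError("top_frac must be in (0, 1)")
    m = marker_signal(X, marker)
    others = X.drop(index=marker)
    xc = others.to_numpy(dtype=np.float64)
    mc = m.to_numpy(dtype=np.float64)
    mc = mc - mc.mean()
    xc = xc - xc.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1)) * np.sqrt((mc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ mc) / denom
    r = np.where(np.isfinite(r), r, -np.inf)  # flat genes cannot rank
    k = max(1, int(np.floor(top_frac * others.shape[0])))
    top = np.argsort(-r, kind="stable")[:k]
    return GeneSet(
        name=f"top{top_frac:g}_{marker}_correlated",
        genes=frozenset(str(others.index[i]) for i in top),
        description=f"top {top_frac:g} fraction of genes by Pearson r with {marker}",
    )
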