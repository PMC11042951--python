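"""Score samples against a stemness signature.

Each sample's raw score is the Spearman rank correlation between the
signature's weight vector and the sample's expression profile over the
genes shared by both (average ranks for ties).  Because only ranks enter,
scores are invariant to any strictly increasing transform of a sample's
expression values — TPM, log-TPM and quantile-normalised data all score
identically.  Raw scores are then min-max rescaled to [0, 1] within a
rescaling cohort, so 0 and 1 mean "least/most stem-like *of these
samples*", not absolute stemness.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import validate_expression
from .oclr import StemnessSignature

log = logging.getLogger(__name__)

__all__ = [
    "intersect_signature",
    "score_samples",
    "rescale_unit",
    "score_cohort",
]


class DegenerateCohortError(ValueError):
    """All raw scores identical; rescaling to [0, 1] is undefined."""


def intersect_signature(
    signature: StemnessSignature, X: pd.DataFrame
) -> tuple[StemnessSignature, pd.DataFrame, float]:
    """Restrict signature and matrix to their shared genes.

    Returns the reduced signature, the reduced matrix (rows in signature
    order) and the coverage fraction kept/|signature|.  Empty
    intersection is an error; coverage below 0.5 warns.
    """
    keep = [g for g in signature.gene_ids if g in X.index]
    if not keep:
        raise ValueError("signature and expression matrix share no genes")
    coverage = len(keep) / len(signature.gene_ids)
    if coverage < 0.5:
        warnings.warn(
            f"only {coverage:.1%} of signature genes present in the matrix"
        )
    ser = signature.to_series().loc[keep]
    reduced = StemnessSignature(
        gene_ids=keep,
        weights=ser.to_numpy(),
        lambda2=signature.lambda2,
        n_train=signature.n_train,
        converged=signature.converged,
        final_objective=signature.final_objective,
        n_iter=signature.n_iter,
    )
    return reduced, X.loc[keep], coverage


def score_samples(signature: StemnessSignature, X: pd.DataFrame) -> pd.Series:
    """Raw stemness scores: Spearman rho of weights vs each sample.

    ``X`` must contain every signature gene (run
    :func:`intersect_signature` first if it may not).  A sample with zero
    expression variance across the shared genes has no defined rank
    correlation; it is returned as NaN with a warning.
    """
    missing = set(signature.gene_ids) - set(X.index)
    if missing:
        raise KeyError(
            f"{len(missing)} signature gene(s) absent from the matrix; "
            "call intersect_signature first"
        )
    if len(signature.gene_ids) < 3:
        raise ValueError("need at least 3 shared genes for a rank correlation")
    vals = X.loc[signature.gene_ids].to_numpy(dtype=np.float64)

    rw = rankdata(signature.weights)
    R = rankdata(vals, axis=0).astype(np.float64)

    rw_c = rw - rw.mean()
    R_c = R - R.mean(axis=0)
    denom_w = np.sqrt((rw_c**2).sum())
    denom_x = np.sqrt((R_c**2).sum(axis=0))

    flat = denom_x == 0  # constant expression -> constant ranks
    if denom_w == 0:
        raise ValueError("signature weights are all tied; Spearman undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rw_c @ R_c) / (denom_w * denom_x)
    rho[flat] = np.nan
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} sample(s) with zero expression variance "
            "across signature genes scored as missing"
        )
    return pd.Series(rho, index=X.columns, name="raw_score")


def rescale_unit(raw: pd.Series) -> pd.Series:
    """Min-max rescale raw scores to [0, 1]; NaNs propagate unchanged."""
    finite = raw.dropna()
    if finite.size < 2 or finite.nunique() < 2:
        raise DegenerateCohortError(
            "all raw scores are equal; cannot rescale to [0, 1] — "
            "score jointly with a larger or more diverse cohort"
        )
    lo, hi = finite.min(), finite.max()
    return ((raw - lo) / (hi - lo)).rename("stemness")


def score_cohort(
    signature: StemnessSignature,
    X: pd.DataFrame,
    rescale_scope: str = "all",
    sample_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score a cohort end to end: intersect, correlate, rescale.

    ``rescale_scope`` is ``"all"`` (one pooled min-max over every sample)
    or ``"per-tissue"`` (min-max within each tissue of ``sample_table``).
    Returns a table indexed by sample id with ``raw_score``, ``stemness``
    and ``n_genes_used`` columns; raw scores are always emitted so the
    rescaling can be redone under a different scope without re-scoring.
    """
    X = validate_expression(X, "cohort matrix")
    reduced, Xr, _coverage = intersect_signature(signature, X)
    raw = score_samples(reduced, Xr)

    if rescale_scope == "all":
        stemness = rescale_unit(raw)
    elif rescale_scope == "per-tissue":
        if sample_table is None:
            raise ValueError("per-tissue rescaling needs a sample table")
        tissue = sample_table.set_index("sample_id")["tissue"].reindex(raw.index)
        if tissue.isna().any():
            missing = raw.index[tissue.isna()].tolist()[:5]
            raise ValueError(f"samples missing from sample table, e.g. {missing}")
        stemness = raw.groupby(tissue, group_keys=False).apply(rescale_unit).reindex(raw.index)
        stemness = stemness.rename("stemness")
    else:
        raise ValueError(f"unknown rescale_scope {rescale_scope!r}")

    return pd.DataFrame(
        {
            "raw_score": raw,
            "stemness": stemness,
            "n_genes_used": len(reduced.gene_ids),
        }
    ).rename_axis("sample_id")
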