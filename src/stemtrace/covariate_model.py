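"""Per-tissue linear model of stemness on age with covariate adjustment.

For each tissue the stemness score is regressed on age (years, numeric)
plus treatment-coded dummies for sex, death classification (Hardy code)
and tissue region.  A categorical that has fewer than two observed
levels within a tissue — sex in a single-sex organ, region in a tissue
sampled from one site — carries no information and is dropped, with the
drop recorded.  Rows missing a value in a retained covariate are dropped
(complete-case).  The fit is ordinary least squares with classic
t-based standard errors; with a single response per tissue any
variance-moderation machinery would be inert, so plain OLS is the exact
contract.

The age-effect summary reports ``alpha`` (stemness change per year), its
standard error and p-value, and a fold-change-style quantity
``log2fc = log2( yhat(75) / yhat(25) )`` — the model-predicted stemness
ratio between ages 75 and 25 with every categorical at its reference
level — defined only when both predictions are positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "DesignInfo",
    "OLSFit",
    "build_design",
    "ols_fit",
    "age_effect",
    "age_effect_table",
]

DEFAULT_COVARIATES = ("sex", "death", "region")


@dataclass
class DesignInfo:
    """Bookkeeping for one tissue's design matrix."""

    columns: list[str]
    dropped_covariates: list[str]
    reference_levels: dict[str, str]
    rows_used: pd.Index
    n_rows_dropped_missing: int = 0


@dataclass
class OLSFit:
    params: pd.Series
    se: pd.Series
    t: pd.Series
    p: pd.Series
    sigma2: float
    df_resid: int
    n: int


def build_design(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> tuple[pd.DataFrame, DesignInfo]:
    """Design matrix for one tissue: intercept, age, categorical dummies.

    ``table`` holds that tissue's samples with an ``age_years`` column
    and the categorical covariate columns.  Treatment coding uses the
    most frequent level as the reference (lexicographic tie-break);
    categoricals with a single observed level (or entirely missing) are
    dropped and recorded.  Raises on a rank-deficient result, naming the
    aliased columns.
    """
    if "age_years" not in table.columns:
        raise ValueError("table must contain age_years")

    observed_levels: dict[str, list[str]] = {}
    dropped: list[str] = []
    for cov in covariates:
        levels = (
            table[cov].dropna().unique().tolist() if cov in table.columns else []
        )
        if len(levels) >= 2:
            observed_levels[cov] = [str(l) for l in levels]
        else:
            dropped.append(cov)

    keep = table["age_years"].notna()
    for cov in observed_levels:
        keep &= table[cov].notna()
    used = table.loc[keep]
    n_dropped_rows = int((~keep).sum())
    if n_dropped_rows:
        log.info("build_design: dropped %d row(s) with missing covariates", n_dropped_rows)

    design = pd.DataFrame(index=used.index)
    design["intercept"] = 1.0
    design["age_years"] = used["age_years"].astype(float)
    references: dict[str, str] = {}
    for cov, levels in observed_levels.items():
        counts = used[cov].astype(str).value_counts()
        # a level may vanish after complete-case filtering
        levels = [l for l in levels if l in counts.index]
        if len(levels) < 2:
            dropped.append(cov)
            continue
        ref = sorted(counts.index[counts == counts.max()])[0]
        references[cov] = ref
        for level in sorted(l for l in levels if l != ref):
            design[f"{cov}[{level}]"] = (used[cov].astype(str) == level).astype(float)

    n, p = design.shape
    if n < p + 2:
        raise ValueError(
            f"only {n} usable samples for {p} design columns; need at least {p + 2}"
        )
    mat = design.to_numpy(dtype=np.float64)
    if np.linalg.matrix_rank(mat) < p:
        # identify columns whose removal restores full rank
        aliased = [
            design.columns[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(mat, j, axis=1))
            == np.linalg.matrix_rank(mat)
        ]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

    info = DesignInfo(
        columns=list(design.columns),
        dropped_covariates=sorted(set(dropped)),
        reference_levels=references,
        rows_used=used.index,
        n_rows_dropped_missing=n_dropped_rows,
    )
    return design, info


def ols_fit(design: pd.DataFrame, y: pd.Series | np.ndarray) -> OLSFit:
    """Ordinary least squares with classic t-based inference.

    ``p``-values are two-sided from the t distribution with ``n - p``
    residual degrees of freedom.
    """
    X = np.asarray(design, dtype=np.float64)
    yv = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if yv.shape[0] != n:
        raise ValueError("response length does not match design")
    if n <= p:
        raise ValueError("need more observations than design columns")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular design matrix")

    beta, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    df_resid = n - p
    sigma2 = float(resid @ resid) / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

    cols = list(design.columns) if hasattr(design, "columns") else list(range(p))
    return OLSFit(
        params=pd.Series(beta, index=cols),
        se=pd.Series(se, index=cols),
        t=pd.Series(tvals, index=cols),
        p=pd.Series(pvals, index=cols),
        sigma2=sigma2,
        df_resid=df_resid,
        n=n,
    )


def age_effect(
    fit: OLSFit, age_low: float = 25.0, age_high: float = 75.0
) -> dict[str, object]:
    """Summarise the fitted age coefficient.

    Predictions for the log2 fold change are taken at the categorical
    reference levels (all dummies zero): ``yhat(a) = intercept + alpha*a``.
    """
    if "age_years" not in fit.params.index:
        raise ValueError("model has no age term")
    alpha = float(fit.params["age_years"])
    intercept = float(fit.params.get("intercept", 0.0))
    y_low = intercept + alpha * age_low
    y_high = intercept + alpha * age_high
    if alpha == 0.0:
        log2fc, reason = 0.0, None
    elif y_low > 0 and y_high > 0:
        log2fc, reason = float(np.log2(y_high / y_low)), None
    else:
        log2fc, reason = np.nan, "predicted stemness non-positive at an endpoint"
    return {
        "alpha": alpha,
        "se": float(fit.se["age_years"]),
        "p": float(fit.p["age_years"]),
        "log2fc": log2fc,
        "log2fc_undefined_reason": reason,
    }


def age_effect_table(
    scores: pd.DataFrame,
    table: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    score_col: str = "stemness",
) -> pd.DataFrame:
    """Fit the covariate-adjusted age model per tissue.

    Tissues whose usable sample count cannot support the design are
    skipped with a logged reason.  BH correction is applied across the
    fitted tissues.  Returns one row per fitted tissue: ``tissue, n,
    alpha, se, p, fdr, log2fc, dropped_covariates``.
    """
    merged = table.copy()
    merged["stemness"] = scores[score_col].reindex(merged["sample_id"]).to_numpy()
    merged = merged.dropna(subset=["stemness"])

    rows = []
    for tissue, sub in merged.groupby("tissue", sort=True):
        try:
            design, info = build_design(sub, covariates)
        except ValueError as exc:
            log.warning("age_effect_table: skipping %s (%s)", tissue, exc)
            continue
        fit = ols_fit(design, sub.loc[info.rows_used, "stemness"])
        eff = age_effect(fit)
        rows.append(
            {
                "tissue": tissue,
                "n": fit.n,
                "alpha": eff["alpha"],
                "se": eff["se"],
                "p": eff["p"],
                "log2fc": eff["log2fc"],
                "dropped_covariates": ",".join(info.dropped_covariates),
            }
        )
    if not rows:
        raise ValueError("no tissue could be fitted")
    out = pd.DataFrame(rows)
    # exact fits give p == 0, outside bh_adjust's domain; clip into (0, 1]
    out["fdr"] = bh_adjust(np.clip(out["p"].to_numpy(), 1e-300, 1.0))
    return out[["tissue", "n", "alpha", "se", "p", "fdr", "log2fc", "dropped_covariates"]]
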