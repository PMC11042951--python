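"""One-class logistic regression (OCLR) stemness-signature training.

The signature is a per-gene weight vector ``w`` obtained by maximising the
ridge-penalised one-class logistic likelihood over the pluripotent-labeled
training samples::

    L(w) = (1/n) * sum_i [ s_i - log(1 + exp(s_i)) ] - (lambda2/2) * ||w||^2,
    s_i = w . x_i

where ``x_i`` is the mean-centered expression profile of training sample
``i``.  Each summand equals ``-softplus(-s_i)``, so ``L`` is concave and
``-log 2`` at ``w = 0``; the ridge term makes it strictly concave, and the
maximiser is found by deterministic gradient ascent from ``w = 0`` (no
random initialisation, hence exactly reproducible).  There is no
intercept: downstream scoring uses rank correlation, which is invariant
to adding a constant.

Centering matters.  The per-gene means are taken over the *whole*
training matrix — pluripotent samples and their differentiated
progenitors together — and the likelihood is then maximised over the
pluripotent columns only.  If instead one centers over exactly the fitted
samples, the class mean is identically zero, the gradient at ``w = 0``
vanishes, and by concavity ``w = 0`` is the global maximum: the model can
learn nothing.  :func:`train_signature` implements the two-step pipeline;
:func:`fit_oclr` is the bare optimiser for an already-centered,
already-subset matrix.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import validate_expression

log = logging.getLogger(__name__)

__all__ = [
    "StemnessSignature",
    "mean_center",
    "oclr_objective",
    "oclr_gradient",
    "fit_oclr",
    "train_signature",
]


@dataclass
class StemnessSignature:
    """A trained gene-weight vector plus training metadata."""

    gene_ids: list[str]
    weights: np.ndarray
    lambda2: float
    n_train: int
    converged: bool
    final_objective: float
    n_iter: int = 0
    #: per-iteration objective values (not persisted by save/load)
    objective_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.gene_ids) != self.weights.shape[0]:
            raise ValueError("gene_ids and weights length mismatch")
        if not np.isfinite(self.weights).all():
            raise ValueError("signature weights must be finite")

    def to_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.gene_ids, name="weight")

    def save(self, path: str | Path) -> None:
        """Write weights as two-column TSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_series().to_csv(path, sep="\t", index_label="gene_id")
        meta = {
            "lambda2": self.lambda2,
            "n_train": self.n_train,
            "converged": self.converged,
            "final_objective": self.final_objective,
            "n_iter": self.n_iter,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "StemnessSignature":
        path = Path(path)
        ser = pd.read_csv(path, sep="\t", index_col=0)["weight"]
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            gene_ids=[str(g) for g in ser.index],
            weights=ser.to_numpy(),
            lambda2=float(meta.get("lambda2", np.nan)),
            n_train=int(meta.get("n_train", 0)),
            converged=bool(meta.get("converged", True)),
            final_objective=float(meta.get("final_objective", np.nan)),
            n_iter=int(meta.get("n_iter", 0)),
        )


def mean_center(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Center each gene row to zero mean across the given samples.

    Returns the centered matrix and the subtracted per-gene means (kept
    for provenance).
    """
    means = X.mean(axis=1)
    centered = X.sub(means, axis=0)
    return centered, means.rename("gene_mean")


def _as_array(X_centered) -> np.ndarray:
    arr = np.asarray(
        X_centered.to_numpy() if hasattr(X_centered, "to_numpy") else X_centered,
        dtype=np.float64,
    )
    if arr.ndim != 2:
        raise ValueError("X_centered must be a 2-D genes x samples matrix")
    if not np.isfinite(arr).all():
        raise ValueError("X_centered contains non-finite values")
    return arr


def oclr_objective(w: np.ndarray, X_centered, lambda2: float) -> float:
    """Penalised one-class log-likelihood ``L(w)`` (higher is better)."""
    X = _as_array(X_centered)
    w = np.asarray(w, dtype=np.float64)
    if not np.isfinite(w).all():
        raise ValueError("w contains non-finite values")
    s = w @ X
    # s - log(1+exp(s)) == -log1p(exp(-s)) == -softplus(-s), overflow-safe
    ll = -np.logaddexp(0.0, -s).mean()
    return float(ll - 0.5 * lambda2 * (w @ w))


def oclr_gradient(w: np.ndarray, X_centered, lambda2: float) -> np.ndarray:
    """Gradient of :func:`oclr_objective`: ``(1/n) X (1 - sigma(s)) - lambda2 w``."""
    X = _as_array(X_centered)
    w = np.asarray(w, dtype=np.float64)
    if not np.isfinite(w).all():
        raise ValueError("w contains non-finite values")
    s = w @ X
    # 1 - sigma(s) == sigma(-s), computed stably
    with np.errstate(over="ignore"):
        resid = np.where(s >= 0, np.exp(-s) / (1.0 + np.exp(-s)), 1.0 / (1.0 + np.exp(s)))
    return X @ resid / X.shape[1] - lambda2 * w


def _newton_direction(
    X: np.ndarray, gram: np.ndarray, s: np.ndarray, g: np.ndarray, lambda2: float
) -> np.ndarray:
    """Solve (X D X^T / n + lambda2 I) p = g via the Woodbury identity.

    D = diag(sigma(s)(1 - sigma(s))) is the logistic curvature; the
    p x p Hessian is never formed — only an n x n system is solved,
    which is what makes Newton steps cheap when genes vastly outnumber
    training samples.
    """
    n = X.shape[1]
    with np.errstate(over="ignore"):
        sig = 1.0 / (1.0 + np.exp(-s))
    d = np.maximum(sig * (1.0 - sig) / n, 1e-300)
    # (lambda I + X D X^T)^-1 = I/lambda - X (D^-1 + G/lambda)^-1 X^T / lambda^2
    M = np.diag(1.0 / d) + gram / lambda2
    rhs = X.T @ g
    inner = np.linalg.solve(M, rhs)
    return g / lambda2 - (X @ inner) / lambda2**2


def fit_oclr(
    X_centered,
    gene_ids: list[str] | None = None,
    lambda2: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    seed: int | None = None,
) -> StemnessSignature:
    """Maximise the OCLR objective by damped Newton ascent from ``w = 0``.

    Stops when the gradient max-norm drops below ``tol`` or after
    ``max_iter`` steps (``converged`` records which).  Each step follows
    the exact Newton direction of this strictly concave objective with
    Armijo backtracking, so the objective trace is monotonically
    non-decreasing and the result depends only on the set of training
    samples, not their order.  ``seed`` is accepted for interface
    symmetry but unused: the solver is deterministic.
    """
    if lambda2 <= 0:
        raise ValueError("lambda2 must be > 0")
    X = _as_array(X_centered)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 training samples")
    if gene_ids is None:
        gene_ids = (
            [str(g) for g in X_centered.index]
            if hasattr(X_centered, "index")
            else [f"g{i}" for i in range(X.shape[0])]
        )

    w = np.zeros(X.shape[0])
    if not X.any():
        warnings.warn("all-zero training matrix; returning zero signature")
        return StemnessSignature(
            gene_ids=list(gene_ids),
            weights=w,
            lambda2=lambda2,
            n_train=X.shape[1],
            converged=True,
            final_objective=oclr_objective(w, X, lambda2),
        )

    gram = X.T @ X
    converged = False
    it = 0
    obj = oclr_objective(w, X, lambda2)
    trace = [obj]
    for it in range(1, max_iter + 1):
        s = w @ X
        g = oclr_gradient(w, X, lambda2)
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        direction = _newton_direction(X, gram, s, g, lambda2)
        slope = float(g @ direction)  # > 0: ascent direction
        step = 1.0
        while step > 1e-12:
            cand = w + step * direction
            new_obj = oclr_objective(cand, X, lambda2)
            if new_obj >= obj + 1e-4 * step * slope:
                break
            step *= 0.5
        w = w + step * direction
        obj = oclr_objective(w, X, lambda2)
        trace.append(obj)
    if not converged:
        log.warning("fit_oclr: no convergence in %d iterations", max_iter)
    return StemnessSignature(
        gene_ids=list(gene_ids),
        weights=w,
        lambda2=lambda2,
        n_train=X.shape[1],
        converged=converged,
        final_objective=oclr_objective(w, X, lambda2),
        n_iter=it,
        objective_trace=np.asarray(trace),
    )


def train_signature(
    X: pd.DataFrame,
    stem_labels: pd.Series | None = None,
    lambda2: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> StemnessSignature:
    """Full training pipeline: validate, mean-center, fit on stem samples.

    ``stem_labels`` is a boolean Series over (a superset of) the columns
    of ``X`` flagging the pluripotent samples; centering always uses all
    columns of ``X``.  If ``stem_labels`` is None every sample is treated
    as pluripotent — note that the fit is then degenerate (see module
    docstring), so a reference class should normally be present.
    """
    X = validate_expression(X, "training matrix")
    centered, _ = mean_center(X)
    if stem_labels is None:
        warnings.warn(
            "no stem labels given: centering and fitting on the same samples "
            "makes the one-class fit degenerate (w ~ 0)"
        )
        fit_cols = centered
        n_stem = X.shape[1]
    else:
        stem_ids = [c for c in X.columns if bool(stem_labels.get(c, False))]
        if len(stem_ids) < 2:
            raise ValueError("need at least 2 stem-labeled training samples")
        fit_cols = centered[stem_ids]
        n_stem = len(stem_ids)
    sig = fit_oclr(
        fit_cols, gene_ids=[str(g) for g in X.index], lambda2=lambda2,
        tol=tol, max_iter=max_iter,
    )
    sig.n_train = n_stem
    return sig
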