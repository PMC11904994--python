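"""Per-sample signature scoring and the composite angiogenesis score.

The central statistic is a single-sample gene-set enrichment score (ssGSEA
family): genes are ranked per sample by descending expression and a weighted
running sum is integrated over the ranked list.  Because the score depends on
within-sample ranks only, it is invariant to any monotone transform of a
sample's expression vector, which is the property the downstream analyses
(correlations, group contrasts, averaging into a composite) rely on.

The composite angiogenesis score averages six per-sample features: four
pathway enrichment scores, a reference-based endothelial fraction obtained by
constrained least squares, and a marker-set endothelial enrichment score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ScoringError, UndefinedStatisticError, ValidationError

__all__ = [
    "GeneSet",
    "ReferenceProfiles",
    "ssgsea_score",
    "ssgsea_score_matrix",
    "deconvolve_endothelial",
    "deconvolve_fractions",
    "angiogenesis_composite",
    "correlate",
]


@dataclass(frozen=True)
class GeneSet:
    """A named list of unique gene identifiers."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set needs a non-empty name")
        if len(self.genes) == 0:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate gene IDs")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ReferenceProfiles:
    """Mean linear-scale expression profiles per cell type.

    Used as the regression design for bulk deconvolution; must include an
    ``endothelial`` column to estimate the endothelial fraction feature.
    """

    profiles: pd.DataFrame  # genes x cell types, linear scale, non-negative
    min_overlap: int = 10

    def __post_init__(self) -> None:
        if (self.profiles.values < 0).any():
            raise ValidationError("reference profiles must be non-negative")
        if self.profiles.columns.duplicated().any():
            raise ValidationError("duplicate cell-type names in reference")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)


def _validate_expression(expr: pd.DataFrame) -> None:
    if expr.index.duplicated().any():
        raise ValidationError("expression matrix has duplicate gene IDs")
    if expr.columns.duplicated().any():
        raise ValidationError("expression matrix has duplicate sample IDs")
    if not np.isfinite(expr.values).all():
        raise ValidationError("expression matrix contains non-finite values")


def ssgsea_score(
    expr: pd.DataFrame,
    gene_set: GeneSet,
    alpha: float = 0.25,
    min_overlap: int = 2,
) -> pd.Series:
    """Integrated weighted running-sum enrichment score per sample.

    For each sample, genes are ranked by descending expression (average ranks
    on ties).  Walking the ranked list, in-set genes advance the hit curve by
    ``(G - rank + 1)**alpha`` normalised to the in-set total, out-of-set genes
    advance the miss curve by ``1/(G - m)`` where ``m`` is the in-matrix set
    size.  The score is the sum of (hit - miss) over all positions.

    Parameters
    ----------
    expr
        Genes x samples matrix (any monotone per-sample scale).
    gene_set
        The signature to score.
    alpha
        Rank-weight exponent; 0.25 is the ssGSEA convention.
    min_overlap
        Minimum number of set genes that must be present in the matrix.
    """
    _validate_expression(expr)
    present = [g for g in gene_set.genes if g in expr.index]
    m = len(present)
    G = expr.shape[0]
    if m < min_overlap:
        raise ScoringError(
            f"gene set {gene_set.name!r}: only {m} of {len(gene_set)} genes "
            f"present in matrix (minimum {min_overlap})"
        )
    if G == m:
        raise ScoringError(
            f"gene set {gene_set.name!r} covers the whole matrix; "
            "no out-of-set genes to walk"
        )
    in_set = np.asarray(expr.index.isin(present))
    values = expr.to_numpy(dtype=float)
    scores = np.empty(expr.shape[1])
    miss_step = 1.0 / (G - m)
    for j in range(expr.shape[1]):
        col = values[:, j]
        # descending average ranks; rank 1 = highest expression
        ranks = G + 1.0 - stats.rankdata(col)
        weights = (G - ranks + 1.0) ** alpha
        order = np.argsort(-col, kind="stable")
        in_ord = in_set[order]
        w_ord = weights[order]
        hit = np.cumsum(np.where(in_ord, w_ord, 0.0)) / w_ord[in_ord].sum()
        miss = np.cumsum(np.where(in_ord, 0.0, miss_step))
        scores[j] = float(np.sum(hit - miss))
    return pd.Series(scores, index=expr.columns, name=gene_set.name)


def ssgsea_score_matrix(
    expr: pd.DataFrame,
    gene_sets: list[GeneSet],
    alpha: float = 0.25,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Score several signatures; returns a samples x sets table."""
    cols = {gs.name: ssgsea_score(expr, gs, alpha=alpha, min_overlap=min_overlap)
            for gs in gene_sets}
    return pd.DataFrame(cols, index=expr.columns)


def _solve_simplex_lsq(R: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||R f - b||_2  s.t.  f >= 0,  sum(f) <= 1.

    NNLS solves the problem without the sum constraint; when that solution
    already satisfies sum(f) <= 1 it is the constrained optimum.  Otherwise
    the constraint is active and the problem is re-solved on sum(f) = 1 with
    SLSQP.
    """
    f0, _ = optimize.nnls(R, b)
    if f0.sum() <= 1.0 + 1e-12:
        return f0
    k = R.shape[1]

    def obj(f: np.ndarray) -> float:
        r = R @ f - b
        return float(r @ r)

    def grad(f: np.ndarray) -> np.ndarray:
        return 2.0 * R.T @ (R @ f - b)

    res = optimize.minimize(
        obj,
        x0=f0 / f0.sum(),
        jac=grad,
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda f: f.sum() - 1.0}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return np.clip(res.x, 0.0, 1.0)


def deconvolve_fractions(
    expr: pd.DataFrame,
    ref: ReferenceProfiles,
    log2_input: bool = True,
) -> pd.DataFrame:
    """Constrained-least-squares cell-type fractions per sample.

    Fits each linear-scale sample vector as a non-negative combination of the
    reference profiles with total fraction at most 1.  ``log2_input`` converts
    log2(x+1) values back to the linear scale before fitting.
    """
    _validate_expression(expr)
    shared = expr.index.intersection(ref.profiles.index)
    if len(shared) < ref.min_overlap:
        raise ScoringError(
            f"only {len(shared)} genes shared with reference "
            f"(minimum {ref.min_overlap})"
        )
    R = ref.profiles.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        warnings.warn(
            "reference profile matrix is rank-deficient; "
            "fractions are a pseudo-solution",
            stacklevel=2,
        )
    B = expr.loc[shared].to_numpy(dtype=float)
    if log2_input:
        B = np.maximum(np.exp2(B) - 1.0, 0.0)
    out = np.empty((expr.shape[1], R.shape[1]))
    for j in range(expr.shape[1]):
        out[j] = _solve_simplex_lsq(R, B[:, j])
    return pd.DataFrame(out, index=expr.columns, columns=ref.cell_types)


def deconvolve_endothelial(
    expr: pd.DataFrame,
    ref: ReferenceProfiles,
    log2_input: bool = True,
) -> pd.Series:
    """Endothelial fraction in [0, 1] per sample."""
    if "endothelial" not in ref.cell_types:
        raise ValidationError("reference profiles lack an 'endothelial' type")
    frac = deconvolve_fractions(expr, ref, log2_input=log2_input)
    return frac["endothelial"].rename("endothelial_fraction")


def angiogenesis_composite(
    features: pd.DataFrame,
    standardize: bool = True,
) -> pd.Series:
    """Average the angiogenesis features into one score per sample.

    The six canonical features are four pathway enrichment scores plus two
    endothelial-abundance estimates; any feature table works.  With
    ``standardize`` each feature is z-scored across samples before averaging,
    since enrichment scores and fractions live on different scales.  A feature
    that is constant across samples carries no contrast and is dropped (with a
    warning) when standardizing.
    """
    if features.isna().any().any():
        raise ValidationError("feature table contains missing values")
    X = features.astype(float)
    if standardize:
        if X.shape[0] < 2:
            raise ValidationError("standardization needs at least 2 samples")
        sd = X.std(axis=0, ddof=1)
        constant = sd == 0.0
        if constant.any():
            dropped = list(X.columns[constant])
            warnings.warn(
                f"constant features dropped before z-scoring: {dropped}",
                stacklevel=2,
            )
            X = X.loc[:, ~constant]
            sd = sd[~constant]
            if X.shape[1] == 0:
                raise ValidationError("all features constant; no score possible")
        X = (X - X.mean(axis=0)) / sd
    return X.mean(axis=1).rename("angiogenesis_score")


def correlate(
    x,
    y,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation coefficient and p-value for paired per-sample values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ValidationError("correlation needs at least 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("correlation inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined: zero variance")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(r), float(p)
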