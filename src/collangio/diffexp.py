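"""Differential expression and gene-set enrichment.

Genes associated with a subtype contrast are called by a Welch two-sample t
test on log2 expression with a joint raw-p and linear fold-change gate
(defaults p < 0.05, FC >= 1.5).  Set-level enrichment comes in two flavours:
a preranked GSEA (maximum-deviation weighted Kolmogorov-Smirnov running sum,
gene-label permutation null) and a one-sided hypergeometric
over-representation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ScoringError, ValidationError
from .scoring import GeneSet, ssgsea_score_matrix

__all__ = [
    "differential_expression",
    "gsea_preranked",
    "GseaResult",
    "overrepresentation",
    "signature_contrast_heatmap_stats",
]


def differential_expression(
    expr: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    direction: str = "both",
) -> pd.DataFrame:
    """Per-gene Welch t test on log2 values with a p + fold-change gate.

    ``fold_change`` is the linear-scale ratio ``2**(mean_a - mean_b)``.  A gene
    is ``flagged`` when p < ``p_threshold`` and the fold change clears
    ``fc_threshold`` in the requested ``direction`` ("up" = higher in group A,
    "down", or "both").  A Benjamini-Hochberg column is included for
    convenience; the gate itself uses raw p-values.
    """
    if fc_threshold < 1.0:
        raise ValidationError("fc_threshold must be >= 1")
    if direction not in ("both", "up", "down"):
        raise ValidationError(f"unknown direction {direction!r}")
    missing = (set(group_a) | set(group_b)) - set(expr.columns)
    if missing:
        raise ValidationError(f"sample IDs not in matrix: {sorted(missing)[:5]}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("need >= 2 samples per group")
    A = expr[group_a].to_numpy(dtype=float)
    B = expr[group_b].to_numpy(dtype=float)
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tstat, pval = stats.ttest_ind(A, B, axis=1, equal_var=False)
    # zero variance in both groups: p = 1 when means agree, 0 when they differ
    nan = ~np.isfinite(pval)
    pval = np.where(nan & (mean_a == mean_b), 1.0, pval)
    pval = np.where(nan & (mean_a != mean_b), 0.0, pval)
    log2_fc = mean_a - mean_b
    fc = np.exp2(log2_fc)
    up = fc >= fc_threshold
    down = fc <= 1.0 / fc_threshold
    if direction == "up":
        fc_pass = up
    elif direction == "down":
        fc_pass = down
    else:
        fc_pass = up | down
    out = pd.DataFrame(
        {
            "gene": expr.index,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": log2_fc,
            "fold_change": fc,
            "t_statistic": np.where(np.isfinite(tstat), tstat, 0.0),
            "p_value": pval,
            "p_adj_bh": multipletests(pval, method="fdr_bh")[1],
        }
    )
    out["flagged"] = (out["p_value"] < p_threshold) & fc_pass
    return out.set_index("gene")


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    leading_edge: list[str]
    n_overlap: int


def _running_es(in_set: np.ndarray, weights: np.ndarray, n_miss: int) -> np.ndarray:
    """Running hit-minus-miss curve over a ranked list (weight exponent 1)."""
    hit_total = weights[in_set].sum()
    if hit_total == 0:  # all in-set weights zero: fall back to unweighted hits
        hit = np.cumsum(in_set) / in_set.sum()
    else:
        hit = np.cumsum(np.where(in_set, weights, 0.0)) / hit_total
    miss = np.cumsum(~in_set) / n_miss
    return hit - miss


def gsea_preranked(
    ranking: pd.Series,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    min_overlap: int = 3,
) -> GseaResult:
    """Preranked GSEA with a gene-label permutation null.

    ``ranking`` maps gene -> ranking weight (e.g. signed t); genes are sorted
    by descending weight and the enrichment score is the maximum deviation of
    the weighted running sum (in-set steps proportional to |weight|).  The
    null re-draws random same-size gene sets ``n_perm`` times; NES divides the
    observed ES by the mean |null ES| of matching sign, and the p-value is the
    add-one permutation estimate among same-sign nulls.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if ranking.index.duplicated().any():
        raise ValidationError("ranking has duplicate gene IDs")
    ranking = ranking.sort_values(ascending=False, kind="stable")
    genes = ranking.index.to_numpy()
    weights = np.abs(ranking.to_numpy(dtype=float))
    in_set = np.isin(genes, list(gene_set.genes))
    m = int(in_set.sum())
    N = len(genes)
    if m < min_overlap:
        raise ScoringError(
            f"gene set {gene_set.name!r}: overlap {m} below minimum {min_overlap}"
        )
    if m == N:
        raise ScoringError(f"gene set {gene_set.name!r} covers the whole ranking")
    curve = _running_es(in_set, weights, N - m)
    peak = int(np.argmax(np.abs(curve)))
    es = float(curve[peak])
    if es >= 0:
        leading = list(genes[: peak + 1][in_set[: peak + 1]])
    else:
        leading = list(genes[peak:][in_set[peak:]])

    rng = np.random.default_rng(seed)
    null_es = np.empty(n_perm)
    idx = np.arange(N)
    for b in range(n_perm):
        pick = rng.choice(idx, size=m, replace=False)
        mask = np.zeros(N, dtype=bool)
        mask[pick] = True
        c = _running_es(mask, weights, N - m)
        null_es[b] = c[np.argmax(np.abs(c))]
    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        warnings.warn(
            f"no same-sign permutations for {gene_set.name!r}; "
            "p reported at the permutation floor",
            stacklevel=2,
        )
        nes = np.nan
        p = 1.0 / (n_perm + 1)
    else:
        mean_abs = np.abs(null_es[same_sign]).mean()
        nes = es / mean_abs if mean_abs > 0 else np.nan
        p = (1 + int((np.abs(null_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
    return GseaResult(gene_set.name, es, float(nes), float(p), leading, m)


def overrepresentation(
    hits: set[str],
    universe: set[str],
    gene_set: GeneSet,
) -> tuple[float, float]:
    """One-sided hypergeometric over-representation test.

    Returns ``(odds_ratio, p)`` for the upper tail of the 2x2 table of hit
    membership x set membership within ``universe``; the odds ratio gets the
    Haldane 0.5 correction when a cell is zero.
    """
    hits = set(hits)
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    if not hits <= universe:
        raise ValidationError("hits must be a subset of the universe")
    set_in_universe = set(gene_set.genes) & universe
    if not set_in_universe:
        raise ValidationError(
            f"gene set {gene_set.name!r} has no overlap with the universe"
        )
    M = len(universe)
    K = len(set_in_universe)
    n = len(hits)
    k = len(hits & set_in_universe)
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    a, b = k, n - k
    c, d = K - k, M - K - (n - k)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return float(odds), min(p, 1.0)


def signature_contrast_heatmap_stats(
    expr: pd.DataFrame,
    groups: pd.Series,
    gene_sets: list[GeneSet],
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Per-signature, per-group mean single-sample enrichment scores.

    Pure composition: score every signature on every sample, then average
    within groups.  Returns a signatures x groups table.
    """
    if not groups.index.equals(pd.Index(expr.columns)):
        groups = groups.reindex(expr.columns)
        if groups.isna().any():
            raise ValidationError("group labels missing for some samples")
    scores = ssgsea_score_matrix(expr, gene_sets, alpha=alpha)
    return scores.groupby(groups).mean().T
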