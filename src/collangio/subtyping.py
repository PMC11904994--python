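"""Immuno-collagenic subtype assignment and subtype discrimination statistics.

Tumors are placed into three microenvironment subtypes from collagen and
immune activity: ``soft_hot`` (immune-high, fibrosis-low), ``armored_cold``
(collagen-high, immune-low) and ``quiescent`` (both low).  Two bases exist:
ordinal histology scores (tumor-infiltrating immune cell score and fibrosis
score, applied as fixed threshold rules) and continuous transcriptomic scores
(cutpoint rules).  Discrimination of a subtype by a continuous feature is
summarised by the ROC AUC; group differences by ANOVA/Tukey or
Kruskal-Wallis/Dunn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "SUBTYPES",
    "SubtypeCall",
    "assign_histologic_subtype",
    "assign_transcriptomic_subtype",
    "roc_auc",
    "group_contrast",
    "GroupContrastResult",
]

SUBTYPES = ("quiescent", "armored_cold", "soft_hot", "unclassified")


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    subtype: str
    basis: str  # "histologic" | "transcriptomic"

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValidationError(f"unknown subtype {self.subtype!r}")
        if self.basis not in ("histologic", "transcriptomic"):
            raise ValidationError(f"unknown basis {self.basis!r}")


def _histologic_rule(tiic: int, fibrosis: int) -> str:
    if tiic >= 3 and fibrosis in (0, 1):
        return "soft_hot"
    if tiic <= 2 and fibrosis in (2, 3):
        return "armored_cold"
    if tiic <= 2 and fibrosis in (0, 1):
        return "quiescent"
    # e.g. immune-high with heavy fibrosis: not covered by any stated rule
    return "unclassified"


def assign_histologic_subtype(scores: pd.DataFrame) -> list[SubtypeCall]:
    """Apply the histology threshold rules verbatim.

    ``scores`` needs columns ``sample_id``, ``tiic_score`` (ordinal, >= 0) and
    ``fibrosis_score`` (ordinal 0-3).  Combinations outside the three stated
    rules come back ``unclassified``.
    """
    calls: list[SubtypeCall] = []
    for row in scores.itertuples(index=False):
        tiic = int(row.tiic_score)
        fib = int(row.fibrosis_score)
        if tiic < 0:
            raise ValidationError(f"{row.sample_id}: TIIC score must be >= 0")
        if fib not in (0, 1, 2, 3):
            raise ValidationError(
                f"{row.sample_id}: fibrosis score {fib} outside 0-3"
            )
        calls.append(
            SubtypeCall(str(row.sample_id), _histologic_rule(tiic, fib), "histologic")
        )
    return calls


def _resolve_cut(values: pd.Series, cut) -> float:
    """A cutpoint is a number, a quantile spec like ``'q0.75'``, or
    ``'bimodal'`` (midpoint between the two 1-D k-means centres, for cohorts
    where the score distribution has a clear high/low gap)."""
    if isinstance(cut, str):
        if cut == "bimodal":
            x = np.sort(values.to_numpy(dtype=float))
            lo, hi = x[0], x[-1]
            if lo == hi:
                raise ValidationError("bimodal cutpoint needs non-constant scores")
            # 1-D 2-means by threshold sweep (exact: clusters are contiguous)
            best_cut, best_ss = None, np.inf
            for i in range(1, len(x)):
                a, b = x[:i], x[i:]
                ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
                if ss < best_ss:
                    best_ss = ss
                    best_cut = 0.5 * (a.mean() + b.mean())
            return float(best_cut)
        if not cut.startswith("q"):
            raise ValidationError(f"cutpoint spec {cut!r} not understood")
        q = float(cut[1:])
        if not 0.0 < q < 1.0:
            raise ValidationError("quantile cutpoint must be in (0, 1)")
        return float(values.quantile(q))
    return float(cut)


def assign_transcriptomic_subtype(
    collagen_score: pd.Series,
    immune_score: pd.Series,
    collagen_cut="q0.5",
    immune_cut="q0.5",
    high_high: str = "soft_hot",
) -> list[SubtypeCall]:
    """Cutpoint rule on continuous collagen and immune scores.

    immune >= cut -> soft_hot; else collagen >= cut -> armored_cold; else
    quiescent.  Samples high on both axes are rare and fold into soft_hot by
    default (immune dominates); pass ``high_high='unclassified'`` to flag them
    instead.  Cutpoints may be absolute values or per-cohort quantiles
    (default: medians), the latter making the assignment invariant to common
    monotone transforms of both scores.
    """
    if not collagen_score.index.equals(immune_score.index):
        raise ValidationError("collagen and immune scores must share sample IDs")
    if not (np.isfinite(collagen_score).all() and np.isfinite(immune_score).all()):
        raise ValidationError("subtype scores must be finite")
    if high_high not in ("soft_hot", "unclassified"):
        raise ValidationError("high_high must be 'soft_hot' or 'unclassified'")
    quantile_based = isinstance(collagen_cut, str) or isinstance(immune_cut, str)
    if quantile_based and len(collagen_score) < 4:
        raise ValidationError("need >= 4 samples to derive quantile cutpoints")
    ccut = _resolve_cut(collagen_score, collagen_cut)
    icut = _resolve_cut(immune_score, immune_cut)
    calls = []
    for sid in collagen_score.index:
        c_high = collagen_score[sid] >= ccut
        i_high = immune_score[sid] >= icut
        if i_high:
            subtype = high_high if c_high else "soft_hot"
        elif c_high:
            subtype = "armored_cold"
        else:
            subtype = "quiescent"
        calls.append(SubtypeCall(str(sid), subtype, "transcriptomic"))
    return calls


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), plus the ROC curve.

    Computed rank-equivalently (Mann-Whitney identity), which handles ties
    exactly; curve points are (FPR, TPR) over the distinct score thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # curve: sweep thresholds from high to low
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = labels[order].astype(float)
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(1.0 - sorted_pos)
    # keep only the last point of each tied-score run
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    curve = pd.DataFrame(
        {
            "fpr": np.r_[0.0, fps[distinct] / n_neg],
            "tpr": np.r_[0.0, tps[distinct] / n_pos],
        }
    )
    return float(auc), curve


def _dunn_pairwise(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests with tie correction, Holm-adjusted."""
    ranks = stats.rankdata(values)
    n = len(values)
    labels = pd.unique(groups)
    # tie correction term for the common rank variance
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            ra = ranks[groups == a]
            rb = ranks[groups == b]
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term) * (1.0 / len(ra) + 1.0 / len(rb))
            )
            z = (ra.mean() - rb.mean()) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "statistic": z, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method="holm")[1]
    return out


@dataclass
class GroupContrastResult:
    summary: pd.DataFrame       # per-group n, mean, sd
    statistic: float            # ANOVA F or Kruskal-Wallis H
    p_value: float
    test: str                   # "anova" | "kruskal"
    pairwise: pd.DataFrame      # group_a, group_b, statistic, p_raw, p_adj


def group_contrast(
    values,
    groups,
    test: str = "anova",
) -> GroupContrastResult:
    """Omnibus group comparison with matched pairwise follow-up.

    ``anova`` pairs one-way ANOVA with Tukey's HSD; ``kruskal`` pairs
    Kruskal-Wallis with Dunn's test (Holm adjustment).  Degenerate data with
    zero between-group variance yields statistic 0 and p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    if len(labels) < 2 or any(len(s) < 2 for s in samples):
        raise ValidationError("need >= 2 groups with >= 2 samples each")
    summary = pd.DataFrame(
        {
            "group": labels,
            "n": [len(s) for s in samples],
            "mean": [s.mean() for s in samples],
            "sd": [s.std(ddof=1) for s in samples],
        }
    )
    degenerate = np.ptp(values) == 0
    if test == "anova":
        if degenerate:
            stat, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", stats.ConstantInputWarning)
                stat, p = stats.f_oneway(*samples)
            if np.isnan(stat):  # zero within-variance, equal means
                stat, p = 0.0, 1.0
            elif np.isinf(stat):  # zero within-variance, unequal means
                p = 0.0
        rows = []
        if degenerate:
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    rows.append(
                        {"group_a": labels[i], "group_b": labels[j],
                         "statistic": 0.0, "p_raw": 1.0, "p_adj": 1.0}
                    )
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                tk = stats.tukey_hsd(*samples)
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    rows.append(
                        {
                            "group_a": labels[i],
                            "group_b": labels[j],
                            "statistic": float(tk.statistic[i, j]),
                            "p_raw": float(tk.pvalue[i, j]),
                            "p_adj": float(tk.pvalue[i, j]),  # Tukey is family-wise already
                        }
                    )
        pairwise = pd.DataFrame(rows)
    elif test == "kruskal":
        if degenerate:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*samples)
        pairwise = _dunn_pairwise(values, groups)
    else:
        raise ValidationError(f"unknown test {test!r}")
    return GroupContrastResult(summary, float(stat), float(p), test, pairwise)
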