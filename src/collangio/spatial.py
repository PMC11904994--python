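"""Spatial proximity between annotated spot types.

The co-localization statistic is the nearest-neighbour Euclidean distance
from each source-type spot (endothelial by default) to the nearest spot of a
target type; distance distributions toward the reference type (fibroblast)
and toward other types are compared with a two-sided Mann-Whitney U test.
Mean pairwise distance is available behind a flag.  Samples are never pooled:
array coordinates are not comparable across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .errors import ValidationError

__all__ = [
    "nearest_type_distance",
    "colocalization_test",
    "multi_sample_summary",
    "ColocalizationResult",
]

REQUIRED_COLUMNS = ("spot_id", "x", "y", "cell_type")


def _check_spots(spots: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in spots.columns]
    if missing:
        raise ValidationError(f"spot table lacks columns {missing}")
    if not np.isfinite(spots[["x", "y"]].to_numpy(dtype=float)).all():
        raise ValidationError("spot coordinates must be finite")


def _coords(spots: pd.DataFrame, cell_type: str) -> np.ndarray:
    xy = spots.loc[spots["cell_type"] == cell_type, ["x", "y"]].to_numpy(dtype=float)
    if len(xy) == 0:
        raise ValidationError(f"no spots of type {cell_type!r}")
    return xy


def nearest_type_distance(
    spots: pd.DataFrame,
    source_type: str,
    target_type: str,
) -> np.ndarray:
    """Per source spot, the Euclidean distance to the nearest target spot.

    When source and target type coincide, the spot itself is excluded (so a
    duplicate coordinate yields distance 0 to the *other* spot, never to
    itself).
    """
    _check_spots(spots)
    src = _coords(spots, source_type)
    tgt = _coords(spots, target_type)
    tree = cKDTree(tgt)
    if source_type == target_type:
        if len(tgt) < 2:
            raise ValidationError(
                f"self-distance for {source_type!r} needs >= 2 spots"
            )
        d, idx = tree.query(src, k=2)
        # the spot itself appears among its own neighbours; skip it by index
        out = np.where(idx[:, 0] == np.arange(len(src)), d[:, 1], d[:, 0])
        return out
    d, _ = tree.query(src, k=1)
    return d


def _pooled_other_distance(
    spots: pd.DataFrame, source_type: str, reference_type: str
) -> np.ndarray:
    """Nearest distance from each source spot to any non-reference,
    non-source type."""
    mask = ~spots["cell_type"].isin([source_type, reference_type])
    tgt = spots.loc[mask, ["x", "y"]].to_numpy(dtype=float)
    if len(tgt) == 0:
        raise ValidationError("no non-reference spots to compare against")
    src = _coords(spots, source_type)
    d, _ = cKDTree(tgt).query(src, k=1)
    return d


def _mean_pairwise(spots: pd.DataFrame, source_type: str, target_type: str):
    src = _coords(spots, source_type)
    tgt = _coords(spots, target_type)
    diff = src[:, None, :] - tgt[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)).mean(axis=1)


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(np.r_[a, b]) == 0:  # complete ties, e.g. all spots coincide
        return float(len(a) * len(b) / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class ColocalizationResult:
    sample_id: str
    mode: str                      # "pooled" | "per-type"
    comparisons: pd.DataFrame      # other_type, n_*, medians, U, p


def colocalization_test(
    spots: pd.DataFrame,
    source_type: str = "endothelial",
    reference_type: str = "fibroblast",
    mode: str = "pooled",
    metric: str = "nearest",
    sample_id: str | None = None,
) -> ColocalizationResult:
    """Compare source->reference distances against source->other distances.

    ``pooled`` runs one test of D(source->reference) against the nearest
    distance to any non-reference type; ``per-type`` runs one test per other
    type.  ``metric='mean_pairwise'`` swaps nearest-neighbour distances for
    mean pairwise distances.
    """
    _check_spots(spots)
    if mode not in ("pooled", "per-type"):
        raise ValidationError(f"unknown mode {mode!r}")
    if metric not in ("nearest", "mean_pairwise"):
        raise ValidationError(f"unknown metric {metric!r}")
    if sample_id is None:
        sample_id = str(spots["sample_id"].iloc[0]) if "sample_id" in spots else "sample"

    dist = nearest_type_distance if metric == "nearest" else _mean_pairwise
    d_ref = dist(spots, source_type, reference_type)
    rows = []
    if mode == "pooled":
        if metric == "nearest":
            d_other = _pooled_other_distance(spots, source_type, reference_type)
        else:
            others = [
                t
                for t in spots["cell_type"].unique()
                if t not in (source_type, reference_type)
            ]
            if not others:
                raise ValidationError("no non-reference types present")
            d_other = np.concatenate([dist(spots, source_type, t) for t in others])
        if len(d_ref) < 3 or len(d_other) < 3:
            warnings.warn("fewer than 3 distances; comparison skipped", stacklevel=2)
        else:
            u, p = _mannwhitney(d_ref, d_other)
            rows.append(
                {
                    "other_type": "pooled_non_reference",
                    "n_ref": len(d_ref),
                    "n_other": len(d_other),
                    "median_ref": float(np.median(d_ref)),
                    "median_other": float(np.median(d_other)),
                    "u_statistic": u,
                    "p_value": p,
                }
            )
    else:
        others = [
            t
            for t in spots["cell_type"].unique()
            if t not in (source_type, reference_type)
        ]
        if not others:
            raise ValidationError("no non-reference types present")
        for t in others:
            d_t = dist(spots, source_type, t)
            if len(d_ref) < 3 or len(d_t) < 3:
                warnings.warn(
                    f"fewer than 3 distances for {t!r}; comparison skipped",
                    stacklevel=2,
                )
                continue
            u, p = _mannwhitney(d_ref, d_t)
            rows.append(
                {
                    "other_type": t,
                    "n_ref": len(d_ref),
                    "n_other": len(d_t),
                    "median_ref": float(np.median(d_ref)),
                    "median_other": float(np.median(d_t)),
                    "u_statistic": u,
                    "p_value": p,
                }
            )
    return ColocalizationResult(sample_id, mode, pd.DataFrame(rows))


def multi_sample_summary(
    samples: list[pd.DataFrame],
    source_type: str = "endothelial",
    reference_type: str = "fibroblast",
    mode: str = "pooled",
    metric: str = "nearest",
) -> pd.DataFrame:
    """Per-sample co-localization statistics; distances are never pooled
    across samples (array coordinates are not comparable between arrays)."""
    frames = []
    for i, spots in enumerate(samples):
        sid = (
            str(spots["sample_id"].iloc[0])
            if "sample_id" in spots and len(spots)
            else f"sample_{i}"
        )
        res = colocalization_test(
            spots,
            source_type=source_type,
            reference_type=reference_type,
            mode=mode,
            metric=metric,
            sample_id=sid,
        )
        df = res.comparisons.copy()
        df.insert(0, "sample_id", sid)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=[
                "sample_id",
                "other_type",
                "n_ref",
                "n_other",
                "median_ref",
                "median_other",
                "u_statistic",
                "p_value",
            ]
        )
    return pd.concat(frames, ignore_index=True)
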