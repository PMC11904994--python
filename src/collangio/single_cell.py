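"""Single-cell QC, dimensionality reduction, annotation and the
ligand-receptor label-permutation interaction test.

Cells are filtered on mitochondrial fraction and detected-gene count,
library-size normalised and log-transformed, reduced by PCA on the most
variable genes, clustered on a kNN graph (Leiden community detection, with a
seeded k-means fallback) and labelled by marker expression.  Intercellular
signalling between annotated types is then scored per ligand-receptor pair as
the mean of the ligand's mean expression in the source type and the
receptor's in the target type, with significance from permuting the cell-type
labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .errors import ValidationError

__all__ = [
    "LRPair",
    "compute_qc_metrics",
    "qc_filter",
    "normalize_reduce",
    "cluster_annotate",
    "lr_permutation_test",
]

MITO_PREFIX = "MT-"


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValidationError("ligand and receptor must both be named")


def _counts(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    return np.asarray(X)


def compute_qc_metrics(adata: ad.AnnData, mito_prefix: str = MITO_PREFIX) -> pd.DataFrame:
    """Recompute mito_fraction and n_detected_genes from the count matrix."""
    X = _counts(adata)
    if (X < 0).any():
        raise ValidationError("counts must be non-negative")
    total = X.sum(axis=1)
    mito = adata.var_names.str.startswith(mito_prefix)
    mito_counts = X[:, mito].sum(axis=1) if mito.any() else np.zeros(adata.n_obs)
    return pd.DataFrame(
        {
            "mito_fraction": np.divide(
                mito_counts, total, out=np.zeros(adata.n_obs, float), where=total > 0
            ),
            "n_detected_genes": (X > 0).sum(axis=1),
        },
        index=adata.obs_names,
    )


def qc_filter(
    adata: ad.AnnData,
    mito_max: float = 0.10,
    min_genes: int = 200,
    max_genes: int = 5000,
    mito_prefix: str = MITO_PREFIX,
) -> tuple[ad.AnnData, dict]:
    """Keep cells with mito fraction <= ``mito_max`` and detected genes in
    ``[min_genes, max_genes]`` (both bounds inclusive: only strict exceedance
    excludes a cell).  Returns the filtered table and a removal report.
    """
    qc = compute_qc_metrics(adata, mito_prefix=mito_prefix)
    high_mito = qc["mito_fraction"].to_numpy() > mito_max
    too_few = qc["n_detected_genes"].to_numpy() < min_genes
    too_many = qc["n_detected_genes"].to_numpy() > max_genes
    keep = ~(high_mito | too_few | too_many)
    report = {
        "n_input": int(adata.n_obs),
        "n_kept": int(keep.sum()),
        "removed_high_mito": int(high_mito.sum()),
        "removed_too_few_genes": int(too_few.sum()),
        "removed_too_many_genes": int(too_many.sum()),
    }
    out = adata[keep].copy()
    out.obs["mito_fraction"] = qc.loc[keep, "mito_fraction"].to_numpy()
    out.obs["n_detected_genes"] = qc.loc[keep, "n_detected_genes"].to_numpy()
    if out.n_obs == 0:
        warnings.warn("QC removed every cell", stacklevel=2)
    return out, report


def lognormalize(adata: ad.AnnData, target_sum: float = 1e4) -> np.ndarray:
    """Library-size normalise each cell to ``target_sum`` and log1p."""
    X = _counts(adata).astype(float)
    total = X.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return np.log1p(X / total * target_sum)


def normalize_reduce(
    adata: ad.AnnData,
    n_hvg: int = 4000,
    n_pcs: int = 40,
    target_sum: float = 1e4,
    batch_center: bool = False,
    batch_key: str = "batch",
) -> np.ndarray:
    """Log-normalise, select highly variable genes and run PCA.

    Genes are ranked by variance of the log-normalised values and the top
    ``n_hvg`` kept; the centred submatrix is projected onto the first
    ``n_pcs`` principal components.  ``batch_center`` subtracts each batch's
    mean from the embedding afterwards — a deliberately simple surrogate for
    iterative batch-integration methods.  The embedding is also stored in
    ``adata.obsm['X_pca']`` and the log matrix in ``adata.layers['lognorm']``.
    """
    logX = lognormalize(adata, target_sum=target_sum)
    adata.layers["lognorm"] = logX
    n_hvg = min(n_hvg, adata.n_vars)
    max_pcs = min(adata.n_obs, n_hvg)
    if n_pcs > max_pcs:
        warnings.warn(
            f"n_pcs reduced from {n_pcs} to {max_pcs} (too few cells/genes)",
            stacklevel=2,
        )
        n_pcs = max_pcs
    var = logX.var(axis=0)
    hvg_idx = np.sort(np.argsort(-var, kind="stable")[:n_hvg])
    adata.var["highly_variable"] = False
    adata.var.iloc[
        hvg_idx, adata.var.columns.get_loc("highly_variable")
    ] = True
    sub = logX[:, hvg_idx]
    sub = sub - sub.mean(axis=0, keepdims=True)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    emb = pca.fit_transform(sub)
    if batch_center:
        if batch_key not in adata.obs:
            raise ValidationError(f"no {batch_key!r} column for batch centering")
        for b in adata.obs[batch_key].unique():
            mask = (adata.obs[batch_key] == b).to_numpy()
            emb[mask] -= emb[mask].mean(axis=0, keepdims=True)
    adata.obsm["X_pca"] = emb
    adata.uns["pca_explained_variance_ratio"] = pca.explained_variance_ratio_
    return emb


def _leiden_labels(
    emb: np.ndarray, n_neighbors: int, resolution: float, seed: int
) -> np.ndarray:
    import igraph
    import leidenalg

    n_neighbors = min(n_neighbors, emb.shape[0] - 1)
    knn = kneighbors_graph(emb, n_neighbors=n_neighbors, mode="connectivity")
    sources, targets = knn.nonzero()
    g = igraph.Graph(
        n=emb.shape[0], edges=list(zip(sources.tolist(), targets.tolist()))
    )
    g.simplify()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


def cluster_annotate(
    embedding: np.ndarray,
    adata: ad.AnnData,
    markers: dict[str, list[str]],
    method: str = "leiden",
    n_neighbors: int = 15,
    resolution: float = 1.0,
    k: int | None = None,
    seed: int = 0,
) -> pd.Series:
    """Cluster the embedding and label clusters by marker expression.

    Each cluster receives the cell type whose marker list has the highest mean
    z-scored (across cells) log-normalised expression in that cluster; ties
    break lexicographically with a warning.  ``k=1`` degenerates to a single
    cluster labelled by the overall argmax type.  Labels are written to
    ``adata.obs['cell_type']``.
    """
    if embedding.shape[0] != adata.n_obs:
        raise ValidationError("embedding and cell table disagree on cell count")
    if "lognorm" in adata.layers:
        logX = np.asarray(adata.layers["lognorm"])
    else:
        logX = lognormalize(adata)
    usable: dict[str, list[int]] = {}
    for ctype, genes in markers.items():
        idx = [adata.var_names.get_loc(g) for g in genes if g in adata.var_names]
        if not idx:
            warnings.warn(
                f"no marker genes of {ctype!r} in matrix; type skipped",
                stacklevel=2,
            )
            continue
        usable[ctype] = idx
    if not usable:
        raise ValidationError("no marker genes found for any cell type")

    if k == 1:
        clusters = np.zeros(adata.n_obs, dtype=int)
    elif method == "kmeans" or k is not None:
        kk = k if k is not None else 8
        clusters = KMeans(n_clusters=kk, random_state=seed, n_init=10).fit_predict(
            embedding
        )
    elif method == "leiden":
        clusters = _leiden_labels(embedding, n_neighbors, resolution, seed)
    else:
        raise ValidationError(f"unknown clustering method {method!r}")

    mu = logX.mean(axis=0)
    sd = logX.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (logX - mu) / sd
    types = sorted(usable)  # lexicographic order makes ties deterministic
    labels = np.empty(adata.n_obs, dtype=object)
    for c in np.unique(clusters):
        mask = clusters == c
        scores = np.array([Z[np.ix_(mask, usable[t])].mean() for t in types])
        best = np.flatnonzero(scores == scores.max())
        if len(best) > 1:
            warnings.warn(
                f"marker-score tie in cluster {c}; broken lexicographically",
                stacklevel=2,
            )
        labels[mask] = types[best[0]]
    out = pd.Series(labels, index=adata.obs_names, name="cell_type")
    adata.obs["cell_type"] = out
    adata.obs["cluster"] = clusters
    return out


def lr_permutation_test(
    adata: ad.AnnData,
    pairs: list[LRPair],
    cell_type_key: str = "cell_type",
    n_perm: int = 1000,
    seed: int = 0,
    expressed_fraction_min: float = 0.10,
    alpha: float = 0.05,
    include_self: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ligand-receptor interaction test by cell-type label permutation.

    For each ordered type pair (A, B) and each (ligand, receptor) pair the
    score is ``0.5 * (mean ligand in A + mean receptor in B)`` on
    log-normalised expression.  If either gene is expressed in fewer than
    ``expressed_fraction_min`` of its cluster the score is set to 0 with
    p = 1.  The null permutes the cell-type labels ``n_perm`` times; the
    p-value is the add-one estimate ``(1 + #{null >= observed}) / (1 +
    n_perm)``.  Returns the per-pair results and the significant-pair count
    matrix over ordered type pairs.
    """
    if cell_type_key not in adata.obs:
        raise ValidationError(f"no {cell_type_key!r} labels on the cell table")
    labels = adata.obs[cell_type_key].to_numpy()
    types = sorted(pd.unique(labels))
    if len(types) < 2:
        raise ValidationError("need >= 2 cell types")
    if "lognorm" in adata.layers:
        logX = np.asarray(adata.layers["lognorm"])
    else:
        logX = lognormalize(adata)

    kept: list[LRPair] = []
    gene_idx: dict[str, int] = {}
    for pair in pairs:
        if pair.ligand in adata.var_names and pair.receptor in adata.var_names:
            kept.append(pair)
            gene_idx[pair.ligand] = adata.var_names.get_loc(pair.ligand)
            gene_idx[pair.receptor] = adata.var_names.get_loc(pair.receptor)
        else:
            warnings.warn(
                f"pair {pair.ligand}->{pair.receptor} skipped: gene absent",
                stacklevel=2,
            )
    if not kept:
        raise ValidationError("no ligand-receptor pair has both genes in the matrix")
    genes = sorted(gene_idx)
    gcol = {g: i for i, g in enumerate(genes)}
    E = logX[:, [gene_idx[g] for g in genes]]  # cells x used genes

    # canonical cell order (by cell ID) so results do not depend on row order
    canon = np.argsort(adata.obs_names.to_numpy(), kind="stable")
    labels = labels[canon]
    E = E[canon]

    type_rows = {t: np.flatnonzero(labels == t) for t in types}
    onehot = np.zeros((len(types), adata.n_obs))
    for i, t in enumerate(types):
        onehot[i, type_rows[t]] = 1.0 / len(type_rows[t])
    obs_means = onehot @ E  # types x genes
    expr_frac = np.vstack(
        [(E[type_rows[t]] > 0).mean(axis=0) for t in types]
    )

    rng = np.random.default_rng(seed)
    # null type-mean tensor: n_perm x types x genes
    null_means = np.empty((n_perm, len(types), len(genes)))
    for b in range(n_perm):
        perm = rng.permutation(adata.n_obs)
        null_means[b] = onehot[:, perm] @ E

    ordered = [
        (a, bb)
        for a in types
        for bb in types
        if include_self or a != bb
    ]
    t_index = {t: i for i, t in enumerate(types)}
    rows = []
    counts = pd.DataFrame(0, index=types, columns=types)
    for src, tgt in ordered:
        ia, ib = t_index[src], t_index[tgt]
        for pair in kept:
            jl, jr = gcol[pair.ligand], gcol[pair.receptor]
            gated = (
                expr_frac[ia, jl] < expressed_fraction_min
                or expr_frac[ib, jr] < expressed_fraction_min
            )
            if gated:
                score, p, sig = 0.0, 1.0, False
            else:
                score = 0.5 * (obs_means[ia, jl] + obs_means[ib, jr])
                null = 0.5 * (null_means[:, ia, jl] + null_means[:, ib, jr])
                p = (1 + int((null >= score).sum())) / (1 + n_perm)
                sig = p < alpha
            if sig:
                counts.loc[src, tgt] += 1
            rows.append(
                {
                    "source": src,
                    "target": tgt,
                    "ligand": pair.ligand,
                    "receptor": pair.receptor,
                    "score": score,
                    "p_value": p,
                    "significant": sig,
                }
            )
    return pd.DataFrame(rows), counts
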