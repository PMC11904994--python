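"""Readers and writers for the plain-text formats the pipeline touches.

GMT gene-set collections, genes-by-samples expression TSV, MatrixMarket
triplet directories for single-cell counts, spot/survival/histology CSV, and
CSV outputs with provenance comment headers.  All readers reject malformed
input with located errors; all writers round-trip.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .errors import ValidationError
from .scoring import GeneSet

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_mtx_dir",
    "write_mtx_dir",
    "read_csv_table",
    "write_csv_with_provenance",
    "read_lr_pairs",
]


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: tab-separated name, description, genes...

    Duplicate genes within a set are deduplicated (order-preserving) with a
    warning; a line without at least one gene is an error naming the line.
    """
    sets: list[GeneSet] = []
    text = Path(path).read_text()
    if not text.strip():
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
        return sets
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
            )
        name = fields[0]
        genes = [g for g in fields[2:] if g]
        if not genes:
            raise ValidationError(f"{path}:{lineno}: set {name!r} has no genes")
        unique = list(dict.fromkeys(genes))
        if len(unique) != len(genes):
            warnings.warn(
                f"{path}:{lineno}: duplicate genes in set {name!r} deduplicated",
                stacklevel=2,
            )
        sets.append(GeneSet(name, tuple(unique)))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    lines = [
        "\t".join([s.name, "na", *s.genes]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_tsv(path, collapse_duplicates: bool = False) -> pd.DataFrame:
    """Genes-by-samples TSV: first column gene ID, header sample IDs.

    Duplicate gene IDs are an error unless ``collapse_duplicates`` collapses
    them by row-wise max; non-numeric cells raise with their coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise ValidationError(
                f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
        if converted.isna().any():
            gene = df.index[converted.isna().to_numpy()][0]
            raise ValidationError(
                f"{path}: missing value at gene {gene!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy()
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    if out.index.duplicated().any():
        if not collapse_duplicates:
            dups = out.index[out.index.duplicated()].unique().tolist()[:5]
            raise ValidationError(f"{path}: duplicate gene IDs {dups}")
        out = out.groupby(level=0).max()
    return out


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_mtx_dir(path) -> ad.AnnData:
    """Read an MTX triplet directory (matrix.mtx genes x cells, features.tsv,
    barcodes.tsv) into a cells x genes AnnData.  Indices on disk are 1-based
    per the MatrixMarket standard; in memory everything is 0-based.
    """
    path = Path(path)
    M = scipy_io.mmread(path / "matrix.mtx").tocsr()
    features = [
        line.split("\t")[0]
        for line in (path / "features.tsv").read_text().splitlines()
        if line.strip()
    ]
    barcodes = [
        line.strip()
        for line in (path / "barcodes.tsv").read_text().splitlines()
        if line.strip()
    ]
    if M.shape != (len(features), len(barcodes)):
        raise ValidationError(
            f"{path}: matrix is {M.shape} but sidecars declare "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    return ad.AnnData(
        X=M.T.toarray().astype(np.int64),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(features, name="gene_id")),
    )


def write_mtx_dir(adata: ad.AnnData, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    scipy_io.mmwrite(
        path / "matrix.mtx", sparse.coo_matrix(np.asarray(X).T.astype(np.int64))
    )
    (path / "features.tsv").write_text("\n".join(adata.var_names) + "\n")
    (path / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")


def read_csv_table(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def write_csv_with_provenance(df: pd.DataFrame, path, seed=None, params=None,
                              index: bool = False) -> None:
    """CSV output with '#'-prefixed provenance header lines (standard parsers
    that honour comment lines still read the file)."""
    from . import __version__

    header = [f"# collangio {__version__}"]
    if seed is not None:
        header.append(f"# seed: {seed}")
    for k, v in (params or {}).items():
        header.append(f"# {k}: {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=index)


def read_lr_pairs(path):
    """CellPhoneDB-style pair table: columns ligand, receptor[, annotation]."""
    from .single_cell import LRPair

    df = read_csv_table(path, required=("ligand", "receptor"))
    pairs = []
    seen = set()
    for row in df.itertuples(index=False):
        key = (row.ligand, row.receptor)
        if key in seen:
            raise ValidationError(f"{path}: duplicate pair {key}")
        seen.add(key)
        pairs.append(
            LRPair(row.ligand, row.receptor,
                   getattr(row, "annotation", "") or "")
        )
    return pairs
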