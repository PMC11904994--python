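"""Synthetic cohorts with planted ground truth for every pipeline stage.

Four generators emulate the statistical structure the analyses assume:

* a bulk log2-expression cohort with three planted microenvironment subtypes
  in which collagen-program and angiogenesis-program expression covary;
* a single-cell count matrix with labelled cell types, a planted
  mitochondrial-fraction / detected-genes QC structure and planted
  fibroblast-ligand -> endothelial-receptor pairs;
* spatial spot fields where endothelial spots scatter around fibroblast
  anchors;
* exponential survival times with a planted hazard difference between
  marker-high and marker-low groups.

All generators are deterministic given their seed and return ordinary
pandas / AnnData objects plus the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .scoring import GeneSet, ReferenceProfiles

__all__ = [
    "BulkSimConfig",
    "SCSimConfig",
    "SpatialSimConfig",
    "SurvSimConfig",
    "gen_bulk_cohort",
    "gen_sc_dataset",
    "gen_spatial_sample",
    "gen_survival",
    "program_gene_sets",
    "reference_profiles_from_blocks",
]

# gene-block sizes of the bulk design; the angiogenesis program is split into
# four pathway-like subsets plus an endothelial marker set so that the six
# composite features are all scoreable on generated data
_COLLAGEN_N = 40
_IMMUNE_N = 40
_ANGIO_SETS = (
    "ANGIO_HALLMARK",
    "ANGIO_WP",
    "ANGIO_BIOCARTA_VEGF",
    "ANGIO_WP_VEGFA_VEGFR2",
    "ENDOTHELIAL_MARKERS",
)
_ANGIO_PER_SET = 12
_MIN_BULK_GENES = _COLLAGEN_N + _IMMUNE_N + len(_ANGIO_SETS) * _ANGIO_PER_SET + 20

SUBTYPE_ORDER = ("quiescent", "armored_cold", "soft_hot")


@dataclass
class BulkSimConfig:
    """Bulk cohort on log2 scale with three planted subtypes.

    ``collagen_effect`` is the log2 shift added to collagen-program genes in
    armored_cold samples; ``immune_effect`` likewise for immune-program genes
    in soft_hot samples; ``angio_coupling`` scales the per-sample collagen
    activity into a shift of the angiogenesis-program genes, planting the
    collagen-angiogenesis correlation as a tunable quantity.
    """

    n_samples: int = 400
    n_genes: int = 1000
    subtype_proportions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    collagen_effect: float = 4.0
    immune_effect: float = 4.0
    angio_coupling: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_genes < _MIN_BULK_GENES:
            raise ConfigurationError(
                f"need n_samples >= 1 and n_genes >= {_MIN_BULK_GENES}"
            )
        p = np.asarray(self.subtype_proportions, dtype=float)
        if len(p) != 3 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "subtype_proportions must be a 3-vector of non-negative "
                "values summing to 1"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def _bulk_blocks(n_genes: int) -> dict[str, list[str]]:
    blocks: dict[str, list[str]] = {}
    blocks["COLLAGEN_PROGRAM"] = [f"COL_{i:04d}" for i in range(_COLLAGEN_N)]
    blocks["IMMUNE_PROGRAM"] = [f"IMM_{i:04d}" for i in range(_IMMUNE_N)]
    for s, name in enumerate(_ANGIO_SETS):
        blocks[name] = [f"ANG{s}_{i:04d}" for i in range(_ANGIO_PER_SET)]
    n_bg = n_genes - _COLLAGEN_N - _IMMUNE_N - len(_ANGIO_SETS) * _ANGIO_PER_SET
    blocks["BACKGROUND"] = [f"BG_{i:04d}" for i in range(n_bg)]
    return blocks


def program_gene_sets(blocks: dict[str, list[str]]) -> list[GeneSet]:
    """Planted program blocks as scoreable gene sets (background excluded)."""
    return [
        GeneSet(name, tuple(genes))
        for name, genes in blocks.items()
        if name != "BACKGROUND"
    ]


def gen_bulk_cohort(
    config: BulkSimConfig,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Generate a genes x samples log2 matrix with planted subtype structure.

    Returns ``(expr, labels, blocks)`` where ``labels`` holds the true subtype
    per sample and ``blocks`` the gene-block membership.  Per sample, the
    latent collagen activity is ``collagen_effect`` for armored_cold samples
    plus Gaussian sample-level variability (sd = ``noise_sd``); collagen genes
    shift by that activity and angiogenesis genes by ``angio_coupling`` times
    it, so the collagen-angiogenesis correlation is planted and continuous.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    blocks = _bulk_blocks(config.n_genes)
    gene_ids = [g for genes in blocks.values() for g in genes]
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    labels = pd.Series(
        rng.choice(SUBTYPE_ORDER, size=config.n_samples,
                   p=list(config.subtype_proportions)),
        index=samples,
        name="subtype",
    )
    base = rng.uniform(4.0, 8.0, size=len(gene_ids))
    X = base[:, None] + rng.normal(0.0, config.noise_sd,
                                   size=(len(gene_ids), config.n_samples))
    is_armored = (labels == "armored_cold").to_numpy()
    is_soft = (labels == "soft_hot").to_numpy()
    collagen_activity = (
        config.collagen_effect * is_armored
        + config.noise_sd * rng.normal(size=config.n_samples)
    )
    gene_index = pd.Index(gene_ids)
    col_rows = gene_index.isin(blocks["COLLAGEN_PROGRAM"])
    imm_rows = gene_index.isin(blocks["IMMUNE_PROGRAM"])
    angio_genes = [g for name in _ANGIO_SETS for g in blocks[name]]
    ang_rows = gene_index.isin(angio_genes)
    X[col_rows] += collagen_activity[None, :]
    X[imm_rows] += config.immune_effect * is_soft[None, :]
    X[ang_rows] += config.angio_coupling * collagen_activity[None, :]
    expr = pd.DataFrame(X, index=gene_index, columns=samples)
    return expr, labels, blocks


def reference_profiles_from_blocks(
    blocks: dict[str, list[str]],
    marker_level: float = 100.0,
    baseline: float = 5.0,
) -> ReferenceProfiles:
    """Linear-scale reference profiles matched to the bulk gene blocks.

    Three idealised types: endothelial (high on the endothelial marker set),
    fibroblast (high on the collagen program) and immune (high on the immune
    program); all types sit at ``baseline`` elsewhere.
    """
    gene_ids = [g for genes in blocks.values() for g in genes]
    prof = pd.DataFrame(
        baseline,
        index=pd.Index(gene_ids),
        columns=["endothelial", "fibroblast", "immune"],
        dtype=float,
    )
    prof.loc[blocks["ENDOTHELIAL_MARKERS"], "endothelial"] = marker_level
    prof.loc[blocks["COLLAGEN_PROGRAM"], "fibroblast"] = marker_level
    prof.loc[blocks["IMMUNE_PROGRAM"], "immune"] = marker_level
    return ReferenceProfiles(prof)


@dataclass
class SCSimConfig:
    """Single-cell negative-binomial counts with planted structure.

    Each cell type gets a block of ``markers_per_type`` marker genes at mean
    ``nb_mean``; all genes elsewhere sit at ``background_mean``.
    ``nb_dispersion`` is the NB size (shape) parameter, so the per-gene
    variance is ``m + m**2 / dispersion``.  ``planted_lr_pairs`` are tuples
    ``(ligand, receptor, source_type, target_type, effect)``: the ligand gene
    is elevated to mean ``effect`` only in the source type, the receptor only
    in the target type.  Mitochondrial genes carry the ``MT-`` prefix so the
    mitochondrial fraction is recomputable from the matrix itself.
    """

    cells_per_type: dict[str, int] = field(
        default_factory=lambda: {"fibroblast": 200, "endothelial": 200,
                                 "immune": 200, "epithelial": 200}
    )
    nb_mean: float = 20.0
    nb_dispersion: float = 2.0
    background_mean: float = 1.0
    lr_background_mean: float = 0.02
    markers_per_type: int = 20
    n_background_genes: int = 100
    n_mito_genes: int = 10
    mito_fraction_dist: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_mito: tuple[float, float] = (0.05, 0.02)
    planted_lr_pairs: list[tuple[str, str, str, str, float]] = field(
        default_factory=list
    )
    n_batches: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not self.cells_per_type:
            raise ConfigurationError("cells_per_type must not be empty")
        if any(n < 0 for n in self.cells_per_type.values()):
            raise ConfigurationError("cell counts must be >= 0")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        for t, (m, s) in {**{"_default": self.default_mito},
                          **self.mito_fraction_dist}.items():
            if not 0.0 <= m <= 1.0 or s < 0:
                raise ConfigurationError(
                    f"mito fraction mean for {t!r} must be in [0,1], sd >= 0"
                )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float):
    """Negative binomial via gamma-Poisson mixing; exact for mean 0."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(size_param, mean / size_param, size=mean.shape)
    return rng.poisson(lam)


def gen_sc_dataset(config: SCSimConfig) -> ad.AnnData:
    """Generate an annotated single-cell count matrix.

    Returns an AnnData with integer counts in ``X`` and per-cell ``batch``,
    ``cell_type_true``, ``mito_fraction`` and ``n_detected_genes`` in ``obs``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    types = list(config.cells_per_type)
    marker_genes = {
        t: [f"{t.upper()}_MK_{i:03d}" for i in range(config.markers_per_type)]
        for t in types
    }
    lr_genes: list[str] = []
    for lig, rec, src, tgt, _ in config.planted_lr_pairs:
        if src not in types or tgt not in types:
            raise ConfigurationError(
                f"planted pair references unknown cell type: {src!r}/{tgt!r}"
            )
        for g in (lig, rec):
            if g not in lr_genes:
                lr_genes.append(g)
    bg_genes = [f"BG_{i:03d}" for i in range(config.n_background_genes)]
    mito_genes = [f"MT-{i:02d}" for i in range(config.n_mito_genes)]
    gene_ids = (
        [g for t in types for g in marker_genes[t]] + lr_genes + bg_genes + mito_genes
    )
    n_cells = sum(config.cells_per_type.values())
    n_genes = len(gene_ids)
    gene_index = pd.Index(gene_ids)

    # per-type mean vector over non-mito genes
    mito_mask = gene_index.str.startswith("MT-")
    means_by_type: dict[str, np.ndarray] = {}
    for t in types:
        mu = np.full(n_genes, config.background_mean, dtype=float)
        mu[gene_index.isin(marker_genes[t])] = config.nb_mean
        # ligand/receptor genes are near-silent outside their planted type,
        # as the expressed-fraction gate of the interaction test assumes
        mu[gene_index.isin(lr_genes)] = config.lr_background_mean
        for lig, rec, src, tgt, effect in config.planted_lr_pairs:
            if src == t:
                mu[gene_index.get_loc(lig)] = effect
            if tgt == t:
                mu[gene_index.get_loc(rec)] = effect
        mu[mito_mask] = 0.0  # mito means set per cell below
        means_by_type[t] = mu

    X = np.zeros((n_cells, n_genes), dtype=np.int64)
    cell_types: list[str] = []
    row = 0
    for t in types:
        n_t = config.cells_per_type[t]
        if n_t == 0:
            continue
        mu = means_by_type[t]
        mito_mean, mito_sd = config.mito_fraction_dist.get(t, config.default_mito)
        target_f = np.clip(
            rng.normal(mito_mean, mito_sd, size=n_t), 0.0, 0.9
        )
        nonmito_total = mu.sum()
        for c in range(n_t):
            counts = _nb_draw(rng, mu, config.nb_dispersion)
            f = target_f[c]
            if f > 0 and config.n_mito_genes > 0:
                per_gene = f / (1.0 - f) * nonmito_total / config.n_mito_genes
                counts[mito_mask] = _nb_draw(
                    rng,
                    np.full(config.n_mito_genes, per_gene),
                    config.nb_dispersion,
                )
            X[row] = counts
            row += 1
            cell_types.append(t)

    total = X.sum(axis=1)
    mito_counts = X[:, mito_mask].sum(axis=1)
    obs = pd.DataFrame(
        {
            "batch": [f"b{i % config.n_batches}" for i in range(n_cells)],
            "cell_type_true": cell_types,
            "mito_fraction": np.divide(
                mito_counts, total, out=np.zeros(n_cells, float), where=total > 0
            ),
            "n_detected_genes": (X > 0).sum(axis=1),
        },
        index=[f"cell_{i:05d}" for i in range(n_cells)],
    )
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=gene_index))
    adata.uns["marker_genes"] = {t: list(g) for t, g in marker_genes.items()}
    adata.uns["planted_lr_pairs"] = [list(p) for p in config.planted_lr_pairs]
    return adata


@dataclass
class SpatialSimConfig:
    """Spot field with endothelial spots scattered around fibroblast anchors.

    ``coloc_sd`` is the sd of the isotropic Gaussian displacement of each
    endothelial spot around a uniformly chosen fibroblast anchor; ``None``
    (or infinity) places endothelial spots uniformly, encoding the null of no
    co-localization.
    """

    n_fibro: int = 60
    n_endo: int = 60
    n_other: int = 80
    other_types: tuple[str, ...] = ("immune", "epithelial")
    field_size: float = 100.0
    coloc_sd: float | None = 2.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_fibro, self.n_endo, self.n_other) < 0:
            raise ConfigurationError("spot counts must be >= 0")
        if self.field_size <= 0:
            raise ConfigurationError("field_size must be > 0")
        if self.coloc_sd is not None and not (
            self.coloc_sd > 0 or np.isinf(self.coloc_sd)
        ):
            raise ConfigurationError("coloc_sd must be > 0, infinite, or None")
        if self.uniform is False and self.n_fibro == 0 and self.n_endo > 0:
            raise ConfigurationError("co-localized placement needs >= 1 fibroblast")

    @property
    def uniform(self) -> bool:
        return self.coloc_sd is None or np.isinf(self.coloc_sd)


def gen_spatial_sample(config: SpatialSimConfig, sample_id: str = "sample_0") -> pd.DataFrame:
    """One spatial sample: columns sample_id, spot_id, x, y, cell_type."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.field_size
    rows = []
    fibro_xy = rng.uniform(0.0, L, size=(config.n_fibro, 2))
    for i, (x, y) in enumerate(fibro_xy):
        rows.append(("fibroblast", x, y))
    if config.uniform:
        endo_xy = rng.uniform(0.0, L, size=(config.n_endo, 2))
    else:
        anchors = fibro_xy[rng.integers(0, config.n_fibro, size=config.n_endo)]
        endo_xy = np.clip(
            anchors + rng.normal(0.0, config.coloc_sd, size=(config.n_endo, 2)),
            0.0,
            L,
        )
    for x, y in endo_xy:
        rows.append(("endothelial", x, y))
    other_xy = rng.uniform(0.0, L, size=(config.n_other, 2))
    other_labels = [
        config.other_types[i % len(config.other_types)] for i in range(config.n_other)
    ]
    for lab, (x, y) in zip(other_labels, other_xy):
        rows.append((lab, x, y))
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "spot_id": [f"{sample_id}_spot_{i:04d}" for i in range(len(rows))],
            "x": [r[1] for r in rows],
            "y": [r[2] for r in rows],
            "cell_type": [r[0] for r in rows],
        }
    )


@dataclass
class SurvSimConfig:
    """Exponential survival with independent exponential censoring."""

    n_per_group: int = 100
    hazard_low: float = 0.05
    hazard_high: float = 0.20
    censor_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        if self.hazard_low <= 0 or self.hazard_high <= 0:
            raise ConfigurationError("hazard rates must be > 0")
        if self.censor_rate < 0:
            raise ConfigurationError("censor_rate must be >= 0")


def gen_survival(config: SurvSimConfig) -> pd.DataFrame:
    """Survival table: columns subject_id, time, event, group (low/high)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for group, hazard in (("low", config.hazard_low), ("high", config.hazard_high)):
        t_event = rng.exponential(1.0 / hazard, size=config.n_per_group)
        if config.censor_rate > 0:
            t_cens = rng.exponential(1.0 / config.censor_rate,
                                     size=config.n_per_group)
        else:
            t_cens = np.full(config.n_per_group, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        for i in range(config.n_per_group):
            rows.append((f"{group}_{i:04d}", time[i], event[i], group))
    return pd.DataFrame(rows, columns=["subject_id", "time", "event", "group"])
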