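"""Synthetic data generators: reference bundles, bulk mixtures with known
fractions, and labeled single-cell sets with pseudo-bulk construction.

Everything here is synthetic and exists so the estimator can be exercised
end to end with a known ground truth: reference bundles with planted
markers (optionally shared between designated type pairs, and optionally
diluted with non-specific "decoy" markers), bulk mixtures built as
fraction-weighted averages of the reference profiles plus log-scale noise,
and single-cell sets whose pseudo-bulk aggregation carries exact per-type
cell fractions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    IMMUNE_CELL_TYPES,
    IMMUNE_HIERARCHY,
    T_CELL_SUBSETS,
    CellTypeHierarchy,
    ExpressionMatrix,
    ReferenceBundle,
    ValidationError,
)

__all__ = [
    "SyntheticBundleSpec",
    "SingleCellSet",
    "generate_bundle",
    "default_bundle",
    "random_fractions",
    "generate_mixture",
    "generate_single_cells",
    "normalize_single_cells",
    "pseudobulk",
]


@dataclass(frozen=True)
class SyntheticBundleSpec:
    """Recipe for a synthetic reference bundle.

    Reference values are arbitrary log-like intensities: each gene gets a
    background level drawn from ``background_level``; a marker's value in
    the type(s) it marks is ``marker_fold`` times its background. Decoy
    genes are listed in signatures but have flat profiles (no elevation),
    so a sound marker-selection procedure must discard them. Background
    genes are extra rows carried by ``rt`` without any signature
    membership; they populate mixtures but never enter the scoring
    universe.
    """

    n_cell_types: int = 24
    n_marker_per_type: int = 15
    n_decoy_per_type: int = 0
    n_background_genes: int = 0
    marker_fold: float = 8.0
    overlap_fraction: float = 0.0
    overlap_pairs: Optional[Tuple[Tuple[int, int], ...]] = None
    noise_sd: float = 0.25
    background_level: Tuple[float, float] = (4.0, 6.0)
    cell_type_names: Optional[Tuple[str, ...]] = None
    hierarchy: Optional[CellTypeHierarchy] = None
    t_subsets: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self):
        if self.n_cell_types < 1 or self.n_marker_per_type < 1:
            raise ValidationError("counts must be >= 1")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValidationError("overlap_fraction must be in [0, 1)")
        if self.cell_type_names is not None and len(self.cell_type_names) != self.n_cell_types:
            raise ValidationError("cell_type_names length must equal n_cell_types")


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "", name).upper() or "CT"


@dataclass
class SingleCellSet:
    """Per-cell expression with type labels and sample grouping.

    ``expression`` is genes x cells (TPM-like, non-negative before
    normalisation); ``labels`` maps cell barcode -> cell type; ``groups``
    maps cell barcode -> sample/patient id; ``housekeeping`` lists the
    genes used for cross-cell scaling.
    """

    expression: pd.DataFrame
    labels: pd.Series
    groups: pd.Series
    housekeeping: List[str]
    normalized: bool = False


def generate_bundle(spec: SyntheticBundleSpec) -> ReferenceBundle:
    """Deterministically generate a validated synthetic reference bundle."""
    rng = np.random.default_rng(spec.seed)
    names = list(
        spec.cell_type_names
        if spec.cell_type_names is not None
        else (f"CT{i + 1:02d}" for i in range(spec.n_cell_types))
    )
    slugs = [_slug(n) for n in names]
    if len(set(slugs)) != len(slugs):
        slugs = [f"{s}{i:02d}" for i, s in enumerate(slugs)]

    genes: List[str] = []
    owners: Dict[str, List[int]] = {}
    signatures: Dict[str, List[str]] = {n: [] for n in names}
    for i, name in enumerate(names):
        for k in range(spec.n_marker_per_type):
            g = f"{slugs[i]}.M{k + 1:02d}"
            genes.append(g)
            owners[g] = [i]
            signatures[name].append(g)
    # shared markers between designated pairs
    n_shared = int(round(spec.overlap_fraction * spec.n_marker_per_type))
    if n_shared > 0:
        pairs = spec.overlap_pairs
        if pairs is None:
            pairs = tuple(
                (i, i + 1) for i in range(0, spec.n_cell_types - 1, 2)
            )
        for a, b in pairs:
            if not (0 <= a < spec.n_cell_types and 0 <= b < spec.n_cell_types):
                raise ValidationError(f"overlap pair ({a}, {b}) out of range")
            if n_shared > spec.n_marker_per_type:
                raise ValidationError("shared markers exceed the per-type pool")
            for g in signatures[names[a]][:n_shared]:
                owners[g].append(b)
                signatures[names[b]].append(g)
    for i, name in enumerate(names):
        for k in range(spec.n_decoy_per_type):
            g = f"{slugs[i]}.D{k + 1:02d}"
            genes.append(g)
            signatures[name].append(g)
            owners[g] = ("decoy", i)  # signature member, flat profile
    background = [f"BG{k + 1:04d}" for k in range(spec.n_background_genes)]
    all_genes = genes + background

    base = rng.uniform(*spec.background_level, size=len(all_genes))
    rt = np.tile(base[:, None], (1, len(names)))
    st = np.zeros((len(all_genes), len(names)))
    for row, g in enumerate(genes):
        own = owners[g]
        if isinstance(own, tuple):  # decoy: signature member, flat profile
            st[row, own[1]] = 1.0
        else:
            for j in own:
                rt[row, j] = spec.marker_fold * base[row]
                st[row, j] = 1.0
    if spec.noise_sd > 0:
        rt = rt + rng.normal(0.0, spec.noise_sd, size=rt.shape)
    rt = np.clip(rt, 0.0, None)

    hierarchy = spec.hierarchy or CellTypeHierarchy()
    return ReferenceBundle(
        cell_types=names,
        rt=pd.DataFrame(rt, index=all_genes, columns=names),
        st=pd.DataFrame(st, index=all_genes, columns=names),
        signatures=signatures,
        hierarchy=hierarchy,
        t_subsets=frozenset(spec.t_subsets),
    )


def default_bundle(seed: int = 0, **overrides) -> ReferenceBundle:
    """The shipped default bundle: a synthetic 24-type immune reference.

    Carries the full immune ontology (24 types, 18 T-cell subsets, CD4/CD8
    parent -> subset hierarchy) over synthetic reference profiles, so the
    tool is runnable and testable without any external data. A curated
    bundle with real profiles can be dropped in via the same container.
    """
    spec = SyntheticBundleSpec(
        n_cell_types=len(IMMUNE_CELL_TYPES),
        cell_type_names=tuple(IMMUNE_CELL_TYPES),
        hierarchy=IMMUNE_HIERARCHY,
        t_subsets=T_CELL_SUBSETS,
        seed=seed,
        **overrides,
    )
    return generate_bundle(spec)


def random_fractions(
    n_samples: int, cell_types: Sequence[str], seed: int
) -> pd.DataFrame:
    """Per-sample mixing weights drawn i.i.d. from Uniform(0, 1)."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.0, 1.0, size=(n_samples, len(cell_types)))
    index = [f"S{i + 1:03d}" for i in range(n_samples)]
    return pd.DataFrame(values, index=index, columns=list(cell_types))


def generate_mixture(
    bundle: ReferenceBundle,
    fractions: pd.DataFrame,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> Tuple[ExpressionMatrix, pd.DataFrame]:
    """Bulk mixtures with known composition.

    Each sample is the fraction-weighted average of the reference columns
    (weights normalised to sum to 1) plus additive Gaussian noise on the
    log-like scale of the reference, clipped at zero. Returns the
    expression matrix (microarray-tagged: values are already log-scale)
    and the normalised fraction truth table (samples x cell types).
    """
    f = fractions.reindex(columns=bundle.cell_types).to_numpy(dtype=float)
    if (f < 0).any():
        raise ValidationError("fractions must be >= 0")
    row_sums = f.sum(axis=1)
    zero_rows = np.flatnonzero(row_sums == 0)
    if zero_rows.size:
        raise ValidationError(
            f"all-zero fraction row(s): {fractions.index[zero_rows].tolist()}"
        )
    f_norm = f / row_sums[:, None]
    rng = np.random.default_rng(seed)
    rt = bundle.rt.to_numpy(dtype=float)
    values = rt @ f_norm.T  # genes x samples
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    expr = ExpressionMatrix(
        data=pd.DataFrame(values, index=bundle.rt.index, columns=fractions.index),
        platform="microarray",
        units="synthetic log intensity",
    )
    truth = pd.DataFrame(f_norm, index=fractions.index, columns=bundle.cell_types)
    return expr, truth


def generate_single_cells(
    bundle: ReferenceBundle,
    n_cells_per_sample: int = 100,
    n_samples: int = 3,
    n_housekeeping: int = 100,
    depth_spread: float = 0.3,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> SingleCellSet:
    """Labeled single cells on a TPM-like linear scale.

    Cell types are drawn per sample from a random composition; each cell's
    profile is its type's reference column (delogged to a linear scale)
    times a per-cell depth factor, plus multiplicative noise. The first
    ``n_housekeeping`` genes are given a flat profile across types and
    serve as the housekeeping set; the per-cell depth factor emulates the
    library-size differences that housekeeping normalisation removes.
    """
    rng = np.random.default_rng(seed)
    genes = list(bundle.rt.index)
    if n_housekeeping < 1 or n_housekeeping > len(genes):
        raise ValidationError("n_housekeeping out of range")
    hk = [f"HK{k + 1:04d}" for k in range(n_housekeeping)]
    linear = np.power(2.0, bundle.rt.to_numpy(dtype=float)) - 1.0
    hk_level = rng.uniform(50.0, 200.0, size=n_housekeeping)
    barcodes, labels, groups, columns = [], [], [], []
    for s in range(n_samples):
        weights = rng.uniform(0.0, 1.0, size=bundle.n_cell_types)
        weights /= weights.sum()
        types = rng.choice(bundle.n_cell_types, size=n_cells_per_sample, p=weights)
        for c, t in enumerate(types):
            depth = float(np.exp(rng.normal(0.0, depth_spread)))
            profile = linear[:, t] * np.exp(
                rng.normal(0.0, noise_sd, size=len(genes))
            )
            hk_expr = hk_level * np.exp(rng.normal(0.0, noise_sd, size=n_housekeeping))
            columns.append(np.concatenate([hk_expr, profile]) * depth)
            barcodes.append(f"S{s + 1:02d}.C{c + 1:04d}")
            labels.append(bundle.cell_types[t])
            groups.append(f"S{s + 1:02d}")
    expression = pd.DataFrame(
        np.column_stack(columns), index=hk + genes, columns=barcodes
    )
    return SingleCellSet(
        expression=expression,
        labels=pd.Series(labels, index=barcodes, name="cell_type"),
        groups=pd.Series(groups, index=barcodes, name="sample"),
        housekeeping=hk,
    )


def normalize_single_cells(sc: SingleCellSet) -> SingleCellSet:
    """log2(x+1) transform, then housekeeping scaling for cross-cell comparability.

    After the log transform, each cell i is rescaled by ``HKbar / HK_i``
    where ``HK_i`` is the cell's mean over the housekeeping genes and
    ``HKbar`` is the mean of ``HK_i`` over all cells, so every cell ends up
    with an identical mean housekeeping level.
    """
    if sc.normalized:
        raise ValidationError("single-cell set is already normalized")
    if not sc.housekeeping:
        raise ValidationError("housekeeping gene list is empty")
    missing = [g for g in sc.housekeeping if g not in set(sc.expression.index)]
    if missing:
        raise ValidationError(f"housekeeping genes missing from matrix: {missing[:5]}")
    values = sc.expression.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("single-cell expression must be >= 0")
    logged = np.log2(values + 1.0)
    logged = pd.DataFrame(logged, index=sc.expression.index, columns=sc.expression.columns)
    hk_means = logged.loc[sc.housekeeping].mean(axis=0)
    zero = hk_means.index[hk_means.to_numpy() == 0]
    if len(zero):
        raise ValidationError(f"zero housekeeping mean for cell(s): {list(zero[:5])}")
    scale = hk_means.mean() / hk_means
    out = logged.mul(scale, axis=1)
    return replace(sc, expression=out, normalized=True)


def pseudobulk(sc: SingleCellSet) -> Tuple[ExpressionMatrix, pd.DataFrame]:
    """Aggregate normalised cells into per-sample bulk profiles.

    Per sample group, the pseudo-bulk profile is the gene-wise mean over
    its cells, and the truth table holds each cell type's share of the
    group's cells (rows sum to 1). Aggregation by mean keeps the bulk
    values on the same scale as the per-cell values.
    """
    if not sc.normalized:
        raise ValidationError("pseudobulk expects a normalized single-cell set")
    group_ids = sorted(sc.groups.unique())
    cols = {}
    frac_rows = {}
    types = sorted(sc.labels.unique())
    for gid in group_ids:
        cells = sc.groups.index[sc.groups == gid]
        if len(cells) == 0:
            raise ValidationError(f"sample group {gid!r} has no cells")
        cols[gid] = sc.expression[cells].mean(axis=1)
        counts = sc.labels.loc[cells].value_counts()
        frac_rows[gid] = counts.reindex(types, fill_value=0) / len(cells)
    expr = ExpressionMatrix(
        data=pd.DataFrame(cols),
        platform="rnaseq",
        units="normalized log2 TPM",
        transformed=True,  # the log transform was applied per cell
    )
    truth = pd.DataFrame(frac_rows).T
    truth.index.name = "sample"
    return expr, truth
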