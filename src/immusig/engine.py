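"""Abundance estimation core.

For each query sample the pipeline is:

1. platform transform (identity for microarray, log2(x+1) for RNA-Seq);
2. alignment to the bundle's marker-gene universe;
3. deviation vector ``D``: per marker gene, the sample-minus-reference
   difference summed over the cell types that gene marks,
   ``D_g = sum_i ST[g,i] * (S_g - RT[g,i])``;
4. per cell type, the single-sample GSEA (ssGSEA) enrichment score of its
   signature over ``D`` (raw score ``ES``);
5. spillover correction: raw scores are deconvolved through a compensation
   matrix ``C`` by non-negative least squares,
   ``I = argmin_{x >= 0} ||C x - ES||_2``.

``C`` is derived from the bundle itself by scoring every signature against
every reference profile's own deviation vector (the "contribution" of type
j's profile to type i's score), normalising each column by its diagonal,
zeroing parent/subset pairs, and capping the per-column off-diagonal mass
at 0.5 so compensation can never dominate the direct signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .core import (
    CellTypeHierarchy,
    ExpressionMatrix,
    ReferenceBundle,
    ValidationError,
    align_to_reference,
    transform_expression,
)

__all__ = [
    "DEFAULT_ALPHA",
    "CompensationMatrix",
    "AbundanceResult",
    "compute_deviation",
    "ssgsea_score",
    "score_sample",
    "build_contribution_matrix",
    "normalize_compensation",
    "calibrate",
    "estimate",
]

logger = logging.getLogger(__name__)

#: ssGSEA rank-weight exponent (the GSVA ssGSEA default).
DEFAULT_ALPHA = 0.25

#: Cap on the total off-diagonal compensation per column of C.
COMPENSATION_CAP = 0.5


@dataclass(frozen=True)
class CompensationMatrix:
    """N x N spillover-correction matrix with enforced invariants."""

    matrix: pd.DataFrame

    def __post_init__(self):
        m = self.matrix.to_numpy()
        if not np.allclose(np.diag(m), 1.0):
            raise ValidationError("compensation matrix diagonal must be 1")
        off = m - np.diag(np.diag(m))
        if (off < -1e-12).any():
            raise ValidationError("compensation off-diagonals must be >= 0")
        if (off.sum(axis=0) > COMPENSATION_CAP + 1e-9).any():
            raise ValidationError(
                f"off-diagonal column sums must be <= {COMPENSATION_CAP}"
            )

    @property
    def cell_types(self) -> List[str]:
        return list(self.matrix.columns)


@dataclass
class AbundanceResult:
    """Raw ssGSEA scores and calibrated abundances, samples x cell types."""

    raw: pd.DataFrame
    calibrated: pd.DataFrame
    diagnostics: Dict = field(default_factory=dict)


def compute_deviation(sample: pd.Series, bundle: ReferenceBundle) -> pd.Series:
    """Deviation of one aligned, transformed sample from the reference.

    ``D_g = sum_i ST[g,i] * (S_g - RT[g,i])``: for a gene marking a single
    cell type this is simply the sample value minus that type's reference
    value; shared markers accumulate one difference per marking type.
    """
    markers = bundle.marker_genes
    if not sample.index.equals(pd.Index(markers)):
        raise ValidationError("sample is not aligned to the bundle marker order")
    st = bundle.st.loc[markers].to_numpy(dtype=float)
    rt = bundle.rt.loc[markers].to_numpy(dtype=float)
    s = sample.to_numpy(dtype=float)[:, None]
    d = (st * (s - rt)).sum(axis=1)
    return pd.Series(d, index=markers, name=sample.name)


def ssgsea_score(
    values: pd.Series,
    gene_set: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Single-sample GSEA score of *gene_set* within the profile *values*.

    Genes are ordered by decreasing value. Walking down that ordering, the
    in-set running fraction (hits weighted by rank^alpha, normalised by the
    in-set total) minus the out-of-set running fraction (equal weights) is
    accumulated at every position; the score is the sum of that difference
    over all positions. Ties are resolved by average ranks, which makes the
    score independent of the input ordering of tied genes; a profile that
    is constant everywhere scores 0 for every gene set.
    """
    if len(gene_set) == 0:
        raise ValidationError("empty gene set")
    n = len(values)
    index = values.index
    hit_mask = index.isin(set(gene_set))
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise ValidationError("gene set has no overlap with the profile")
    # average ascending ranks == tie-averaged count of positions at or below
    # the gene when walking the decreasing ordering
    rho = scipy.stats.rankdata(values.to_numpy(dtype=float), method="average")
    weights = np.abs(rho[hit_mask]) ** alpha
    total = weights.sum()
    if total == 0:
        raise ValidationError("degenerate rank weights (all zero)")
    hit_term = float((weights / total * rho[hit_mask]).sum())
    n_miss = n - n_hit
    miss_term = float(rho[~hit_mask].sum() / n_miss) if n_miss else 0.0
    return hit_term - miss_term


def score_sample(
    sample: pd.Series,
    bundle: ReferenceBundle,
    alpha: float = DEFAULT_ALPHA,
) -> pd.Series:
    """Raw enrichment score ES per cell type for one aligned sample."""
    deviation = compute_deviation(sample, bundle)
    scores = {
        cell_type: ssgsea_score(deviation, bundle.signatures[cell_type], alpha)
        for cell_type in bundle.cell_types
    }
    return pd.Series(scores, name=sample.name).reindex(bundle.cell_types)


def build_contribution_matrix(
    bundle: ReferenceBundle, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Mutual contribution of reference profiles to signature scores.

    Entry (i, j) is the ssGSEA score of signature i evaluated on the
    deviation vector of cell type j's own reference profile, i.e. how
    strongly a pure type-j sample would light up type i's signature.
    """
    markers = bundle.marker_genes
    cols = {}
    for cell_type in bundle.cell_types:
        profile = bundle.rt.loc[markers, cell_type]
        cols[cell_type] = score_sample(profile, bundle, alpha)
    return pd.DataFrame(cols).reindex(bundle.cell_types)


def normalize_compensation(
    contribution: pd.DataFrame,
    hierarchy: Optional[CellTypeHierarchy] = None,
    cap: float = COMPENSATION_CAP,
) -> CompensationMatrix:
    """Turn a contribution matrix into a compensation matrix C.

    Per column j: divide by the diagonal entry (the self-contribution, so
    the diagonal becomes 1); zero entries pairing a parent type with its
    own subsets; clamp negatives to 0; down-weight the off-diagonal entries
    by the column's off-diagonal mass proportion; finally, if the
    off-diagonal column sum still exceeds *cap*, rescale it to *cap*.
    """
    hierarchy = hierarchy or CellTypeHierarchy()
    types = list(contribution.columns)
    if list(contribution.index) != types:
        raise ValidationError("contribution matrix must be square over cell types")
    m = contribution.to_numpy(dtype=float).copy()
    diag = np.diag(m).copy()
    if (diag == 0).any():
        bad = [types[i] for i in np.flatnonzero(diag == 0)]
        raise ValidationError(f"zero diagonal contribution for {bad}")
    m = m / diag[None, :]
    for i, a in enumerate(types):
        for j, b in enumerate(types):
            if i != j and hierarchy.related(a, b):
                m[i, j] = 0.0
    off_mask = ~np.eye(len(types), dtype=bool)
    m[off_mask] = np.clip(m[off_mask], 0.0, None)
    for j in range(len(types)):
        off = m[:, j][off_mask[:, j]]
        s = off.sum()
        total = s + 1.0  # diagonal is 1 after normalisation
        proportion = s / total
        scaled = off * proportion
        s2 = scaled.sum()
        if s2 > cap:
            scaled *= cap / s2
        m[off_mask[:, j], j] = scaled
    np.fill_diagonal(m, 1.0)
    return CompensationMatrix(pd.DataFrame(m, index=types, columns=types))


def calibrate(es: pd.Series, compensation: CompensationMatrix) -> pd.Series:
    """Non-negative least-squares deconvolution of raw scores.

    Solves ``min_{I >= 0} ||C I - ES||_2`` with the Lawson-Hanson active-set
    method, so shared-marker spillover absorbed by C is removed from the
    reported abundances while keeping them non-negative.
    """
    types = compensation.cell_types
    vec = es.reindex(types).to_numpy(dtype=float)
    if not np.isfinite(vec).all():
        raise ValidationError("enrichment scores must be finite")
    solution, _ = scipy.optimize.nnls(compensation.matrix.to_numpy(), vec)
    return pd.Series(solution, index=types, name=es.name)


def estimate(
    expr: ExpressionMatrix,
    bundle: ReferenceBundle,
    alpha: float = DEFAULT_ALPHA,
    min_coverage: float = 0.5,
) -> AbundanceResult:
    """Full pipeline over a genes x samples matrix.

    Each sample is scored independently (no cross-sample normalisation, so
    single-sample input is supported). Per-sample failures are recorded in
    ``diagnostics["failed_samples"]`` and the batch continues.
    """
    if not expr.transformed:
        expr = transform_expression(expr)
    aligned = align_to_reference(expr, bundle, min_coverage=min_coverage)
    contribution = build_contribution_matrix(bundle, alpha)
    compensation = normalize_compensation(contribution, bundle.hierarchy)

    raw_rows: Dict[str, pd.Series] = {}
    cal_rows: Dict[str, pd.Series] = {}
    residuals: Dict[str, float] = {}
    failed: Dict[str, str] = {}
    c = compensation.matrix.to_numpy()
    for sample_id in aligned.matrix.sample_ids:
        try:
            es = score_sample(aligned.matrix.data[sample_id], bundle, alpha)
            cal = calibrate(es, compensation)
            raw_rows[sample_id] = es
            cal_rows[sample_id] = cal
            residuals[sample_id] = float(
                np.linalg.norm(c @ cal.to_numpy() - es.to_numpy())
            )
        except ValidationError as exc:  # batch continues
            failed[sample_id] = str(exc)
            logger.warning("sample %s failed: %s", sample_id, exc)
    raw = pd.DataFrame(raw_rows).T.reindex(columns=bundle.cell_types)
    calibrated = pd.DataFrame(cal_rows).T.reindex(columns=bundle.cell_types)
    return AbundanceResult(
        raw=raw,
        calibrated=calibrated,
        diagnostics={
            "coverage": aligned.coverage,
            "missing_genes": aligned.missing_genes,
            "residual_norm": residuals,
            "failed_samples": failed,
            "alpha": alpha,
            "compensation": compensation.matrix,
        },
    )
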