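"""Simulation-driven marker gene selection.

Candidate markers are screened on simulated mixtures with known
composition: per stratum (a "tumor-like" expression matrix standing in for
one cancer type), mixing weights f_1..f_N are drawn from Uniform(0,1), the
mean profile is the f-weighted average of the reference columns, and
expression is drawn from a multivariate normal with that mean and the
stratum's gene-gene covariance, so the correlative structure of real
tumors is preserved.

Two filters follow. G1 keeps genes whose expression tracks the fraction of
the cell type(s) they mark (average Pearson r across strata >= 0.6 by
default). G2 keeps genes whose on-target correlation stands out from their
correlations with all unrelated cell types, measured as a z-score of the
on-target r against the off-target r distribution (> 1.5 by default);
parent/subset partners of the marked type are excluded from the off-target
set. The final marker set is the intersection G1 & G2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import ReferenceBundle, ValidationError

__all__ = [
    "MixtureSimulationSpec",
    "SimulatedMixtureSet",
    "MarkerSelectionResult",
    "simulate_mixtures",
    "g1_statistics",
    "g2_statistics",
    "filter_g1",
    "filter_g2",
    "select_markers",
]

logger = logging.getLogger(__name__)

G1_THRESHOLD = 0.6
G2_THRESHOLD = 1.5


@dataclass(frozen=True)
class MixtureSimulationSpec:
    """Inputs for covariance-preserving mixture simulation.

    ``strata`` maps a stratum name to a genes x samples log-scale
    expression matrix; each stratum contributes its own gene-gene
    covariance and ``n_samples`` simulated mixtures.
    """

    candidate_genes: Tuple[str, ...]
    strata: Mapping[str, pd.DataFrame]
    n_samples: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if not self.strata:
            raise ValidationError("at least one stratum is required")
        object.__setattr__(self, "candidate_genes", tuple(self.candidate_genes))


@dataclass
class SimulatedMixtureSet:
    """Simulated mixtures: known fractions, expression, per-sample means."""

    fractions: pd.DataFrame  # samples x cell types, raw Uniform(0,1) draws
    expression: pd.DataFrame  # samples x candidate genes
    mean_profiles: pd.DataFrame  # samples x candidate genes
    strata: pd.Series  # sample -> stratum name

    @property
    def cell_fractions(self) -> pd.DataFrame:
        """True per-sample composition: the mixing weights normalised to 1."""
        return self.fractions.div(self.fractions.sum(axis=1), axis=0)


@dataclass
class MarkerSelectionResult:
    g1: Set[str]
    g2: Set[str]
    gf: Set[str]
    per_gene_stats: pd.DataFrame
    bundle: ReferenceBundle


def _psd_repair(cov: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (clip eigenvalues at 0)."""
    cov = (cov + cov.T) / 2.0
    eigval, eigvec = np.linalg.eigh(cov)
    if not np.isfinite(eigval).all():
        raise ValidationError("covariance matrix is not repairable to PSD")
    eigval = np.clip(eigval, 0.0, None)
    return eigvec, eigval


def simulate_mixtures(
    spec: MixtureSimulationSpec, rt: pd.DataFrame
) -> SimulatedMixtureSet:
    """Draw known-fraction mixtures per stratum.

    Per sample: f_1..f_N ~ Uniform(0,1); the mean profile is the
    f-weighted *average* of the reference columns (weights divided by
    their sum); expression = mean + multivariate normal noise with the
    stratum covariance (PSD-repaired sample covariance of the stratum
    matrix over the candidate genes). Fully reproducible under the seed.
    """
    genes = list(spec.candidate_genes)
    missing = [g for g in genes if g not in set(rt.index)]
    if missing:
        raise ValidationError(f"candidate genes missing from rt: {missing[:5]}")
    ref = rt.loc[genes].to_numpy(dtype=float)
    n_types = ref.shape[1]
    rng = np.random.default_rng(spec.seed)

    frac_blocks, expr_blocks, mean_blocks, labels, index = [], [], [], [], []
    for stratum, matrix in spec.strata.items():
        missing = [g for g in genes if g not in set(matrix.index)]
        if missing:
            raise ValidationError(
                f"stratum {stratum!r} lacks candidate genes: {missing[:5]}"
            )
        cov = np.cov(matrix.loc[genes].to_numpy(dtype=float))
        cov = np.atleast_2d(cov)
        eigvec, eigval = _psd_repair(cov)
        f = rng.uniform(0.0, 1.0, size=(spec.n_samples, n_types))
        mu = (f / f.sum(axis=1, keepdims=True)) @ ref.T  # samples x genes
        z = rng.standard_normal(size=(spec.n_samples, len(genes)))
        noise = z @ (eigvec * np.sqrt(eigval)).T
        frac_blocks.append(f)
        mean_blocks.append(mu)
        expr_blocks.append(mu + noise)
        labels.extend([stratum] * spec.n_samples)
        index.extend(f"{stratum}.S{i + 1:04d}" for i in range(spec.n_samples))

    columns = list(rt.columns)
    return SimulatedMixtureSet(
        fractions=pd.DataFrame(np.vstack(frac_blocks), index=index, columns=columns),
        expression=pd.DataFrame(np.vstack(expr_blocks), index=index, columns=genes),
        mean_profiles=pd.DataFrame(np.vstack(mean_blocks), index=index, columns=genes),
        strata=pd.Series(labels, index=index, name="stratum"),
    )


def _pearson_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlations between x (n x p) and y (n x q).

    Zero-variance columns yield NaN correlations.
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    xs = np.sqrt((xc**2).sum(axis=0))
    ys = np.sqrt((yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / np.outer(xs, ys)
    r[~np.isfinite(r)] = np.nan
    return r


def _marker_map(bundle: ReferenceBundle, genes: Sequence[str]) -> Dict[str, List[str]]:
    """gene -> cell types whose signature lists it."""
    out: Dict[str, List[str]] = {g: [] for g in genes}
    for cell_type, sig in bundle.signatures.items():
        for g in sig:
            if g in out:
                out[g].append(cell_type)
    return out


def _per_stratum_correlations(
    sim: SimulatedMixtureSet, genes: List[str], cell_types: List[str]
) -> np.ndarray:
    """Average over strata of the gene x cell-type correlation matrix.

    Expression is correlated with the true composition (normalised
    fractions), not the raw mixing draws.
    """
    fractions = sim.cell_fractions
    mats = []
    for stratum in sim.strata.unique():
        rows = sim.strata.index[sim.strata == stratum]
        if len(rows) < 3:
            raise ValidationError(
                f"stratum {stratum!r} has fewer than 3 simulated samples"
            )
        expr = sim.expression.loc[rows, genes].to_numpy(dtype=float)
        frac = fractions.loc[rows, cell_types].to_numpy(dtype=float)
        mats.append(_pearson_matrix(expr, frac))
    return np.nanmean(np.stack(mats), axis=0)


def g1_statistics(sim: SimulatedMixtureSet, bundle: ReferenceBundle) -> pd.Series:
    """Per candidate gene: average on-target correlation across strata.

    A gene marking several cell types uses the mean of its on-target
    correlations. Genes with zero variance (undefined correlation) get NaN
    and a logged note.
    """
    genes = list(sim.expression.columns)
    cell_types = list(sim.fractions.columns)
    marker_of = _marker_map(bundle, genes)
    r = _per_stratum_correlations(sim, genes, cell_types)
    col = {c: j for j, c in enumerate(cell_types)}
    out = {}
    for i, g in enumerate(genes):
        targets = [col[c] for c in marker_of[g] if c in col]
        if not targets:
            out[g] = np.nan
            continue
        vals = r[i, targets]
        if np.isnan(vals).all():
            logger.warning("gene %s has undefined correlation (zero variance)", g)
            out[g] = np.nan
        else:
            out[g] = float(np.nanmean(vals))
    return pd.Series(out, name="avg_r")


def filter_g1(
    sim: SimulatedMixtureSet,
    bundle: ReferenceBundle,
    threshold: float = G1_THRESHOLD,
) -> Set[str]:
    """Genes whose average on-target correlation reaches the threshold."""
    stats = g1_statistics(sim, bundle)
    return set(stats.index[stats.to_numpy() >= threshold])


def g2_statistics(sim: SimulatedMixtureSet, bundle: ReferenceBundle) -> pd.DataFrame:
    """Specificity z-scores per (gene, marked cell type).

    For gene g marking type c, the off-target set is every cell type that
    is neither c, another type g marks, nor a parent/subset partner of c.
    z = (r_c - mean(r_off)) / sd(r_off); large z means the gene's
    association is specific to its own type.
    """
    genes = list(sim.expression.columns)
    cell_types = list(sim.fractions.columns)
    marker_of = _marker_map(bundle, genes)
    r = _per_stratum_correlations(sim, genes, cell_types)
    col = {c: j for j, c in enumerate(cell_types)}
    records = []
    for i, g in enumerate(genes):
        for c in marker_of[g]:
            if c not in col:
                continue
            excluded = {c} | set(marker_of[g]) | set(bundle.hierarchy.relatives(c))
            off = [col[t] for t in cell_types if t not in excluded]
            if len(off) < 3:
                raise ValidationError(
                    f"fewer than 3 off-target cell types for gene {g!r} of {c!r}"
                )
            r_on = r[i, col[c]]
            r_off = r[i, off]
            sd = float(np.nanstd(r_off, ddof=1))
            if np.isnan(r_on) or sd == 0:
                z = np.nan
            else:
                z = float((r_on - np.nanmean(r_off)) / sd)
            records.append(
                {"gene": g, "cell_type": c, "r_on": r_on, "z": z, "n_off": len(off)}
            )
    return pd.DataFrame.from_records(records)


def filter_g2(
    sim: SimulatedMixtureSet,
    bundle: ReferenceBundle,
    threshold: float = G2_THRESHOLD,
) -> Set[str]:
    """Genes specific to (at least one of) the types they mark."""
    stats = g2_statistics(sim, bundle)
    if stats.empty:
        return set()
    best = stats.groupby("gene")["z"].max()
    return set(best.index[best.to_numpy() > threshold])


def select_markers(
    sim: SimulatedMixtureSet,
    bundle: ReferenceBundle,
    g1_threshold: float = G1_THRESHOLD,
    g2_threshold: float = G2_THRESHOLD,
) -> MarkerSelectionResult:
    """Intersect the correlation and specificity filters; rebuild the bundle.

    The returned bundle is the input restricted to the final gene set, with
    signatures, rt and st rebuilt accordingly. It is an error for a cell
    type to lose all of its markers.
    """
    g1_stats = g1_statistics(sim, bundle)
    g2_stats = g2_statistics(sim, bundle)
    g1 = set(g1_stats.index[g1_stats.to_numpy() >= g1_threshold])
    if g2_stats.empty:
        g2: Set[str] = set()
        best_z = pd.Series(dtype=float)
    else:
        best_z = g2_stats.groupby("gene")["z"].max()
        g2 = set(best_z.index[best_z.to_numpy() > g2_threshold])
    gf = g1 & g2

    restricted = bundle.restrict(sorted(gf))
    empty = [t for t in restricted.cell_types if not restricted.signatures.get(t)]
    if empty:
        raise ValidationError(f"cell type(s) left with zero markers: {empty}")

    stats = pd.DataFrame({"avg_r": g1_stats})
    stats["z_max"] = best_z.reindex(stats.index)
    stats["in_g1"] = stats.index.isin(g1)
    stats["in_g2"] = stats.index.isin(g2)
    stats["selected"] = stats.index.isin(gf)
    return MarkerSelectionResult(
        g1=g1, g2=g2, gf=gf, per_gene_stats=stats, bundle=restricted
    )
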