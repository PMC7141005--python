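"""Core domain types: expression matrices, the reference bundle, and validation.

The estimator works off a *reference bundle*: a reference expression matrix
``rt`` (marker genes x cell types, median-aggregated per type), a binary
marker indicator ``st`` of the same shape, per-type marker gene lists
(signatures), and a shallow cell-type hierarchy (parent type -> functional
subsets, e.g. CD4 T -> Th1/Th2/...). Query profiles are brought onto the
bundle's marker-gene universe before scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, NamedTuple, Sequence, Set

import numpy as np
import pandas as pd

__all__ = [
    "IMMUNE_CELL_TYPES",
    "T_CELL_SUBSETS",
    "IMMUNE_HIERARCHY",
    "ExpressionMatrix",
    "CellTypeHierarchy",
    "ReferenceBundle",
    "AlignedExpression",
    "ValidationError",
    "transform_expression",
    "validate_bundle",
    "align_to_reference",
]

#: The 24 immune cell types of the shipped ontology. Eighteen of them are
#: T-cell subsets (see T_CELL_SUBSETS); the remaining six are B cells,
#: macrophages, monocytes, neutrophils, dendritic cells and NK cells.
IMMUNE_CELL_TYPES: tuple = (
    "CD4 T",
    "CD8 T",
    "CD4 naive",
    "CD8 naive",
    "Tcm",
    "Tem",
    "Tr1",
    "iTreg",
    "nTreg",
    "Th1",
    "Th2",
    "Th17",
    "Tfh",
    "Tc",
    "MAIT",
    "Tex",
    "Gamma delta T",
    "NKT",
    "B cell",
    "Macrophage",
    "Monocyte",
    "Neutrophil",
    "DC",
    "NK",
)

#: T-cell subsets within the ontology (18 of the 24 types).
T_CELL_SUBSETS: frozenset = frozenset(
    {
        "CD4 T",
        "CD8 T",
        "CD4 naive",
        "CD8 naive",
        "Tcm",
        "Tem",
        "Tr1",
        "iTreg",
        "nTreg",
        "Th1",
        "Th2",
        "Th17",
        "Tfh",
        "Tc",
        "MAIT",
        "Tex",
        "Gamma delta T",
        "NKT",
    }
)

#: Parent -> subset relations. Compensation between a parent and its own
#: subsets is suppressed, and marker specificity is never scored against
#: the parent/subset partner.
IMMUNE_HIERARCHY_RELATIONS: Dict[str, FrozenSet[str]] = {
    "CD4 T": frozenset(
        {"CD4 naive", "Th1", "Th2", "Th17", "Tfh", "Tr1", "iTreg", "nTreg"}
    ),
    "CD8 T": frozenset({"CD8 naive", "Tc", "MAIT", "Tex"}),
}


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class CellTypeHierarchy:
    """Shallow (depth-1) parent -> subsets relation between cell types."""

    relations: Mapping[str, FrozenSet[str]] = field(default_factory=dict)

    def __post_init__(self):
        rel = {p: frozenset(c) for p, c in self.relations.items()}
        object.__setattr__(self, "relations", rel)
        seen: Set[str] = set()
        for parent, children in rel.items():
            if parent in children:
                raise ValidationError(f"hierarchy: self-relation for {parent!r}")
            if parent in seen or any(c in rel for c in children):
                raise ValidationError("hierarchy depth must be <= 1")
            overlap = seen & children
            if overlap:
                raise ValidationError(
                    f"hierarchy: children of distinct parents overlap: {sorted(overlap)}"
                )
            seen |= children

    def related(self, a: str, b: str) -> bool:
        """True iff *a* and *b* are a parent/subset pair (either direction)."""
        return b in self.relations.get(a, ()) or a in self.relations.get(b, ())

    def relatives(self, cell_type: str) -> FrozenSet[str]:
        """Parent and/or subsets of *cell_type* (empty for unrelated types)."""
        out: Set[str] = set(self.relations.get(cell_type, ()))
        for parent, children in self.relations.items():
            if cell_type in children:
                out.add(parent)
        return frozenset(out)


IMMUNE_HIERARCHY = CellTypeHierarchy(IMMUNE_HIERARCHY_RELATIONS)


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with platform provenance.

    Parameters
    ----------
    data:
        Numeric DataFrame, rows indexed by gene identifiers (HGNC-style
        symbols; matching downstream is case-insensitive), columns by
        sample identifiers.
    platform:
        ``"microarray"`` (log-scale intensities) or ``"rnaseq"``
        (linear TPM/FPKM, log2(x+1)-transformed before scoring).
    units:
        Free-text unit note, e.g. ``"TPM"`` or ``"intensity"``.
    transformed:
        Whether the platform transform has already been applied.
    """

    data: pd.DataFrame
    platform: str
    units: str = ""
    transformed: bool = False

    def __post_init__(self):
        if self.platform not in ("microarray", "rnaseq"):
            raise ValidationError(f"unknown platform {self.platform!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression values must be finite")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self):
        return self.data.shape


def transform_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Apply the platform-dependent expression transform.

    Microarray intensities are assumed to be on log scale already and pass
    through unchanged; RNA-Seq values m (TPM/FPKM) become log2(m + 1).
    Applying the transform twice is an error.
    """
    if expr.transformed:
        raise ValidationError("expression matrix is already transformed")
    values = expr.data.to_numpy()
    if values.size and (values < 0).any():
        raise ValidationError("expression values must be >= 0 before transform")
    if expr.platform == "rnaseq":
        data = pd.DataFrame(
            np.log2(values + 1.0), index=expr.gene_ids, columns=expr.sample_ids
        )
    else:
        data = expr.data.copy()
    return ExpressionMatrix(
        data=data, platform=expr.platform, units=expr.units, transformed=True
    )


@dataclass
class ReferenceBundle:
    """Reference profiles, marker indicator and signatures for N cell types.

    ``rt`` may carry extra non-signature rows (background genes used by the
    synthetic generators); the scoring universe is :attr:`marker_genes`,
    i.e. the rows flagged in ``st``.
    """

    cell_types: List[str]
    rt: pd.DataFrame  # genes x cell types
    st: pd.DataFrame  # genes x cell types, binary
    signatures: Dict[str, List[str]]
    hierarchy: CellTypeHierarchy = field(default_factory=CellTypeHierarchy)
    t_subsets: FrozenSet[str] = frozenset()

    @property
    def marker_genes(self) -> pd.Index:
        """Genes flagged as a marker of at least one cell type, in rt row order."""
        mask = self.st.to_numpy().sum(axis=1) > 0
        return self.rt.index[mask]

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def restrict(self, genes: Sequence[str]) -> "ReferenceBundle":
        """Bundle restricted to *genes* (rt row order preserved)."""
        keep = self.rt.index.isin(set(genes))
        rt = self.rt.loc[keep]
        st = self.st.loc[keep]
        kept = set(rt.index)
        sigs = {t: [g for g in gs if g in kept] for t, gs in self.signatures.items()}
        return replace(self, rt=rt, st=st, signatures=sigs)


def validate_bundle(bundle: ReferenceBundle) -> List[str]:
    """Check every bundle invariant; return one finding string per violation.

    Returns an empty list iff the bundle is internally consistent. Findings
    are diagnostics, not exceptions: advisory conditions (e.g. two cell
    types with identical reference profiles) are reported the same way.
    """
    findings: List[str] = []
    ct = list(bundle.cell_types)
    if len(set(ct)) != len(ct):
        findings.append("duplicate cell-type names")
    for frame, name in ((bundle.rt, "rt"), (bundle.st, "st")):
        if list(frame.columns) != ct:
            findings.append(f"{name} columns do not match cell_types order")
    if not bundle.rt.index.equals(bundle.st.index):
        findings.append("rt and st row indices differ")
    if not np.isfinite(bundle.rt.to_numpy()).all():
        findings.append("rt contains non-finite values")
    st_vals = bundle.st.to_numpy()
    if not np.isin(st_vals, (0, 1)).all():
        findings.append("st must be binary")

    rows = set(bundle.rt.index)
    for cell_type in ct:
        sig = bundle.signatures.get(cell_type, [])
        if len(sig) == 0:
            findings.append(f"cell type {cell_type!r} has no marker genes")
        for gene in sig:
            if gene not in rows:
                findings.append(
                    f"signature gene {gene!r} of {cell_type!r} missing from rt rows"
                )
            elif cell_type in bundle.st.columns and bundle.st.at[gene, cell_type] != 1:
                findings.append(
                    f"signature gene {gene!r} of {cell_type!r} not flagged in st"
                )
    # st -> signature consistency
    for j, cell_type in enumerate(ct):
        if cell_type not in bundle.st.columns:
            continue
        flagged = set(bundle.st.index[bundle.st[cell_type].to_numpy() == 1])
        declared = set(bundle.signatures.get(cell_type, []))
        for gene in sorted(flagged - declared):
            findings.append(
                f"gene {gene!r} flagged in st for {cell_type!r} but absent from its signature"
            )

    for parent in bundle.hierarchy.relations:
        if parent not in set(ct):
            findings.append(f"hierarchy parent {parent!r} not a bundle cell type")
    for parent, children in bundle.hierarchy.relations.items():
        for child in children:
            if child not in set(ct):
                findings.append(f"hierarchy child {child!r} not a bundle cell type")
    for t in bundle.t_subsets:
        if t not in set(ct):
            findings.append(f"t_subset {t!r} not a bundle cell type")

    # advisory: indistinguishable reference profiles
    marker_rt = bundle.rt.loc[bundle.marker_genes] if len(bundle.rt) else bundle.rt
    for i in range(len(ct)):
        for j in range(i + 1, len(ct)):
            a, b = ct[i], ct[j]
            if a in marker_rt.columns and b in marker_rt.columns and len(marker_rt):
                if np.array_equal(marker_rt[a].to_numpy(), marker_rt[b].to_numpy()):
                    findings.append(
                        f"advisory: cell types {a!r} and {b!r} have identical reference profiles"
                    )
    return findings


class AlignedExpression(NamedTuple):
    """Expression restricted to the bundle marker universe plus coverage info."""

    matrix: ExpressionMatrix
    coverage: float
    missing_genes: List[str]


def align_to_reference(
    expr: ExpressionMatrix,
    bundle: ReferenceBundle,
    min_coverage: float = 0.5,
) -> AlignedExpression:
    """Subset and reorder a transformed profile to the bundle marker universe.

    Matching is case-insensitive on gene symbols; duplicate rows after
    case-folding are collapsed by median (the same aggregation rule used to
    build reference profiles). Marker genes absent from the query are
    imputed with the per-sample median of the observed marker values, which
    keeps their deviations near the middle of the distribution instead of
    at an extreme rank.
    """
    if not expr.transformed:
        raise ValidationError("align_to_reference requires a transformed matrix")
    markers = bundle.marker_genes
    folded = expr.data.copy()
    folded.index = folded.index.astype(str).str.upper()
    if folded.index.has_duplicates:
        folded = folded.groupby(level=0, sort=False).median()
    upper_to_marker = {str(g).upper(): g for g in markers}
    present = [g for g in markers if str(g).upper() in set(folded.index)]
    coverage = len(present) / len(markers) if len(markers) else 0.0
    if coverage < min_coverage:
        raise ValidationError(
            f"marker coverage {coverage:.3f} below floor {min_coverage:.3f}"
        )
    missing = [g for g in markers if g not in set(present)]
    sub = folded.loc[[str(g).upper() for g in present]]
    sub.index = pd.Index(present)
    out = sub.reindex(markers)
    if missing:
        fill = sub.median(axis=0)
        for gene in missing:
            out.loc[gene] = fill
    aligned = ExpressionMatrix(
        data=out,
        platform=expr.platform,
        units=expr.units,
        transformed=True,
    )
    return AlignedExpression(matrix=aligned, coverage=coverage, missing_genes=missing)
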