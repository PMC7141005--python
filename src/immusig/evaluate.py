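"""Performance assessment against ground-truth compositions.

Accuracy per cell type is the Pearson correlation r_i between estimated
and true abundance across samples; the scalar summary is the correlation
deviation, (1/n) * sum_i (1 - r_i)^2, which is 0 iff every r_i is 1 and at
most 4 (all r_i = -1). Lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ValidationError

__all__ = [
    "EvaluationReport",
    "per_cell_correlation",
    "correlation_deviation",
    "benchmark_report",
]


@dataclass
class EvaluationReport:
    per_cell_r: Dict[str, float]  # NaN marks unavailable correlations
    n_cells: int
    correlation_deviation: float
    n_samples: int


def per_cell_correlation(
    estimates: pd.DataFrame, truth: pd.DataFrame
) -> Dict[str, float]:
    """Pearson r per shared cell type, over shared samples.

    Cell types with zero variance in either vector are reported as NaN
    (unavailable) rather than dropped silently, mirroring how benchmark
    tables flag non-evaluable cells.
    """
    samples = estimates.index.intersection(truth.index)
    if len(samples) == 0:
        raise ValidationError("no shared samples between estimates and truth")
    if len(samples) < 3:
        raise ValidationError("need at least 3 shared samples for correlation")
    types = [c for c in estimates.columns if c in set(truth.columns)]
    if not types:
        raise ValidationError("no shared cell types between estimates and truth")
    out: Dict[str, float] = {}
    for cell_type in types:
        x = estimates.loc[samples, cell_type].to_numpy(dtype=float)
        y = truth.loc[samples, cell_type].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            out[cell_type] = float("nan")
        else:
            out[cell_type] = float(np.corrcoef(x, y)[0, 1])
    return out


def correlation_deviation(
    r: Sequence[float], variant: str = "squared_error"
) -> float:
    """Aggregate per-type correlations into a single accuracy penalty.

    ``squared_error`` (default): mean of (1 - r_i)^2. The alternative
    reading ``one_minus_r2`` (mean of 1 - r_i^2) is available for
    comparison. NaN entries (unavailable correlations) are excluded from n.
    """
    values = np.asarray([v for v in r if not np.isnan(v)], dtype=float)
    if values.size == 0:
        raise ValidationError("no evaluable correlations")
    if (np.abs(values) > 1 + 1e-12).any():
        raise ValidationError("correlations must lie in [-1, 1]")
    if variant == "squared_error":
        return float(np.mean((1.0 - values) ** 2))
    if variant == "one_minus_r2":
        return float(np.mean(1.0 - values**2))
    raise ValidationError(f"unknown variant {variant!r}")


def evaluate(estimates: pd.DataFrame, truth: pd.DataFrame) -> EvaluationReport:
    """Full report: per-type r plus the correlation-deviation summary."""
    per_cell = per_cell_correlation(estimates, truth)
    usable = [v for v in per_cell.values() if not np.isnan(v)]
    return EvaluationReport(
        per_cell_r=per_cell,
        n_cells=len(usable),
        correlation_deviation=correlation_deviation(list(per_cell.values())),
        n_samples=len(estimates.index.intersection(truth.index)),
    )


def benchmark_report(
    estimates_by_method: Mapping[str, pd.DataFrame], truth: pd.DataFrame
) -> pd.DataFrame:
    """Long-format method x cell-type accuracy table.

    One row per (method, cell type) with the Pearson r (NaN when the
    method does not cover the type or the correlation is undefined), plus
    one summary row per method carrying the correlation deviation.
    """
    if not estimates_by_method:
        raise ValidationError("at least one method is required")
    all_types: list = list(truth.columns)
    records = []
    for method, estimates in estimates_by_method.items():
        per_cell = per_cell_correlation(estimates, truth)
        for cell_type in all_types:
            records.append(
                {
                    "method": method,
                    "cell_type": cell_type,
                    "r": per_cell.get(cell_type, float("nan")),
                }
            )
        records.append(
            {
                "method": method,
                "cell_type": "__correlation_deviation__",
                "r": correlation_deviation(list(per_cell.values())),
            }
        )
    return pd.DataFrame.from_records(records)
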