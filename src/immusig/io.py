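"""Matrix readers/writers, bundle persistence, and run manifests.

Expression matrices travel as delimited text (tab or comma, auto-detected;
gzip-transparent): first column gene identifiers, header row sample
identifiers. Bundles are directories holding the reference matrix as TSV
plus YAML metadata. Every CLI run emits a JSON manifest with the command,
parameters, seeds, input checksums and tool version.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .core import (
    CellTypeHierarchy,
    ExpressionMatrix,
    ReferenceBundle,
    ValidationError,
)

__all__ = [
    "read_expression",
    "write_matrix",
    "read_matrix",
    "write_abundance",
    "save_bundle",
    "load_bundle",
    "RunManifest",
]


def read_matrix(path) -> pd.DataFrame:
    """Delimited text -> DataFrame (first column is the row index)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if frame.empty:
        raise ValidationError(f"empty matrix: {path}")
    return frame


def read_expression(path, platform: str, units: str = "") -> ExpressionMatrix:
    """Read a genes x samples matrix, collapsing duplicate genes by median.

    Non-numeric cells are reported with their coordinates.
    """
    frame = read_matrix(path)
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric value at gene {frame.index[row]!r}, sample {frame.columns[col]!r}"
        )
    if numeric.isna().to_numpy().any():
        row, col = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"missing value at gene {numeric.index[row]!r}, sample {numeric.columns[col]!r}"
        )
    if numeric.index.has_duplicates:
        numeric = numeric.groupby(level=0, sort=False).median()
    return ExpressionMatrix(data=numeric, platform=platform, units=units)


def write_matrix(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", float_format="%.17g")


def write_abundance(result, path, raw: bool = False) -> None:
    """Write calibrated abundances (or raw scores) as samples x types TSV."""
    table = result.raw if raw else result.calibrated
    write_matrix(table, path)


def save_bundle(bundle: ReferenceBundle, directory) -> None:
    """Persist a bundle as a directory of TSV + YAML files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_matrix(bundle.rt, directory / "rt.tsv")
    write_matrix(bundle.st, directory / "st.tsv")
    meta = {
        "cell_types": list(bundle.cell_types),
        "signatures": {t: list(g) for t, g in bundle.signatures.items()},
        "hierarchy": {p: sorted(c) for p, c in bundle.hierarchy.relations.items()},
        "t_subsets": sorted(bundle.t_subsets),
    }
    with open(directory / "bundle.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_bundle(directory) -> ReferenceBundle:
    directory = Path(directory)
    meta_path = directory / "bundle.yaml"
    if not meta_path.exists():
        raise ValidationError(f"no bundle.yaml in {directory}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    rt = read_matrix(directory / "rt.tsv")
    st = read_matrix(directory / "st.tsv")
    return ReferenceBundle(
        cell_types=list(meta["cell_types"]),
        rt=rt,
        st=st,
        signatures={t: list(g) for t, g in meta["signatures"].items()},
        hierarchy=CellTypeHierarchy(
            {p: frozenset(c) for p, c in (meta.get("hierarchy") or {}).items()}
        ),
        t_subsets=frozenset(meta.get("t_subsets") or ()),
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted alongside every CLI result."""

    command: str
    parameters: Dict = field(default_factory=dict)
    seed: Optional[int] = None
    inputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256
    version: str = ""
    timestamp: str = ""

    @classmethod
    def create(cls, command: str, parameters: Dict, seed: Optional[int], inputs: List):
        from . import __version__

        checksums = {}
        for p in inputs:
            if p and os.path.isfile(p):
                checksums[str(p)] = _sha256(p)
        return cls(
            command=command,
            parameters={k: v for k, v in parameters.items() if v is not None},
            seed=seed,
            inputs=checksums,
            version=__version__,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)
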