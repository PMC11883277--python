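"""Validated TSV/CSV readers and writers.

Counts are gene x sample non-negative integers; the design table names each
sample's genotype (WT, ett, arf4, ett_arf4), treatment (mock, IAA) and
replicate.  Output files carry a ``#``-prefixed header recording the tool
version, seed and thresholds; readers skip such comment lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .factorial import GENOTYPES, TREATMENTS


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read and validate a gene x sample count matrix."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0, comment="#")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()][:5].tolist()
        raise ValueError(f"duplicated gene ids: {dupes}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()][:5].tolist()
        raise ValueError(f"duplicated sample ids: {dupes}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: counts must be numeric")
    frac = arr != np.floor(arr)
    if frac.any():
        i, j = np.argwhere(frac)[0]
        raise ValueError(
            f"non-integer count for gene {df.index[i]!r}, sample "
            f"{df.columns[j]!r}: {arr[i, j]}"
        )
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative count for gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    df = df.astype(np.int64)
    df.index.name = "gene_id"
    return df


def read_design(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample design table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), comment="#")
    required = {"sample_id", "genotype", "treatment", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"][:5].tolist()
        raise ValueError(f"duplicated sample ids: {dupes}")
    bad_g = set(df["genotype"]) - set(GENOTYPES)
    if bad_g:
        raise ValueError(
            f"unknown genotype labels {sorted(bad_g)}; allowed: {GENOTYPES}"
        )
    bad_t = set(df["treatment"]) - set(TREATMENTS)
    if bad_t:
        raise ValueError(
            f"unknown treatment labels {sorted(bad_t)}; allowed: {TREATMENTS}"
        )
    return df.set_index("sample_id")


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Read a two-column (gene_id, length_bp) table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected gene_id and length columns")
    s = df.set_index(df.columns[0])[df.columns[1]].astype(float)
    if (s <= 0).any():
        raise ValueError("gene lengths must be positive")
    s.name = "length_bp"
    return s


def validate_matching(counts: pd.DataFrame, design: pd.DataFrame) -> None:
    """Counts and design must describe exactly the same samples."""
    c, d = set(counts.columns), set(design.index)
    if c != d:
        raise ValueError(
            f"sample mismatch: counts-only {sorted(c - d)[:5]}, "
            f"design-only {sorted(d - c)[:5]}"
        )


def require_full_grid(design: pd.DataFrame) -> None:
    """The classifiers need every genotype x treatment cell populated."""
    cells = set(zip(design["genotype"], design["treatment"]))
    missing = [
        (g, t) for g in GENOTYPES for t in TREATMENTS if (g, t) not in cells
    ]
    if missing:
        raise ValueError(f"design is missing factorial cells: {missing}")


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    header_lines: list[str] | None = None,
    index: bool = True,
) -> Path:
    """Write a TSV with ``#``-prefixed provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)
    return path
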