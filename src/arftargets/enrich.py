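"""Flat over-representation analysis (hypergeometric tail + BH FDR).

Gene lists are tested against the expressed-gene background with the exact
hypergeometric upper tail P(X >= k); the annotation is a flat gene->term
mapping (no ontology DAG or ancestor propagation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .de import bh_adjust


@dataclass
class TermAnnotation:
    """Flat mapping term id -> set of gene ids (with optional labels)."""

    terms: dict[str, set[str]]
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        empty = [t for t, genes in self.terms.items() if not genes]
        if empty:
            warnings.warn(f"dropping {len(empty)} empty terms", stacklevel=2)
            for t in empty:
                del self.terms[t]


def read_annotation(path: str | Path) -> TermAnnotation:
    """Read a two-column (gene, term) TSV; duplicate pairs are deduplicated.

    Malformed lines raise with their line number.  An empty file yields an
    empty annotation with a warning.
    """
    terms: dict[str, set[str]] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated columns, "
                    f"got {line!r}"
                )
            gene, term = parts[0].strip(), parts[1].strip()
            terms.setdefault(term, set()).add(gene)
            n_rows += 1
    if n_rows == 0:
        warnings.warn(f"annotation file {path} is empty", stacklevel=2)
    return TermAnnotation(terms=terms)


def enrich(
    gene_set: set[str] | pd.Index,
    background: set[str] | pd.Index,
    annotation: TermAnnotation,
    fdr_cutoff: float = 0.05,
    min_term_size: int = 1,
    max_term_size: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_set`` within
    ``background``.

    For a term annotating K of the N background genes, with n query genes
    and overlap k, the p-value is the upper tail P(X >= k) of
    Hypergeom(N, K, n) and fold enrichment is (k/n) / (K/N).  Terms are
    intersected with the background before testing and reported only when
    k >= 1; BH FDR is computed across all tested terms and rows with
    FDR < ``fdr_cutoff`` are flagged significant.  Sorted by FDR, then p.
    """
    gene_set = set(gene_set)
    background = set(background)
    if not background:
        raise ValueError("background is empty")
    stray = gene_set - background
    if stray:
        raise ValueError(
            f"{len(stray)} query genes missing from the background, "
            f"e.g. {sorted(stray)[:5]}"
        )
    N = len(background)
    n = len(gene_set)
    rows = []
    for term, genes in annotation.terms.items():
        members = genes & background
        K = len(members)
        if K < min_term_size or K == 0:
            continue
        if max_term_size is not None and K > max_term_size:
            continue
        k = len(members & gene_set)
        if k < 1:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n else 0.0
        label = (annotation.labels or {}).get(term, term)
        rows.append((term, label, k, n, K, N, fold, p))
    out = pd.DataFrame(
        rows, columns=["term", "label", "k", "n", "K", "N", "fold", "p"]
    )
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["fdr"] < fdr_cutoff
        out = out.sort_values(["fdr", "p", "term"]).reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
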