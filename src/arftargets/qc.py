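"""Sample-level QC: PCA of log-normalized counts.

The study's qualitative QC claim is that samples separate by genotype more
than by auxin treatment; :func:`qc_pca` computes the first principal
components of log2(normalized counts + 1) and a centroid-spread diagnostic
quantifying exactly that comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class QcSummary:
    """PCA coordinates and genotype/treatment separation diagnostics."""

    coordinates: pd.DataFrame       # sample x PC scores
    variance_explained: np.ndarray  # fraction per component, non-increasing
    genotype_spread: float          # RMS distance of genotype centroids (PC1-2)
    treatment_spread: float         # RMS distance of treatment centroids (PC1-2)

    @property
    def spread_ratio(self) -> float:
        """genotype_spread / treatment_spread; > 1 means the samples
        separate more by genotype than by treatment."""
        return self.genotype_spread / self.treatment_spread


def _centroid_spread(coords: np.ndarray, groups: pd.Series) -> float:
    """RMS distance of group centroids from the grand centroid (PC1-2)."""
    centroids = np.stack(
        [coords[(groups == g).to_numpy()].mean(axis=0) for g in groups.unique()]
    )
    grand = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((centroids - grand) ** 2, axis=1))))


def qc_pca(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: pd.Series,
    n_components: int = 2,
) -> QcSummary:
    """PCA of log2(normalized counts + 1) across samples.

    Components are deterministic up to sign; the sign is fixed by making
    each component's largest-magnitude gene loading positive.  Requires at
    least 3 samples and a non-constant matrix.
    """
    if counts.shape[1] < 3:
        raise ValueError("need at least 3 samples for QC PCA")
    x = np.log2(
        counts.to_numpy(dtype=float) / factors.reindex(counts.columns).to_numpy()
        + 1.0
    )
    x = x - x.mean(axis=1, keepdims=True)  # center per gene
    if np.allclose(x, 0.0, atol=1e-10):
        raise ValueError("constant expression matrix; PCA undefined")
    # samples are observations: SVD of the samples x genes matrix
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    n_components = min(n_components, len(s))
    for j in range(n_components):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :n_components] * s[:n_components]
    var = s**2
    var_frac = (var / var.sum())[:n_components]
    coords = pd.DataFrame(
        scores,
        index=counts.columns,
        columns=[f"PC{j + 1}" for j in range(n_components)],
    )
    plane = scores[:, : min(2, n_components)]
    return QcSummary(
        coordinates=coords,
        variance_explained=var_frac,
        genotype_spread=_centroid_spread(plane, design.loc[counts.columns, "genotype"]),
        treatment_spread=_centroid_spread(plane, design.loc[counts.columns, "treatment"]),
    )
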