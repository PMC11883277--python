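"""Negative-binomial differential-expression engine.

Median-of-ratios size factors, per-gene method-of-moments dispersion, a
two-group NB Wald contrast, Benjamini-Hochberg adjustment, threshold-based
DEG sets and FPKM.  The engine is a deliberately simple stand-in for DESeq2:
no dispersion shrinkage, no independent filtering, no fold-change shrinkage.
Downstream classifiers consume only (log2FC, padj), so the engine is a
swappable interface, not a numerical clone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .factorial import GENOTYPES, TREATMENTS

DISPERSION_FLOOR = 1e-8
LOG2FC_CAP = 30.0


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    padj_(i) = min_{j >= i} ( n * p_(j) / j ), clipped to [0, 1], where (i)
    indexes p-values in ascending order.
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For every gene with nonzero counts in all samples, each sample's counts
    are divided by the gene's geometric mean across samples; the sample's
    size factor is the median of those ratios, rescaled so the factors'
    geometric mean is 1.
    """
    arr = counts.to_numpy(dtype=float)
    expressed = (arr > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logs = np.log(arr[expressed])
    log_ref = logs.mean(axis=1)
    s = np.exp(np.median(logs - log_ref[:, None], axis=0))
    s /= np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: pd.Series,
    floor: float = DISPERSION_FLOOR,
    prior_df: float = 30.0,
) -> pd.Series:
    """Per-gene method-of-moments NB dispersion, moderated across genes.

    Within every genotype x treatment cell with >= 2 replicates, the sample
    mean m and variance v of normalized counts estimate alpha through
    v ~= m * mean(1/s) + alpha * m**2 (the first term is the counting noise
    of normalized counts); m**2 is debiased to m**2 - v/n_c since the
    squared mean overestimates mu**2 by the mean's own variance.
    Cell-level moment contrasts are pooled across cells with df = n_c - 1
    weights.

    The raw per-gene estimate has only sum(n_c - 1) residual df, and its
    sampling noise would inflate downstream normal-tail Wald sizes well
    past nominal at typical replication.  Each estimate is therefore shrunk
    toward the across-gene mean of the raw estimates with ``prior_df``
    pseudo-degrees of freedom (edgeR-style moderation; ``prior_df=0``
    disables it), then floored at ``floor``.  The default prior weight is
    calibrated by null simulation so the Wald test holds its nominal size
    at 3 replicates per cell.
    """
    cells = []
    for g in GENOTYPES:
        for t in TREATMENTS:
            ids = design.index[
                (design["genotype"] == g) & (design["treatment"] == t)
            ]
            if len(ids) >= 2:
                cells.append(ids)
    if not cells:
        raise ValueError("no design cell has >= 2 replicates")

    norm = counts.to_numpy(dtype=float) / factors.reindex(counts.columns).to_numpy()
    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    cols = {c: i for i, c in enumerate(counts.columns)}
    inv_s = 1.0 / factors.reindex(counts.columns).to_numpy()
    for ids in cells:
        idx = [cols[c] for c in ids]
        sub = norm[:, idx]
        n_c = len(idx)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = n_c - 1
        num += w * (v - m * inv_s[idx].mean())
        den += w * np.maximum(m**2 - v / n_c, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, 0.0)
    if prior_df > 0:
        resid_df = sum(len(ids) - 1 for ids in cells)
        center = max(float(np.mean(raw)), floor)
        alpha = (resid_df * raw + prior_df * center) / (resid_df + prior_df)
    else:
        alpha = raw
    alpha = np.maximum(alpha, floor)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _fit_group_log_mean(
    k: np.ndarray, s: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """NB MLE of the per-gene group mean with size-factor offsets.

    Solves the score equation sum_j (k_ij - s_j mu_i) / (1 + alpha_i s_j
    mu_i) = 0 by Newton iteration (vectorised over genes) and returns
    (mu_hat, fisher_info) where the information is for eta = log mu:
    I = sum_j s_j mu / (1 + alpha s_j mu).  Genes with all-zero counts get
    mu_hat = 0 and information 0.
    """
    total = k.sum(axis=1)
    mu = k.mean(axis=1) / s.mean()
    mu = np.where(total > 0, np.maximum(mu, 1e-12), 0.0)
    active = total > 0
    for _ in range(100):
        denom = 1.0 + alpha[:, None] * np.outer(mu, s)
        f = ((k - mu[:, None] * s[None, :]) / denom).sum(axis=1)
        fp = -(s[None, :] * (1.0 + alpha[:, None] * k) / denom**2).sum(axis=1)
        step = np.where(active & (fp != 0), f / fp, 0.0)
        new = np.maximum(mu - step, mu * 1e-3)
        moved = np.abs(new - mu) > 1e-12 * (mu + 1e-12)
        mu = new
        if not moved.any():
            break
    with np.errstate(divide="ignore", invalid="ignore"):
        info = np.where(
            active,
            (np.outer(mu, s) / (1.0 + alpha[:, None] * np.outer(mu, s))).sum(axis=1),
            0.0,
        )
    return mu, info


def _resolve_cells(design: pd.DataFrame, group) -> pd.Index:
    """A group is a (genotype, treatment) cell or a list of such cells."""
    if isinstance(group, tuple):
        group = [group]
    ids: list[str] = []
    for g, t in group:
        cell = design.index[(design["genotype"] == g) & (design["treatment"] == t)]
        ids.extend(cell)
    return pd.Index(ids)


@dataclass
class ContrastTable:
    """Per-gene results of one two-group NB Wald contrast."""

    contrast_id: str
    table: pd.DataFrame  # baseMean, log2FC, stat, p, padj; tested genes only
    excluded: pd.Index   # genes with zero counts in all samples of both groups


def nb_wald_contrast(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: pd.Series,
    dispersions: pd.Series,
    group_a,
    group_b,
    contrast_id: str = "contrast",
) -> ContrastTable:
    """Wald test of group A vs group B under an NB model with offsets.

    log2FC = log2(mu_A) - log2(mu_B) from per-group NB fits; the Wald
    statistic is the estimate over its standard error (delta method on the
    per-group Fisher information) referred to the standard normal; BH is
    applied across all tested genes.  Genes with zero counts in every sample
    of both groups are excluded from testing and from BH.  When exactly one
    group's mean is zero the log2FC is capped at +/-30 and no significance
    is claimed (the Wald information degenerates).
    """
    ids_a = _resolve_cells(design, group_a)
    ids_b = _resolve_cells(design, group_b)
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError("both contrast groups must be non-empty")
    if len(ids_a.intersection(ids_b)) > 0:
        raise ValueError("contrast groups overlap")

    ka = counts[ids_a].to_numpy(dtype=float)
    kb = counts[ids_b].to_numpy(dtype=float)
    tested = (ka.sum(axis=1) + kb.sum(axis=1)) > 0
    excluded = counts.index[~tested]

    sa = factors.reindex(ids_a).to_numpy()
    sb = factors.reindex(ids_b).to_numpy()
    alpha = dispersions.reindex(counts.index).to_numpy()[tested]

    mu_a, info_a = _fit_group_log_mean(ka[tested], sa, alpha)
    mu_b, info_b = _fit_group_log_mean(kb[tested], sb, alpha)

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = (np.log2(mu_a) - np.log2(mu_b))
        lfc = np.clip(np.nan_to_num(lfc, nan=0.0, posinf=LOG2FC_CAP,
                                    neginf=-LOG2FC_CAP), -LOG2FC_CAP, LOG2FC_CAP)
        se = np.sqrt(
            np.where(info_a > 0, 1.0 / info_a, np.inf)
            + np.where(info_b > 0, 1.0 / info_b, np.inf)
        ) / np.log(2)
    stat = np.where(np.isfinite(se), lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(stat))
    padj = bh_adjust(p)

    norm_all = np.concatenate([ka[tested] / sa, kb[tested] / sb], axis=1)
    table = pd.DataFrame(
        {
            "baseMean": norm_all.mean(axis=1),
            "log2FC": lfc,
            "stat": stat,
            "p": p,
            "padj": padj,
        },
        index=counts.index[tested],
    )
    return ContrastTable(contrast_id=contrast_id, table=table, excluded=excluded)


@dataclass
class DEGSet:
    """Genes passing the significance (and optional fold) thresholds of one
    contrast, each with a direction sign (+1 up, -1 down)."""

    contrast_id: str
    directions: pd.Series          # gene_id -> +1 / -1 (int)
    tau_fdr: float = 0.05
    tau_lfc: float | None = None

    @property
    def genes(self) -> pd.Index:
        return self.directions.index

    def __len__(self) -> int:
        return len(self.directions)

    def __contains__(self, gene: str) -> bool:
        return gene in self.directions.index


def deg_set(
    contrast: ContrastTable,
    tau_fdr: float = 0.05,
    tau_lfc: float | None = None,
) -> DEGSet:
    """Threshold a contrast table: padj < tau_fdr and, when given,
    |log2FC| > tau_lfc.  Direction is the sign of log2FC."""
    if not (0 < tau_fdr <= 1):
        raise ValueError("tau_fdr must lie in (0, 1]")
    t = contrast.table
    keep = t["padj"] < tau_fdr
    if tau_lfc is not None:
        keep &= t["log2FC"].abs() > tau_lfc
    sel = t.loc[keep & (t["log2FC"] != 0)]
    directions = np.sign(sel["log2FC"]).astype(int)
    directions.name = "direction"
    return DEGSet(contrast.contrast_id, directions, tau_fdr, tau_lfc)


def compute_fpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """FPKM_ij = count_ij * 1e9 / (length_i[bp] * total_count_j)."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:5].tolist()
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    return counts * 1e9 / np.outer(lengths.to_numpy(), totals.to_numpy())
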