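"""Synthetic factorial RNA-seq counts with planted regulatory classes.

The generator emulates the study design the classifiers were built for:
4 genotypes x 2 auxin treatments x ``n_replicates`` biological replicates,
negative-binomial counts with a quadratic mean-variance relationship
(var = mu + alpha * mu**2), per-sample library size factors, and genes
planted in the regulatory-model classes the downstream analyses look for.

Planted classes
---------------
Three auxin-independent classes (a genotype effect of the same size and sign
under both treatments, no auxin response anywhere):

``redundant``        mis-regulated in the double mutant only
``ETT_specific``     mis-regulated in *ett* and in the double mutant
``ARF4_specific``    mis-regulated in *arf4* and in the double mutant

Three auxin-sensitivity (A-B ARF antagonism) classes, auxin-UPregulated in
the listed backgrounds and auxin-insensitive in wild type, with no baseline
genotype effect:

``redundant_prevention``       auxin response in the double mutant only
``heterodimer``                auxin response in all three mutants
``ARF4_specific_prevention``   auxin response in *arf4* and the double mutant

All remaining genes are ``null`` (no planted effect).  Auxin-independent
classes carry a random sign per gene (up or down, shared by all member
contrasts); the antagonism classes are planted upregulated, which is the
direction the antagonism model predicts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .factorial import (
    AUXIN_CONTRASTS,
    GENOTYPE_CONTRASTS,
    GENOTYPES,
    MUTANTS,
    TREATMENTS,
    auxin_contrast_id,
    genotype_contrast_id,
)


@dataclass(frozen=True)
class ClassTemplate:
    """Which design cells carry the planted effects for one class."""

    genotype_effect: frozenset[str]  # genotypes with a constitutive effect vs WT
    auxin_effect: frozenset[str]     # genotypes with an IAA-vs-mock response
    random_sign: bool                # if False the effect is planted upward


CLASS_TEMPLATES: dict[str, ClassTemplate] = {
    "redundant": ClassTemplate(frozenset({"ett_arf4"}), frozenset(), True),
    "ETT_specific": ClassTemplate(frozenset({"ett", "ett_arf4"}), frozenset(), True),
    "ARF4_specific": ClassTemplate(frozenset({"arf4", "ett_arf4"}), frozenset(), True),
    "redundant_prevention": ClassTemplate(frozenset(), frozenset({"ett_arf4"}), False),
    "heterodimer": ClassTemplate(
        frozenset(), frozenset({"ett", "arf4", "ett_arf4"}), False
    ),
    "ARF4_specific_prevention": ClassTemplate(
        frozenset(), frozenset({"arf4", "ett_arf4"}), False
    ),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic factorial experiment.

    Defaults follow the study design: three biological replicates per
    genotype x treatment cell, genotype effects (2.0 log2 units) larger than
    auxin-response effects (1.5 log2 units), moderate biological dispersion.
    """

    n_genes: int = 3200
    n_replicates: int = 3
    baseline_mean_range: tuple[float, float] = (20.0, 500.0)
    dispersion: float = 0.1
    genotype_lfc: float = 2.0
    auxin_lfc: float = 1.5
    library_size_factor_range: tuple[float, float] = (0.7, 1.3)
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {name: 0.0625 for name in CLASS_TEMPLATES}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        for name, (lo, hi) in (
            ("baseline_mean_range", self.baseline_mean_range),
            ("library_size_factor_range", self.library_size_factor_range),
        ):
            if lo <= 0 or hi <= 0 or lo > hi:
                raise ValueError(f"{name} must satisfy 0 < low <= high")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        unknown = set(self.class_fractions) - set(CLASS_TEMPLATES)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        fracs = list(self.class_fractions.values())
        if any(f < 0 for f in fracs):
            raise ValueError("class fractions must be non-negative")
        if sum(fracs) > 1 + 1e-12:
            raise ValueError("class fractions must sum to <= 1")


@dataclass
class GroundTruth:
    """Planted class labels, true per-contrast log2 fold changes and the
    true library size factors of a simulated experiment."""

    table: pd.DataFrame          # gene_id-indexed: class_label, direction, true_lfc_*
    size_factors: pd.Series      # sample_id -> true library scaling factor

    def genes_of_class(self, label: str) -> pd.Index:
        return self.table.index[self.table["class_label"] == label]


def generate_design(n_replicates: int = 3) -> pd.DataFrame:
    """Full-factorial sample sheet: 4 genotypes x 2 treatments x replicates.

    Samples are deterministically ordered (genotype, then treatment, then
    replicate) and named ``<genotype>_<treatment>_r<k>``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = [
        (f"{g}_{t}_r{r}", g, t, r)
        for g in GENOTYPES
        for t in TREATMENTS
        for r in range(1, n_replicates + 1)
    ]
    design = pd.DataFrame(
        rows, columns=["sample_id", "genotype", "treatment", "replicate"]
    ).set_index("sample_id")
    return design


def _assign_classes(config: SimulationConfig) -> list[str]:
    """Deterministic block assignment of genes to classes; remainder null."""
    labels: list[str] = []
    for name in CLASS_TEMPLATES:
        frac = config.class_fractions.get(name, 0.0)
        labels.extend([name] * int(round(frac * config.n_genes)))
    if len(labels) > config.n_genes:
        raise ValueError("class fractions must sum to <= 1")
    labels.extend(["null"] * (config.n_genes - len(labels)))
    return labels


def _true_lfc_table(labels: list[str], signs: np.ndarray,
                    config: SimulationConfig) -> pd.DataFrame:
    """True log2 fold change of every gene in each of the 10 contrasts.

    The planted mean model is log2 mu(g, t) = log2 baseline
    + sign * genotype_lfc * [g in genotype_effect]
    + sign * auxin_lfc * [t == IAA and g in auxin_effect], so a genotype
    contrast under IAA also picks up any planted auxin response (wild type
    never carries one).
    """
    n = len(labels)
    cols: dict[str, np.ndarray] = {
        f"true_lfc_{cid}": np.zeros(n) for cid in GENOTYPE_CONTRASTS + AUXIN_CONTRASTS
    }
    for i, label in enumerate(labels):
        if label == "null":
            continue
        tpl = CLASS_TEMPLATES[label]
        s = signs[i]
        for g in MUTANTS:
            geno = config.genotype_lfc * s if g in tpl.genotype_effect else 0.0
            aux = config.auxin_lfc * s if g in tpl.auxin_effect else 0.0
            cols[f"true_lfc_{genotype_contrast_id(g, 'mock')}"][i] = geno
            cols[f"true_lfc_{genotype_contrast_id(g, 'IAA')}"][i] = geno + aux
        for g in GENOTYPES:
            aux = config.auxin_lfc * s if g in tpl.auxin_effect else 0.0
            cols[f"true_lfc_{auxin_contrast_id(g)}"][i] = aux
    return pd.DataFrame(cols)


def generate_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a factorial experiment with planted regulatory classes.

    Returns ``(counts, design, truth)`` where ``counts`` is a gene x sample
    integer DataFrame, ``design`` the sample sheet from
    :func:`generate_design`, and ``truth`` the planted ground truth.  Counts
    are NB(mu, alpha) with mu = baseline * 2**(planted effects) * size
    factor.  The same config and seed reproduce the output bit for bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = generate_design(config.n_replicates)
    n_samples = len(design)

    gene_ids = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    labels = _assign_classes(config)

    lo, hi = config.baseline_mean_range
    baseline = 10 ** rng.uniform(np.log10(lo), np.log10(hi), config.n_genes)

    signs = np.zeros(config.n_genes)
    for i, label in enumerate(labels):
        if label == "null":
            continue
        if CLASS_TEMPLATES[label].random_sign:
            signs[i] = rng.choice([-1.0, 1.0])
        else:
            signs[i] = 1.0

    sf_lo, sf_hi = config.library_size_factor_range
    size_factors = rng.uniform(sf_lo, sf_hi, n_samples)

    # per-gene, per-sample log2 effect
    eta = np.zeros((config.n_genes, n_samples))
    geno = design["genotype"].to_numpy()
    iaa = (design["treatment"] == "IAA").to_numpy()
    for i, label in enumerate(labels):
        if label == "null":
            continue
        tpl = CLASS_TEMPLATES[label]
        in_geno = np.isin(geno, list(tpl.genotype_effect))
        in_aux = np.isin(geno, list(tpl.auxin_effect)) & iaa
        eta[i] = signs[i] * (
            config.genotype_lfc * in_geno + config.auxin_lfc * in_aux
        )

    mu = baseline[:, None] * 2.0**eta * size_factors[None, :]
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=design.index)
    truth_tbl = _true_lfc_table(labels, signs, config)
    truth_tbl.index = counts_df.index
    direction = np.where(signs > 0, "up", np.where(signs < 0, "down", "none"))
    truth_tbl.insert(0, "class_label", labels)
    truth_tbl.insert(1, "direction", direction)
    truth = GroundTruth(
        table=truth_tbl,
        size_factors=pd.Series(size_factors, index=design.index, name="size_factor"),
    )
    return counts_df, design, truth


def write_fixture(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    truth: GroundTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write counts/design/truth TSVs that round-trip losslessly."""
    if counts.shape[0] == 0:
        raise ValueError("empty gene set: nothing to write")
    if not counts.columns.equals(design.index):
        raise ValueError("counts columns and design samples disagree")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "design": directory / "design.tsv",
        "truth": directory / "truth.tsv",
        "size_factors": directory / "true_size_factors.tsv",
    }
    counts.to_csv(paths["counts"], sep="\t")
    design.to_csv(paths["design"], sep="\t")
    truth.table.to_csv(paths["truth"], sep="\t")
    truth.size_factors.to_frame().to_csv(paths["size_factors"], sep="\t")
    return paths
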