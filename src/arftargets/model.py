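"""Model/Results interface for the full comparative analysis.

:class:`FactorialTargetModel` wraps a validated count matrix plus design
table; :meth:`FactorialTargetModel.fit` runs normalization, dispersion
estimation and all ten NB Wald contrasts, then both target classifications,
returning a :class:`FactorialTargetResults` that carries the estimates and
downstream tables and knows how to summarise and score itself.

>>> from arftargets import FactorialTargetModel, SimulationConfig
>>> model = FactorialTargetModel.simulate(SimulationConfig(seed=7))
>>> res = model.fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import de, independent, qc, sensitive
from .enrich import TermAnnotation, enrich as _enrich
from .factorial import (
    AUXIN_CONTRASTS,
    GENOTYPE_CONTRASTS,
    MUTANTS,
    TREATMENTS,
    auxin_contrast_id,
    genotype_contrast_id,
)
from .io import require_full_grid, read_counts, read_design, validate_matching
from .simulate import GroundTruth, SimulationConfig, generate_counts


class FactorialTargetModel:
    """ETT/ARF4 target-classification model for a 4 x 2 factorial count
    matrix.

    Parameters
    ----------
    counts : DataFrame
        Gene x sample non-negative integer counts.
    design : DataFrame
        Sample-indexed table with ``genotype``, ``treatment`` and
        ``replicate`` columns covering the full factorial grid.
    truth : GroundTruth, optional
        Planted ground truth (attached automatically by :meth:`simulate`);
        enables :meth:`FactorialTargetResults.recovery`.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        design: pd.DataFrame,
        truth: GroundTruth | None = None,
    ) -> None:
        validate_matching(counts, design)
        require_full_grid(design)
        self.counts = counts
        self.design = design
        self.truth = truth

    @classmethod
    def from_tsv(cls, counts_path: str | Path, design_path: str | Path):
        return cls(read_counts(counts_path), read_design(design_path))

    @classmethod
    def simulate(cls, config: SimulationConfig | None = None, **kwargs):
        """Build a model from a synthetic experiment with planted classes."""
        config = config or SimulationConfig(**kwargs)
        counts, design, truth = generate_counts(config)
        return cls(counts, design, truth=truth)

    def fit(
        self,
        tau_fdr: float = 0.05,
        tau_lfc: float = 1.0,
        auxin_fold_gate: bool = True,
        strict_arf4_prevention: bool = True,
    ) -> "FactorialTargetResults":
        """Run the DE engine and both classification analyses.

        ``auxin_fold_gate`` applies the twofold |log2FC| gate to the four
        auxin-response DEG lists of the auxin-sensitive analysis;
        ``strict_arf4_prevention`` keeps *ett*-responding genes out of the
        ARF4-specific-prevention model segment.
        """
        factors = de.size_factors(self.counts)
        dispersions = de.estimate_dispersion(self.counts, self.design, factors)

        contrasts: dict[str, de.ContrastTable] = {}
        for t in TREATMENTS:
            for g in MUTANTS:
                cid = genotype_contrast_id(g, t)
                contrasts[cid] = de.nb_wald_contrast(
                    self.counts, self.design, factors, dispersions,
                    group_a=(g, t), group_b=("WT", t), contrast_id=cid,
                )
        for g in ("WT",) + MUTANTS:
            cid = auxin_contrast_id(g)
            contrasts[cid] = de.nb_wald_contrast(
                self.counts, self.design, factors, dispersions,
                group_a=(g, "IAA"), group_b=(g, "mock"), contrast_id=cid,
            )

        genotype_tables = {c: contrasts[c] for c in GENOTYPE_CONTRASTS}
        auxin_tables = {c: contrasts[c] for c in AUXIN_CONTRASTS}

        # auxin-sensitivity removal always uses the twofold-gated sets,
        # matching the removal rule's own wording
        removal_sets = sensitive.build_four_lists(
            auxin_tables, tau_fdr=tau_fdr, tau_lfc=tau_lfc
        )
        auxin_independent = independent.run_auxin_independent(
            genotype_tables, removal_sets, tau_fdr=tau_fdr, tau_lfc=tau_lfc
        )

        partition4, conformance = sensitive.run_auxin_sensitive(
            auxin_tables,
            tau_fdr=tau_fdr,
            tau_lfc=tau_lfc if auxin_fold_gate else None,
            strict_arf4_prevention=strict_arf4_prevention,
        )

        return FactorialTargetResults(
            model=self,
            size_factors=factors,
            dispersions=dispersions,
            contrasts=contrasts,
            auxin_independent=auxin_independent,
            partition4=partition4,
            antagonism=conformance,
            tau_fdr=tau_fdr,
            tau_lfc=tau_lfc,
            auxin_fold_gate=auxin_fold_gate,
            strict_arf4_prevention=strict_arf4_prevention,
        )


@dataclass
class FactorialTargetResults:
    """Fitted estimates and classification tables of one analysis run."""

    model: FactorialTargetModel
    size_factors: pd.Series
    dispersions: pd.Series
    contrasts: dict[str, de.ContrastTable]
    auxin_independent: pd.DataFrame       # gene-indexed assignment table
    partition4: sensitive.VennPartition4
    antagonism: sensitive.AntagonismConformance
    tau_fdr: float
    tau_lfc: float
    auxin_fold_gate: bool
    strict_arf4_prevention: bool

    @property
    def classified(self) -> pd.DataFrame:
        """Auxin-independent assignments surviving the sensitivity removal."""
        a = self.auxin_independent
        return a.loc[~a["removed_auxin_sensitive"]]

    @property
    def expressed_genes(self) -> pd.Index:
        """All tested genes: the enrichment background."""
        any_table = next(iter(self.contrasts.values()))
        return any_table.table.index

    def class_counts(self) -> pd.DataFrame:
        """Per regulatory-model label: total, up and down gene counts."""
        rows = []
        for label, sub in self.classified.groupby("model_label"):
            rows.append(
                (
                    label,
                    len(sub),
                    int((sub["direction"] == "up").sum()),
                    int((sub["direction"] == "down").sum()),
                )
            )
        return pd.DataFrame(
            rows, columns=["model_label", "n", "n_up", "n_down"]
        ).set_index("model_label")

    def genes_of_label(self, label: str) -> pd.Index:
        return self.classified.index[self.classified["model_label"] == label]

    def enrich(
        self,
        label: str,
        annotation: TermAnnotation,
        fdr_cutoff: float = 0.05,
    ) -> pd.DataFrame:
        """Over-representation of one labelled class against the
        expressed-gene background."""
        genes = set(self.genes_of_label(label)) & set(self.expressed_genes)
        return _enrich(
            genes, self.expressed_genes, annotation, fdr_cutoff=fdr_cutoff
        )

    def qc(self) -> qc.QcSummary:
        return qc.qc_pca(self.model.counts, self.model.design, self.size_factors)

    def recovery(self) -> pd.DataFrame:
        """Planted-class recovery metrics against the simulation truth.

        For the auxin-independent classes: the fraction of planted genes
        receiving their planted label.  For the antagonism classes: the
        fraction recovered into the model's Venn segment (sensitivity) and,
        among those, the fraction conforming (upregulated in all member
        genotypes).  Also reports the fraction of null genes receiving any
        auxin-independent label.
        """
        if self.model.truth is None:
            raise ValueError("no ground truth attached to this model")
        truth = self.model.truth.table
        rows = []
        for label in ("redundant", "ETT_specific", "ARF4_specific"):
            planted = truth.index[truth["class_label"] == label]
            if len(planted) == 0:
                continue
            got = self.genes_of_label(label)
            rows.append((label, len(planted), len(planted.intersection(got)) / len(planted)))
        null = truth.index[truth["class_label"] == "null"]
        if len(null):
            labelled = self.classified.index[self.classified["model_label"].notna()]
            rows.append(("null_labelled", len(null),
                         len(null.intersection(labelled)) / len(null)))
        seg_tbl = self.partition4.table
        for label, members in sensitive.ANTAGONISM_MODELS.items():
            planted = truth.index[truth["class_label"] == label]
            if len(planted) == 0:
                continue
            seg = sensitive.segment_name4(members)
            in_seg = seg_tbl.index[seg_tbl["segment"] == seg]
            recovered = planted.intersection(in_seg)
            rows.append((f"{label}_segment", len(planted),
                         len(recovered) / len(planted)))
            if len(recovered):
                conf = self.antagonism.assignments.loc[recovered, "conforming"]
                rows.append((f"{label}_conformance", len(recovered),
                             float(conf.mean())))
        return pd.DataFrame(
            rows, columns=["metric", "n", "fraction"]
        ).set_index("metric")

    def summary(self) -> str:
        """Human-readable run summary."""
        lines = [
            "ETT/ARF4 factorial target classification",
            "=" * 44,
            f"genes tested          {len(self.expressed_genes)}",
            f"samples               {len(self.model.design)}",
            f"thresholds            padj < {self.tau_fdr}, |log2FC| > {self.tau_lfc}",
            f"median dispersion     {self.dispersions.median():.4f}",
            "",
            "Auxin-independent classes (post removal):",
        ]
        cc = self.class_counts()
        if len(cc) == 0:
            lines.append("  (none)")
        for label, row in cc.iterrows():
            lines.append(
                f"  {label:<28s} {row['n']:>5d}  "
                f"({row['n_up']} up / {row['n_down']} down)"
            )
        removed = int(self.auxin_independent["removed_auxin_sensitive"].sum())
        lines.append(f"  removed as auxin-sensitive   {removed:>5d}")
        lines.append("")
        lines.append("A-B ARF antagonism conformance:")
        for m, row in self.antagonism.tallies.iterrows():
            lines.append(
                f"  {m:<28s} {row['n_conforming']:>5d} / {row['n_total']}"
                f" conforming ({row['n_up']} up / {row['n_down']} down)"
            )
        return "\n".join(lines)
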