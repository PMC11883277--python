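"""Auxin-independent ETT/ARF4 target classification.

Starting from the six mutant-vs-WT contrasts (three mutants under mock and
under IAA), the analysis:

1. builds six DEG lists (padj < 0.05) restricted to genes at least twofold
   up- or down-regulated (|log2FC| > 1) in at least one of the six contrasts;
2. partitions each treatment's three lists by a three-way Venn diagram;
3. keeps genes mis-regulated in the same manner under mock and IAA
   (identical Venn segment and identical direction in every member list);
4. removes genes that are themselves auxin-responsive in any genotype;
5. maps the surviving genes' Venn segment to a regulatory-model label:
   {ett, ett_arf4} -> ETT-specific, {arf4, ett_arf4} -> ARF4-specific,
   {ett_arf4} alone -> redundant regulation; other segments keep a
   pattern-derived label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import ContrastTable, DEGSet, deg_set
from .factorial import (
    AUXIN_CONTRASTS,
    GENOTYPE_CONTRASTS,
    GENOTYPES,
    MUTANTS,
    TREATMENTS,
    genotype_contrast_id,
)

#: fixed member order of the three-way Venn (bitmask order)
SEGMENT_ORDER: tuple[str, ...] = ("ett", "arf4", "ett_arf4")

#: Venn segment -> regulatory-model label for the three named models
MODEL_LABELS: dict[frozenset[str], str] = {
    frozenset({"ett", "ett_arf4"}): "ETT_specific",
    frozenset({"arf4", "ett_arf4"}): "ARF4_specific",
    frozenset({"ett_arf4"}): "redundant",
}


def segment_name(members: frozenset[str]) -> str:
    """Canonical '+'-joined segment name in fixed bitmask order."""
    return "+".join(m for m in SEGMENT_ORDER if m in members)


def build_six_lists(
    contrasts: dict[str, ContrastTable],
    tau_fdr: float = 0.05,
    tau_lfc: float = 1.0,
) -> dict[str, DEGSet]:
    """Six genotype-vs-WT DEG lists with the global twofold inclusion rule.

    Per-list membership is padj < tau_fdr; a gene is then retained anywhere
    only if |log2FC| > tau_lfc in at least one of the six contrasts, so a
    gene just under twofold in one background stays in that background's
    list when another background carries it over the threshold.
    """
    expected = set(GENOTYPE_CONTRASTS)
    if set(contrasts) != expected:
        raise ValueError(
            f"need exactly the six genotype-vs-WT contrasts {sorted(expected)}"
        )
    included: set[str] = set()
    for ct in contrasts.values():
        t = ct.table
        included.update(t.index[t["log2FC"].abs() > tau_lfc])
    sets: dict[str, DEGSet] = {}
    for cid, ct in contrasts.items():
        full = deg_set(ct, tau_fdr=tau_fdr, tau_lfc=None)
        keep = full.directions.index.isin(included)
        sets[cid] = DEGSet(cid, full.directions[keep], tau_fdr, tau_lfc)
    return sets


@dataclass
class VennPartition3:
    """Disjoint three-way Venn partition of DEG sets from one treatment.

    ``table`` is indexed by every gene in the union, with boolean membership
    columns (one per mutant), int direction columns ``dir_<mutant>`` (+1/-1,
    0 if not a member) and a ``segment`` name column.
    """

    treatment: str
    table: pd.DataFrame

    def segment_counts(self) -> pd.Series:
        return self.table["segment"].value_counts()


def three_way_partition(
    sets: dict[str, DEGSet], treatment: str
) -> VennPartition3:
    """Assign every gene in the union of the three mutant DEG sets of one
    treatment to exactly one of the 7 non-empty Venn segments."""
    by_mutant = {}
    for g in SEGMENT_ORDER:
        cid = genotype_contrast_id(g, treatment)
        if cid not in sets:
            raise ValueError(f"missing DEG set for contrast {cid}")
        by_mutant[g] = sets[cid]
    universe = pd.Index(sorted(set().union(*(s.genes for s in by_mutant.values()))))
    data: dict[str, object] = {}
    for g, s in by_mutant.items():
        data[g] = universe.isin(s.genes)
        data[f"dir_{g}"] = (
            s.directions.reindex(universe).fillna(0).astype(int).to_numpy()
        )
    table = pd.DataFrame(data, index=universe)
    table["segment"] = [
        segment_name(frozenset(g for g in SEGMENT_ORDER if row[g]))
        for _, row in table.iterrows()
    ]
    return VennPartition3(treatment, table)


def cross_treatment_match(
    mock: VennPartition3, iaa: VennPartition3
) -> pd.Index:
    """Genes mis-regulated in the same manner under mock and IAA: identical
    Venn segment and identical direction sign in every member contrast."""
    common = mock.table.index.intersection(iaa.table.index)
    m = mock.table.loc[common]
    i = iaa.table.loc[common]
    same_segment = m["segment"] == i["segment"]
    same_dirs = np.ones(len(common), dtype=bool)
    for g in SEGMENT_ORDER:
        same_dirs &= (m[f"dir_{g}"] == i[f"dir_{g}"]).to_numpy()
    return common[same_segment.to_numpy() & same_dirs]


def classify(
    matched: pd.Index,
    mock: VennPartition3,
    iaa: VennPartition3,
    auxin_response_sets: dict[str, DEGSet],
) -> pd.DataFrame:
    """Label cross-treatment-matched genes by their regulatory model.

    Genes significantly auxin-responsive (per the supplied within-genotype
    IAA-vs-mock DEG sets, any of the four genotypes) are flagged
    ``removed_auxin_sensitive`` and carry no model label.  Survivors are
    labelled from their Venn segment via :data:`MODEL_LABELS`; unnamed
    segments get ``segment_<pattern>`` labels.  Direction is up/down when
    all member contrasts agree, else ``mixed``.
    """
    missing = set(AUXIN_CONTRASTS) - set(auxin_response_sets)
    if missing:
        raise ValueError(f"missing auxin-response DEG sets: {sorted(missing)}")
    auxin_sensitive: set[str] = set()
    for s in auxin_response_sets.values():
        auxin_sensitive.update(s.genes)

    rows = []
    for gene in matched:
        seg = mock.table.at[gene, "segment"]
        members = frozenset(seg.split("+"))
        dirs = {
            g: int(mock.table.at[gene, f"dir_{g}"]) for g in members
        }
        uniq = set(dirs.values())
        direction = {1: "up", -1: "down"}[uniq.pop()] if len(uniq) == 1 else "mixed"
        removed = gene in auxin_sensitive
        label = (
            None
            if removed
            else MODEL_LABELS.get(members, f"segment_{segment_name(members)}")
        )
        rows.append(
            (
                gene,
                seg,
                iaa.table.at[gene, "segment"],
                direction,
                removed,
                label,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "segment_mock",
            "segment_iaa",
            "direction",
            "removed_auxin_sensitive",
            "model_label",
        ],
    ).set_index("gene_id")
    return out


def run_auxin_independent(
    genotype_contrasts: dict[str, ContrastTable],
    auxin_response_sets: dict[str, DEGSet],
    tau_fdr: float = 0.05,
    tau_lfc: float = 1.0,
) -> pd.DataFrame:
    """End-to-end auxin-independent analysis from contrast tables."""
    six = build_six_lists(genotype_contrasts, tau_fdr=tau_fdr, tau_lfc=tau_lfc)
    mock = three_way_partition(six, "mock")
    iaa = three_way_partition(six, "IAA")
    matched = cross_treatment_match(mock, iaa)
    return classify(matched, mock, iaa, auxin_response_sets)
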