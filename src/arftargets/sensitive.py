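"""Auxin-sensitive analysis and A-B ARF antagonism conformance.

The four within-genotype IAA-vs-mock DEG lists (wild type and the three
B-ARF mutants) are partitioned by a four-way Venn diagram; three segments
map onto models of A-B ARF antagonism, under which repressive B-ARFs block
the auxin response that activating A-ARFs would otherwise drive:

``redundant_prevention``      auxin-sensitive only in the double mutant
``heterodimer``               auxin-sensitive in all three mutants, not WT
``ARF4_specific_prevention``  auxin-sensitive in *arf4* and the double
                              mutant (strictly excluding *ett* by default)

A gene *conforms* to its model when it is auxin-UPregulated in every member
genotype (wild-type insensitivity is implied by segment membership).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import ContrastTable, DEGSet, deg_set
from .factorial import AUXIN_CONTRASTS, GENOTYPES, auxin_contrast_id

#: fixed member order of the four-way Venn (bitmask order)
SEGMENT_ORDER4: tuple[str, ...] = ("WT", "ett", "arf4", "ett_arf4")

#: antagonism model -> exact Venn segment (strict reading)
ANTAGONISM_MODELS: dict[str, frozenset[str]] = {
    "redundant_prevention": frozenset({"ett_arf4"}),
    "heterodimer": frozenset({"ett", "arf4", "ett_arf4"}),
    "ARF4_specific_prevention": frozenset({"arf4", "ett_arf4"}),
}


def segment_name4(members: frozenset[str]) -> str:
    return "+".join(m for m in SEGMENT_ORDER4 if m in members)


def build_four_lists(
    contrasts: dict[str, ContrastTable],
    tau_fdr: float = 0.05,
    tau_lfc: float | None = 1.0,
) -> dict[str, DEGSet]:
    """The four within-genotype auxin-response DEG lists.

    Membership is padj < tau_fdr and, by default, |log2FC| > tau_lfc (the
    twofold gate applied for symmetry with the auxin-independent analysis;
    pass ``tau_lfc=None`` for the significance-only reading).
    """
    expected = set(AUXIN_CONTRASTS)
    if set(contrasts) != expected:
        raise ValueError(
            f"need exactly the four auxin-response contrasts {sorted(expected)}"
        )
    return {
        cid: deg_set(ct, tau_fdr=tau_fdr, tau_lfc=tau_lfc)
        for cid, ct in contrasts.items()
    }


@dataclass
class VennPartition4:
    """Disjoint four-way Venn partition of the auxin-response DEG sets.

    ``table``: gene-indexed, boolean membership per genotype, int direction
    columns ``dir_<genotype>`` and a ``segment`` name column.
    """

    table: pd.DataFrame

    def segment_counts(self) -> pd.Series:
        return self.table["segment"].value_counts()


def four_way_partition(sets: dict[str, DEGSet]) -> VennPartition4:
    """Assign every gene in the union of the four auxin-response sets to
    exactly one of the 15 non-empty Venn segments."""
    by_geno = {}
    for g in SEGMENT_ORDER4:
        cid = auxin_contrast_id(g)
        if cid not in sets:
            raise ValueError(f"missing DEG set for contrast {cid}")
        by_geno[g] = sets[cid]
    universe = pd.Index(sorted(set().union(*(s.genes for s in by_geno.values()))))
    data: dict[str, object] = {}
    for g, s in by_geno.items():
        data[g] = universe.isin(s.genes)
        data[f"dir_{g}"] = (
            s.directions.reindex(universe).fillna(0).astype(int).to_numpy()
        )
    table = pd.DataFrame(data, index=universe)
    table["segment"] = [
        segment_name4(frozenset(g for g in SEGMENT_ORDER4 if row[g]))
        for _, row in table.iterrows()
    ]
    return VennPartition4(table)


@dataclass
class AntagonismConformance:
    """Per-model tallies of the antagonism-conformance scoring.

    ``n_up``/``n_down`` count genes whose auxin response is concordantly up
    (resp. down) in every member genotype; genes with discordant directions
    across members are counted in ``n_total`` and ``n_discordant`` only.
    ``n_conforming`` equals ``n_up``: the models predict auxin
    UPregulation in all member genotypes and insensitivity in wild type.
    """

    tallies: pd.DataFrame      # model-indexed: n_total, n_up, n_down, n_discordant, n_conforming
    assignments: pd.DataFrame  # gene-indexed: segment, model_id, conforming


def score_antagonism(
    partition: VennPartition4,
    strict_arf4_prevention: bool = True,
) -> AntagonismConformance:
    """Score the three highlighted Venn segments against the antagonism
    models.

    With ``strict_arf4_prevention=False`` the ARF4-specific-prevention
    model also admits genes that additionally respond in *ett* (the
    permissive reading); such genes then match the heterodimer model too
    and are assigned to the heterodimer, but counted in both tallies.
    """
    t = partition.table
    rows = []
    assign: dict[str, tuple[str, str, bool]] = {}
    for model, members in ANTAGONISM_MODELS.items():
        in_seg = t["segment"] == segment_name4(members)
        if model == "ARF4_specific_prevention" and not strict_arf4_prevention:
            in_seg = in_seg | (
                t["segment"] == segment_name4(frozenset({"ett", "arf4", "ett_arf4"}))
            )
        sub = t.loc[in_seg]
        dirs = sub[[f"dir_{g}" for g in SEGMENT_ORDER4 if g in members]]
        # members of the wider permissive segment still score on their own members
        all_up = (dirs > 0).all(axis=1) if len(sub) else pd.Series(dtype=bool)
        all_down = (dirs < 0).all(axis=1) if len(sub) else pd.Series(dtype=bool)
        n_up = int(all_up.sum())
        n_down = int(all_down.sum())
        n_total = len(sub)
        rows.append(
            (model, n_total, n_up, n_down, n_total - n_up - n_down, n_up)
        )
        for gene, up in all_up.items():
            seg = t.at[gene, "segment"]
            if gene not in assign or seg == segment_name4(members):
                assign[gene] = (seg, model, bool(up))
    tallies = pd.DataFrame(
        rows,
        columns=["model", "n_total", "n_up", "n_down", "n_discordant", "n_conforming"],
    ).set_index("model")

    # full per-gene table: every gene in the union, model where applicable
    seg_to_model = {
        segment_name4(m): name for name, m in ANTAGONISM_MODELS.items()
    }
    genes = []
    for gene, row in t.iterrows():
        model = seg_to_model.get(row["segment"])
        conforming = bool(assign[gene][2]) if gene in assign and model else False
        genes.append((gene, row["segment"], model, conforming))
    assignments = pd.DataFrame(
        genes, columns=["gene_id", "segment", "model_id", "conforming"]
    ).set_index("gene_id")
    return AntagonismConformance(tallies=tallies, assignments=assignments)


def run_auxin_sensitive(
    auxin_contrasts: dict[str, ContrastTable],
    tau_fdr: float = 0.05,
    tau_lfc: float | None = 1.0,
    strict_arf4_prevention: bool = True,
) -> tuple[VennPartition4, AntagonismConformance]:
    """End-to-end auxin-sensitive analysis from contrast tables."""
    four = build_four_lists(auxin_contrasts, tau_fdr=tau_fdr, tau_lfc=tau_lfc)
    partition = four_way_partition(four)
    conformance = score_antagonism(partition, strict_arf4_prevention)
    return partition, conformance
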