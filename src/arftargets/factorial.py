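"""Vocabulary of the 4 genotype x 2 treatment factorial design.

The experiment crosses four Arabidopsis lines -- wild type (``WT``), the two
single B-ARF mutants (``ett``, ``arf4``) and the double mutant (``ett_arf4``)
-- with a mock and an auxin (IAA) treatment.  Ten contrasts are analysed:
six genotype-vs-wild-type contrasts (three mutants under each treatment) and
four within-genotype auxin-response contrasts.
"""

from __future__ import annotations

GENOTYPES: tuple[str, ...] = ("WT", "ett", "arf4", "ett_arf4")
MUTANTS: tuple[str, ...] = ("ett", "arf4", "ett_arf4")
TREATMENTS: tuple[str, ...] = ("mock", "IAA")


def genotype_contrast_id(genotype: str, treatment: str) -> str:
    """Identifier of a mutant-vs-WT contrast within one treatment."""
    if genotype not in MUTANTS:
        raise ValueError(f"not a mutant genotype: {genotype!r}")
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment: {treatment!r}")
    return f"{genotype}_vs_WT_{treatment}"


def auxin_contrast_id(genotype: str) -> str:
    """Identifier of the IAA-vs-mock contrast within one genotype."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype: {genotype!r}")
    return f"IAA_vs_mock_{genotype}"


#: the six genotype-vs-WT contrast ids (mock first, then IAA)
GENOTYPE_CONTRASTS: tuple[str, ...] = tuple(
    genotype_contrast_id(g, t) for t in TREATMENTS for g in MUTANTS
)

#: the four within-genotype auxin-response contrast ids
AUXIN_CONTRASTS: tuple[str, ...] = tuple(auxin_contrast_id(g) for g in GENOTYPES)

ALL_CONTRASTS: tuple[str, ...] = GENOTYPE_CONTRASTS + AUXIN_CONTRASTS
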