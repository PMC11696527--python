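"""Release-strategy presets: YLE strains and comparator self-limiting tools.

Each preset bundles a genotype space, germline-editing parameters, a
phenotype map and the released male genotype:

* ``yle_dsx_b`` — the engineered strain baseline: 94.5% transmission of the
  dominant female-sterilising allele, a 3% rate of new recessive target
  mutations, and a fitted 22% mating-competitiveness cost.
* ``optimal_yle`` — an idealised editor: perfect transmission, fully
  penetrant dominant sterility, no cost.
* ``optimal_sit`` — sterile, fully competitive released males.
* ``optimal_ridl`` / ``optimal_fs_ridl`` — released males homozygous for a
  dominant construct lethal after density-dependent larval competition, in
  both sexes or in females only.
* ``optimal_xshredder`` — released males homozygous for an idealised
  autosomal X-shredder (complete shredding, no cost).
* ``yle_dsx_b_xshredder_het`` / ``_hom`` — the engineered-strain YLE combined
  with an idealised X-shredder carried het- or homozygously.

Optimal autosomal strategies release homozygous males.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .genetics import (
    ConstructAllele,
    EditingParams,
    Genotype,
    LociConfig,
    Lethality,
    PhenotypeParams,
    ShredderAllele,
    TargetAllele,
    YAllele,
)

__all__ = [
    "StrategyPreset",
    "strategy_preset",
    "STRATEGY_NAMES",
    "STRAIN_B_EDITING",
    "STRAIN_B_PHENOTYPE",
]

#: Engineered-strain germline baseline.  ``nhej_given_cleave`` solves
#: 0.5*(1 + C*(1-j)) = 0.945 and 0.5*C*j = 0.030 at C = 0.95, i.e. gametes of
#: a heterozygous YLE male carry the dominant allele with probability 0.945
#: and a new recessive mutation with probability 0.030.
STRAIN_B_EDITING = EditingParams(
    cleave_het=0.95,
    nhej_given_cleave=0.06 / 0.95,
    p_dom_new=0.0,
    mut_wtwt=0.945,
    shred_eff=0.0,
)

#: Fully penetrant dominant sterility; 22% YLE-male competitiveness cost.
STRAIN_B_PHENOTYPE = PhenotypeParams(
    dom_released=1.0, dom_new=1.0, yle_male_cost=0.22
)

_WT = TargetAllele.WT
_DOM = TargetAllele.DOM_R
_NO_EDITING = EditingParams(
    cleave_het=0.0, nhej_given_cleave=0.0, p_dom_new=0.0, mut_wtwt=0.0, shred_eff=0.0
)


@dataclass(frozen=True)
class StrategyPreset:
    """Fully specified parameter bundle for one release strategy."""

    name: str
    loci: LociConfig
    editing: EditingParams
    phen: PhenotypeParams
    released: Genotype


def _yle_dsx_b() -> StrategyPreset:
    return StrategyPreset(
        name="yle_dsx_b",
        loci=LociConfig.base(),
        editing=STRAIN_B_EDITING,
        phen=STRAIN_B_PHENOTYPE,
        released=Genotype.male(YAllele.Y_YLE, (_WT, _DOM)),
    )


def _optimal_yle() -> StrategyPreset:
    return StrategyPreset(
        name="optimal_yle",
        loci=LociConfig.base(),
        editing=EditingParams(
            cleave_het=1.0, nhej_given_cleave=0.0, p_dom_new=0.0, mut_wtwt=0.0,
            shred_eff=0.0,
        ),
        phen=PhenotypeParams(dom_released=1.0, dom_new=1.0, yle_male_cost=0.0),
        released=Genotype.male(YAllele.Y_YLE, (_WT, _DOM)),
    )


def _construct_preset(name: str, sterile: bool, lethality: Lethality) -> StrategyPreset:
    loci = LociConfig((_WT,), construct=True)
    hom = (ConstructAllele.L_CON, ConstructAllele.L_CON)
    return StrategyPreset(
        name=name,
        loci=loci,
        editing=_NO_EDITING,
        phen=PhenotypeParams(
            dom_released=1.0, dom_new=1.0, yle_male_cost=0.0,
            sterile_males=sterile, lethality=lethality,
        ),
        released=Genotype.male(YAllele.Y_WT, (_WT, _WT), construct=hom),
    )


def _optimal_xshredder() -> StrategyPreset:
    hom = (ShredderAllele.B_SHRED, ShredderAllele.B_SHRED)
    return StrategyPreset(
        name="optimal_xshredder",
        loci=LociConfig((_WT,), shredder=True),
        editing=replace(_NO_EDITING, shred_eff=1.0),
        phen=PhenotypeParams(dom_released=1.0, dom_new=1.0, yle_male_cost=0.0),
        released=Genotype.male(YAllele.Y_WT, (_WT, _WT), shredder=hom),
    )


def _yle_shredder(name: str, hom: bool) -> StrategyPreset:
    shredder = (
        (ShredderAllele.B_SHRED, ShredderAllele.B_SHRED)
        if hom
        else (ShredderAllele.B_WT, ShredderAllele.B_SHRED)
    )
    return StrategyPreset(
        name=name,
        loci=LociConfig.base(shredder=True),
        editing=replace(STRAIN_B_EDITING, shred_eff=1.0),
        # the second transgenic construct carries the same per-construct
        # competitiveness cost as the YLE itself
        phen=replace(STRAIN_B_PHENOTYPE, shredder_male_cost=STRAIN_B_PHENOTYPE.yle_male_cost),
        released=Genotype.male(YAllele.Y_YLE, (_WT, _DOM), shredder=shredder),
    )


_FACTORIES = {
    "yle_dsx_b": _yle_dsx_b,
    "optimal_yle": _optimal_yle,
    "optimal_sit": lambda: _construct_preset("optimal_sit", True, Lethality.NONE),
    "optimal_ridl": lambda: _construct_preset("optimal_ridl", False, Lethality.BOTH),
    "optimal_fs_ridl": lambda: _construct_preset("optimal_fs_ridl", False, Lethality.FEMALE),
    "optimal_xshredder": _optimal_xshredder,
    "yle_dsx_b_xshredder_het": lambda: _yle_shredder("yle_dsx_b_xshredder_het", False),
    "yle_dsx_b_xshredder_hom": lambda: _yle_shredder("yle_dsx_b_xshredder_hom", True),
}

STRATEGY_NAMES = tuple(_FACTORIES)


def strategy_preset(name: str) -> StrategyPreset:
    """Return the named strategy preset.

    Raises ``ValueError`` listing the valid names for an unknown strategy.
    """
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise ValueError(
            f"unknown strategy {name!r}; valid names: {', '.join(STRATEGY_NAMES)}"
        ) from None
    return factory()
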