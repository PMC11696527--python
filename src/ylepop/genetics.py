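"""Genotypes, gametes and crosses for Y-linked genome-editor (YLE) mosquito strains.

A YLE couples a Y-chromosome-borne CRISPR nuclease to an autosomal target
locus — the female-fertility gene *doublesex* (*dsx*) in the engineered
*Anopheles gambiae* strains this package models.  In the germline of a male
carrying the editor, a wild-type target allele is cleaved and repaired either
by homing (copying the mutant homologue, which biases inheritance above the
Mendelian 50%) or by non-homologous end-joining (NHEJ, which creates a new
cleavage-resistant mutation).  Females carrying a dominant mutant allele, or
no functional allele at all, are sterile; males are phenotypically unaffected
but transmit the editor to all of their sons.

Two further autosomal loci can be bookkept alongside the target:

* an X-shredder that destroys X-bearing sperm, biasing offspring toward
  males, and
* a generic "released construct" locus used to model the comparator
  strategies — sterile males (SIT) and dominant lethals acting after
  density-dependent larval competition (RIDL and female-specific fs-RIDL).

Diploid genotypes are unordered at each autosomal locus and canonicalised so
that every biological genotype has exactly one representation.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, fields, replace
from enum import Enum, IntEnum

import numpy as np

__all__ = [
    "Sex",
    "TargetAllele",
    "YAllele",
    "ShredderAllele",
    "ConstructAllele",
    "Lethality",
    "LociConfig",
    "Genotype",
    "Gamete",
    "EditingParams",
    "PhenotypeParams",
    "enumerate_genotypes",
    "female_gametes",
    "male_gamete_distribution",
    "offspring_distribution",
    "female_fertility",
    "male_competitiveness",
    "sire_is_fertile",
    "survives_post_density",
    "is_wt_phenotype_female",
    "GenotypeSpace",
]


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"


class TargetAllele(IntEnum):
    """Alleles at the autosomal target locus.

    WT
        Functional wild-type allele.
    REC
        Cleavage-resistant recessive loss-of-function mutation; females are
        sterile only when no functional copy remains.
    DOM_R
        The released dominant female-sterilising allele carried by YLE males
        (the *dsxF* in-frame deletion role); dominant-negative in females.
    DOM_N
        A new dominant mutation created by NHEJ repair.  With the probability
        of dominant NHEJ outcomes set to zero this class never appears and
        the model collapses to a three-allele space.
    """

    WT = 0
    REC = 1
    DOM_R = 2
    DOM_N = 3


class YAllele(IntEnum):
    """Y-chromosome allele: wild type or the Y-linked editor."""

    Y_WT = 0
    Y_YLE = 1


class ShredderAllele(IntEnum):
    """Autosomal X-shredder locus, unlinked to the target."""

    B_WT = 0
    B_SHRED = 1


class ConstructAllele(IntEnum):
    """Generic released-construct locus for SIT / RIDL / fs-RIDL bookkeeping."""

    L_WT = 0
    L_CON = 1


class Lethality(str, Enum):
    """Post-density-dependence lethality of the released construct."""

    NONE = "none"
    BOTH = "both"
    FEMALE = "female"


_TARGET_LABEL = {
    TargetAllele.WT: "WT",
    TargetAllele.REC: "REC",
    TargetAllele.DOM_R: "DOM_R",
    TargetAllele.DOM_N: "DOM_N",
}
_Y_LABEL = {YAllele.Y_WT: "Y", YAllele.Y_YLE: "y"}
_SHRED_LABEL = {ShredderAllele.B_WT: "B", ShredderAllele.B_SHRED: "b"}
_CON_LABEL = {ConstructAllele.L_WT: "L", ConstructAllele.L_CON: "l"}

_WT_SHRED = (ShredderAllele.B_WT, ShredderAllele.B_WT)
_WT_CON = (ConstructAllele.L_WT, ConstructAllele.L_WT)


@dataclass(frozen=True)
class LociConfig:
    """Which allele classes and optional loci the genotype space contains."""

    target_alleles: tuple[TargetAllele, ...] = (
        TargetAllele.WT,
        TargetAllele.REC,
        TargetAllele.DOM_R,
    )
    shredder: bool = False
    construct: bool = False

    def __post_init__(self) -> None:
        alleles = tuple(sorted(set(self.target_alleles)))
        if not alleles:
            raise ValueError("at least one target allele class is required")
        object.__setattr__(self, "target_alleles", alleles)

    @classmethod
    def base(cls, dom_n: bool = False, shredder: bool = False, construct: bool = False) -> "LociConfig":
        alleles = [TargetAllele.WT, TargetAllele.REC, TargetAllele.DOM_R]
        if dom_n:
            alleles.append(TargetAllele.DOM_N)
        return cls(tuple(alleles), shredder=shredder, construct=construct)


@dataclass(frozen=True)
class EditingParams:
    """Germline editing probabilities of the YLE, plus X-shredding efficiency.

    Defaults are the best-performing engineered strain's baseline values,
    derived from the observed 94.5% transmission of the released dominant
    allele and the ~3% rate of new target-site mutations:
    ``0.5 * (1 + cleave_het * (1 - nhej_given_cleave)) = 0.945`` and
    ``0.5 * cleave_het * nhej_given_cleave = 0.030`` with ``cleave_het = 0.95``.

    Attributes
    ----------
    cleave_het:
        Probability that the WT target allele is cleaved in a YLE male
        heterozygous for any mutant allele.
    nhej_given_cleave:
        Probability that a cleaved allele is repaired by NHEJ rather than
        homing.
    p_dom_new:
        Probability that an NHEJ product is a new dominant (DOM_N) rather
        than a recessive (REC) mutation.
    mut_wtwt:
        Probability that a WT allele in a WT/WT YLE male is converted to an
        NHEJ product (applied independently per allele).  The baseline 0.945
        implements the conservative assumption that such males pass on
        mutant alleles at the same rate as released males pass on the
        dominant allele.
    shred_eff:
        Probability that an X-bearing gamete of a shredder-carrying male is
        eliminated.
    """

    cleave_het: float = 0.95
    nhej_given_cleave: float = 0.06 / 0.95
    p_dom_new: float = 0.0
    mut_wtwt: float = 0.945
    shred_eff: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must lie in [0, 1], got {v}")

    def key(self) -> tuple:
        return tuple(getattr(self, f.name) for f in fields(self))


@dataclass(frozen=True)
class PhenotypeParams:
    """Genotype-to-phenotype map: female fertility, male mating success,
    and the action of a released construct.

    Attributes
    ----------
    dom_released:
        Dominance coefficient of the released dominant allele in
        heterozygous females (1 = fully penetrant sterility).
    dom_new:
        Dominance coefficient of NHEJ-derived dominant alleles.
    yle_male_cost:
        Fractional reduction of YLE-male mating competitiveness relative to
        wild-type males (0.22 at the fitted strain baseline).
    shredder_male_cost:
        Fractional competitiveness reduction of males carrying the
        X-shredder construct; costs of the two constructs multiply in males
        carrying both.  Zero for the idealised stand-alone shredder.
    sterile_males:
        If true, males carrying the released construct sire no viable
        offspring (SIT); they still compete for matings at full weight.
    lethality:
        Post-density-dependence lethality of construct carriers: none,
        both sexes (RIDL), or females only (fs-RIDL).
    """

    dom_released: float = 1.0
    dom_new: float = 1.0
    yle_male_cost: float = 0.22
    shredder_male_cost: float = 0.0
    sterile_males: bool = False
    lethality: Lethality = Lethality.NONE

    def __post_init__(self) -> None:
        for name in ("dom_released", "dom_new", "yle_male_cost", "shredder_male_cost"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not isinstance(self.lethality, Lethality):
            object.__setattr__(self, "lethality", Lethality(self.lethality))


@dataclass(frozen=True)
class Genotype:
    """A single individual's genotype, canonically ordered.

    Males carry exactly one Y allele; females none.  The target, shredder
    and construct loci are unordered diploid pairs stored sorted, so each
    genotype has exactly one representation.
    """

    sex: Sex
    y: YAllele | None
    target: tuple[TargetAllele, TargetAllele]
    shredder: tuple[ShredderAllele, ShredderAllele] = _WT_SHRED
    construct: tuple[ConstructAllele, ConstructAllele] = _WT_CON

    def __post_init__(self) -> None:
        if self.sex == Sex.MALE and self.y is None:
            raise ValueError("male genotypes carry exactly one Y allele")
        if self.sex == Sex.FEMALE and self.y is not None:
            raise ValueError("female genotypes carry no Y allele")
        object.__setattr__(self, "target", tuple(sorted(self.target)))
        object.__setattr__(self, "shredder", tuple(sorted(self.shredder)))
        object.__setattr__(self, "construct", tuple(sorted(self.construct)))

    @classmethod
    def female(cls, target, shredder=_WT_SHRED, construct=_WT_CON) -> "Genotype":
        return cls(Sex.FEMALE, None, tuple(target), tuple(shredder), tuple(construct))

    @classmethod
    def male(cls, y: YAllele, target, shredder=_WT_SHRED, construct=_WT_CON) -> "Genotype":
        return cls(Sex.MALE, y, tuple(target), tuple(shredder), tuple(construct))

    @property
    def label(self) -> str:
        ysym = _Y_LABEL[self.y] if self.y is not None else "-"
        t = "/".join(_TARGET_LABEL[a] for a in self.target)
        s = "/".join(_SHRED_LABEL[a] for a in self.shredder)
        c = "/".join(_CON_LABEL[a] for a in self.construct)
        return f"{self.sex.value}|{ysym}|{t}|{s}|{c}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class Gamete:
    """A haploid gamete: sex chromosome plus one allele per autosomal locus.

    ``y is None`` marks an X-bearing gamete; otherwise the gamete carries the
    father's Y chromosome with the given Y allele.
    """

    y: YAllele | None
    target: TargetAllele
    shredder: ShredderAllele = ShredderAllele.B_WT
    construct: ConstructAllele = ConstructAllele.L_WT

    @property
    def is_x(self) -> bool:
        return self.y is None


def enumerate_genotypes(loci: LociConfig) -> list[Genotype]:
    """Complete, duplicate-free genotype list in canonical order (females first).

    With the base three-allele target and no extra loci this yields the
    model's 6 female and 12 male genotypes.
    """
    tpairs = list(itertools.combinations_with_replacement(loci.target_alleles, 2))
    spairs = (
        list(itertools.combinations_with_replacement((ShredderAllele.B_WT, ShredderAllele.B_SHRED), 2))
        if loci.shredder
        else [_WT_SHRED]
    )
    cpairs = (
        list(itertools.combinations_with_replacement((ConstructAllele.L_WT, ConstructAllele.L_CON), 2))
        if loci.construct
        else [_WT_CON]
    )
    females = [
        Genotype.female(t, s, c)
        for t in tpairs
        for s in spairs
        for c in cpairs
    ]
    males = [
        Genotype.male(y, t, s, c)
        for y in (YAllele.Y_WT, YAllele.Y_YLE)
        for t in tpairs
        for s in spairs
        for c in cpairs
    ]
    return females + males


def _mendelian(pair) -> dict:
    probs: dict = defaultdict(float)
    for a in pair:
        probs[a] += 0.5
    return dict(probs)


def female_gametes(g: Genotype) -> dict[Gamete, float]:
    """Mendelian maternal gamete distribution (always X-bearing).

    No maternal deposition of the nuclease is modelled: eggs segregate
    alleles independently at every locus.
    """
    if g.sex != Sex.FEMALE:
        raise ValueError(f"female_gametes requires a female genotype, got {g.label}")
    out: dict[Gamete, float] = defaultdict(float)
    for t, pt in _mendelian(g.target).items():
        for s, ps in _mendelian(g.shredder).items():
            for c, pc in _mendelian(g.construct).items():
                out[Gamete(None, t, s, c)] += pt * ps * pc
    return dict(out)


def _male_target_marginal(g: Genotype, p: EditingParams) -> dict[TargetAllele, float]:
    """Per-gamete target-allele distribution after germline editing."""
    a1, a2 = g.target
    if g.y != YAllele.Y_YLE:
        return _mendelian(g.target)
    wt = TargetAllele.WT
    if a1 == wt and a2 == wt:
        mu, d = p.mut_wtwt, p.p_dom_new
        out = {
            wt: 1.0 - mu,
            TargetAllele.REC: mu * (1.0 - d),
            TargetAllele.DOM_N: mu * d,
        }
    elif wt in (a1, a2):
        mut = a2 if a1 == wt else a1
        c, j, d = p.cleave_het, p.nhej_given_cleave, p.p_dom_new
        out: dict[TargetAllele, float] = defaultdict(float)
        out[mut] += 0.5                      # the mutant homologue itself
        out[wt] += 0.5 * (1.0 - c)           # escapes cleavage
        out[mut] += 0.5 * c * (1.0 - j)      # homing copies the homologue
        out[TargetAllele.REC] += 0.5 * c * j * (1.0 - d)
        out[TargetAllele.DOM_N] += 0.5 * c * j * d
    else:
        # both alleles already mutant: nothing left to cleave
        out = _mendelian(g.target)
    return {a: pr for a, pr in out.items() if pr > 0.0}


def male_gamete_distribution(g: Genotype, p: EditingParams) -> dict[Gamete, float]:
    """Sperm distribution of a male under YLE editing and X-shredding.

    Editing acts on the target locus only in YLE males (cleavage + homing or
    NHEJ in heterozygotes; de novo NHEJ in WT homozygotes).  All other loci
    segregate Mendelian.  If the male carries the X-shredder, X-bearing
    gametes are removed with probability ``shred_eff`` and the distribution
    renormalised.
    """
    if g.sex != Sex.MALE:
        raise ValueError(f"male_gamete_distribution requires a male genotype, got {g.label}")
    tmarg = _male_target_marginal(g, p)
    sex_chrom: list[tuple[YAllele | None, float]] = [(None, 0.5), (g.y, 0.5)]
    out: dict[Gamete, float] = defaultdict(float)
    for y, py in sex_chrom:
        for t, pt in tmarg.items():
            for s, ps in _mendelian(g.shredder).items():
                for c, pc in _mendelian(g.construct).items():
                    out[Gamete(y, t, s, c)] += py * pt * ps * pc
    if p.shred_eff > 0.0 and ShredderAllele.B_SHRED in g.shredder:
        keep = {
            gam: pr * ((1.0 - p.shred_eff) if gam.is_x else 1.0)
            for gam, pr in out.items()
        }
        total = sum(keep.values())
        out = {gam: pr / total for gam, pr in keep.items() if pr > 0.0}
    return {gam: pr for gam, pr in out.items() if pr > 0.0}


def offspring_distribution(
    mother: Genotype, father: Genotype, p: EditingParams
) -> dict[Genotype, float]:
    """Offspring genotype distribution of a single mating.

    Maternal gametes are Mendelian; paternal gametes follow
    :func:`male_gamete_distribution`.  Offspring sex is set by the paternal
    sex chromosome, and sons inherit the father's Y allele.
    """
    if mother.sex != Sex.FEMALE:
        raise ValueError(f"mother must be female, got {mother.label}")
    if father.sex != Sex.MALE:
        raise ValueError(f"father must be male, got {father.label}")
    paternal = male_gamete_distribution(father, p)
    out: dict[Genotype, float] = defaultdict(float)
    for gm, pm in female_gametes(mother).items():
        for gf, pf in paternal.items():
            target = (gm.target, gf.target)
            shredder = (gm.shredder, gf.shredder)
            construct = (gm.construct, gf.construct)
            if gf.is_x:
                child = Genotype.female(target, shredder, construct)
            else:
                child = Genotype.male(gf.y, target, shredder, construct)
            out[child] += pm * pf
    return dict(out)


def female_fertility(g: Genotype, p: PhenotypeParams) -> float:
    """Relative fertility of a female genotype in [0, 1].

    Females with no functional target allele are sterile.  A single dominant
    allele over a functional one reduces fertility by the corresponding
    dominance coefficient; one recessive allele over wild type is harmless
    (the target is haplo-sufficient).
    """
    if g.sex != Sex.FEMALE:
        raise ValueError(f"female_fertility requires a female genotype, got {g.label}")
    wt = TargetAllele.WT
    n_wt = g.target.count(wt)
    if n_wt == 0:
        return 0.0
    if n_wt == 2:
        return 1.0
    other = g.target[0] if g.target[1] == wt else g.target[1]
    if other == TargetAllele.REC:
        return 1.0
    if other == TargetAllele.DOM_R:
        return 1.0 - p.dom_released
    return 1.0 - p.dom_new  # DOM_N


def male_competitiveness(g: Genotype, p: PhenotypeParams) -> float:
    """Mating-competitiveness weight of a male genotype (wild type = 1).

    Each transgenic construct contributes its own multiplicative cost: the
    Y-linked editor and, where carried, the X-shredder.
    """
    if g.sex != Sex.MALE:
        raise ValueError(f"male_competitiveness requires a male genotype, got {g.label}")
    weight = 1.0
    if g.y == YAllele.Y_YLE:
        weight *= 1.0 - p.yle_male_cost
    if ShredderAllele.B_SHRED in g.shredder:
        weight *= 1.0 - p.shredder_male_cost
    return weight


def sire_is_fertile(g: Genotype, p: PhenotypeParams) -> bool:
    """False for sterile (SIT-style) construct-carrying males."""
    return not (p.sterile_males and ConstructAllele.L_CON in g.construct)


def survives_post_density(g: Genotype, p: PhenotypeParams) -> bool:
    """Whether an offspring genotype survives post-density-dependence lethality."""
    if p.lethality == Lethality.NONE:
        return True
    if ConstructAllele.L_CON not in g.construct:
        return True
    if p.lethality == Lethality.BOTH:
        return False
    return g.sex != Sex.FEMALE  # female-specific lethality


def is_wt_phenotype_female(g: Genotype) -> bool:
    """Wild-type-looking female: carries a functional allele and no dominant one."""
    return (
        g.sex == Sex.FEMALE
        and TargetAllele.WT in g.target
        and TargetAllele.DOM_R not in g.target
        and TargetAllele.DOM_N not in g.target
    )


class GenotypeSpace:
    """Indexed genotype enumeration with vectorised phenotype maps and crosses.

    The space fixes the active allele classes and loci; every model in this
    package works on index-aligned abundance/count vectors over
    ``space.females`` and ``space.males``, and offspring distributions are
    provided as a dense cross tensor ``T[mother, father, child]`` (children
    indexed females-first, then males, offset by ``n_f``).
    """

    def __init__(self, loci: LociConfig | None = None):
        self.loci = loci if loci is not None else LociConfig.base()
        genotypes = enumerate_genotypes(self.loci)
        self.females = [g for g in genotypes if g.sex == Sex.FEMALE]
        self.males = [g for g in genotypes if g.sex == Sex.MALE]
        self.f_index = {g: i for i, g in enumerate(self.females)}
        self.m_index = {g: i for i, g in enumerate(self.males)}
        self._cross_cache: dict[tuple, np.ndarray] = {}

        self.yle_male_mask = np.array([g.y == YAllele.Y_YLE for g in self.males])
        self.wt_pheno_female_mask = np.array(
            [is_wt_phenotype_female(g) for g in self.females]
        )
        self.target_dosage_f = np.array(
            [[g.target.count(a) for a in TargetAllele] for g in self.females], dtype=float
        )
        self.target_dosage_m = np.array(
            [[g.target.count(a) for a in TargetAllele] for g in self.males], dtype=float
        )
        self.shredder_dosage_f = np.array(
            [g.shredder.count(ShredderAllele.B_SHRED) for g in self.females], dtype=float
        )
        self.shredder_dosage_m = np.array(
            [g.shredder.count(ShredderAllele.B_SHRED) for g in self.males], dtype=float
        )
        self.construct_dosage_f = np.array(
            [g.construct.count(ConstructAllele.L_CON) for g in self.females], dtype=float
        )
        self.construct_dosage_m = np.array(
            [g.construct.count(ConstructAllele.L_CON) for g in self.males], dtype=float
        )

    @property
    def n_f(self) -> int:
        return len(self.females)

    @property
    def n_m(self) -> int:
        return len(self.males)

    @property
    def n(self) -> int:
        return self.n_f + self.n_m

    def female_index(self, g: Genotype) -> int:
        try:
            return self.f_index[g]
        except KeyError:
            raise KeyError(f"female genotype {g.label} is not in this genotype space") from None

    def male_index(self, g: Genotype) -> int:
        try:
            return self.m_index[g]
        except KeyError:
            raise KeyError(f"male genotype {g.label} is not in this genotype space") from None

    # -- vectorised phenotype maps ------------------------------------------

    def fertility_vector(self, p: PhenotypeParams) -> np.ndarray:
        return np.array([female_fertility(g, p) for g in self.females])

    def competitiveness_vector(self, p: PhenotypeParams) -> np.ndarray:
        return np.array([male_competitiveness(g, p) for g in self.males])

    def fertile_sire_vector(self, p: PhenotypeParams) -> np.ndarray:
        return np.array([sire_is_fertile(g, p) for g in self.males], dtype=float)

    def female_survival_vector(self, p: PhenotypeParams) -> np.ndarray:
        return np.array([survives_post_density(g, p) for g in self.females], dtype=float)

    def male_survival_vector(self, p: PhenotypeParams) -> np.ndarray:
        return np.array([survives_post_density(g, p) for g in self.males], dtype=float)

    # -- crosses -------------------------------------------------------------

    def cross_tensor(self, p: EditingParams) -> np.ndarray:
        """Dense offspring tensor ``T[f, m, child]``; each slice sums to 1.

        Children are indexed females-first (``child < n_f``) then males
        (``child - n_f`` into :attr:`males`).  Cached per editing-parameter
        set.
        """
        key = p.key()
        cached = self._cross_cache.get(key)
        if cached is not None:
            return cached
        T = np.zeros((self.n_f, self.n_m, self.n))
        for j, father in enumerate(self.males):
            for i, mother in enumerate(self.females):
                for child, pr in offspring_distribution(mother, father, p).items():
                    if child.sex == Sex.FEMALE:
                        if child not in self.f_index:
                            raise ValueError(
                                f"offspring genotype {child.label} falls outside this "
                                "genotype space; enable the DOM_N allele class "
                                "(LociConfig.base(dom_n=True)) when p_dom_new > 0"
                            )
                        T[i, j, self.f_index[child]] += pr
                    else:
                        if child not in self.m_index:
                            raise ValueError(
                                f"offspring genotype {child.label} falls outside this "
                                "genotype space; enable the DOM_N allele class "
                                "(LociConfig.base(dom_n=True)) when p_dom_new > 0"
                            )
                        T[i, j, self.n_f + self.m_index[child]] += pr
        self._cross_cache[key] = T
        return T

    def allele_frequency(
        self, F: np.ndarray, M: np.ndarray, allele: TargetAllele
    ) -> float:
        """Frequency of a target allele among all adults (two copies each)."""
        total = F.sum() + M.sum()
        if total <= 0:
            return float("nan")
        dose = F @ self.target_dosage_f[:, allele] + M @ self.target_dosage_m[:, allele]
        return float(dose / (2.0 * total))
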