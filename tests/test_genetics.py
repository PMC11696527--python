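"""Genotype enumeration, gamete distributions, crosses and phenotype maps."""

import itertools
from collections import defaultdict

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ylepop.genetics import (
    EditingParams,
    Gamete,
    Genotype,
    GenotypeSpace,
    LociConfig,
    PhenotypeParams,
    Sex,
    ShredderAllele,
    TargetAllele,
    YAllele,
    enumerate_genotypes,
    female_fertility,
    female_gametes,
    male_competitiveness,
    male_gamete_distribution,
    offspring_distribution,
)

WT, REC, DOM_R, DOM_N = TargetAllele
NO_EDITING = EditingParams(
    cleave_het=0.0, nhej_given_cleave=0.0, p_dom_new=0.0, mut_wtwt=0.0, shred_eff=0.0
)


@pytest.mark.parametrize(
    "loci, n_female, n_male",
    [
        (LociConfig.base(), 6, 12),
        (LociConfig((WT,)), 1, 2),
        (LociConfig.base(shredder=True), 18, 36),
        (LociConfig.base(dom_n=True), 10, 20),
        (LociConfig((WT,), construct=True), 3, 6),
    ],
)
def test_genotype_counts(loci, n_female, n_male):
    genotypes = enumerate_genotypes(loci)
    females = [g for g in genotypes if g.sex == Sex.FEMALE]
    males = [g for g in genotypes if g.sex == Sex.MALE]
    assert len(females) == n_female
    assert len(males) == n_male
    assert len(set(genotypes)) == len(genotypes)


def test_canonical_representation_is_order_free():
    a = Genotype.female((DOM_R, WT))
    b = Genotype.female((WT, DOM_R))
    assert a == b and a.target == (WT, DOM_R)
    assert "WT/DOM_R" in a.label


def test_wrong_sex_raises_everywhere():
    female = Genotype.female((WT, WT))
    male = Genotype.male(YAllele.Y_WT, (WT, WT))
    with pytest.raises(ValueError):
        male_gamete_distribution(female, NO_EDITING)
    with pytest.raises(ValueError):
        female_gametes(male)
    with pytest.raises(ValueError):
        female_fertility(male, PhenotypeParams())
    with pytest.raises(ValueError):
        male_competitiveness(female, PhenotypeParams())
    with pytest.raises(ValueError):
        offspring_distribution(male, female, NO_EDITING)


def test_wildtype_male_gametes_are_mendelian():
    g = Genotype.male(YAllele.Y_WT, (WT, WT))
    dist = male_gamete_distribution(g, EditingParams())
    assert dist == {
        Gamete(None, WT): pytest.approx(0.5),
        Gamete(YAllele.Y_WT, WT): pytest.approx(0.5),
    }


def test_strain_b_heterozygote_gamete_probabilities():
    """Gametes of an editor male heterozygous for the dominant allele carry it
    with probability 0.945, a new recessive with 0.030 and wild type with
    0.025, split equally over X- and Y-bearing sperm."""
    g = Genotype.male(YAllele.Y_YLE, (WT, DOM_R))
    dist = male_gamete_distribution(g, EditingParams())
    by_target = defaultdict(float)
    by_sex = defaultdict(float)
    for gam, pr in dist.items():
        by_target[gam.target] += pr
        by_sex[gam.is_x] += pr
    assert by_target[DOM_R] == pytest.approx(0.945)
    assert by_target[REC] == pytest.approx(0.030)
    assert by_target[WT] == pytest.approx(0.025)
    assert by_sex[True] == pytest.approx(0.5)


def test_no_cleavage_collapses_to_mendelian():
    g = Genotype.male(YAllele.Y_YLE, (WT, DOM_R))
    dist = male_gamete_distribution(g, EditingParams(cleave_het=0.0, mut_wtwt=0.0))
    by_target = defaultdict(float)
    for gam, pr in dist.items():
        by_target[gam.target] += pr
    assert by_target[DOM_R] == pytest.approx(0.5)
    assert by_target[WT] == pytest.approx(0.5)


def test_complete_shredding_yields_only_y_gametes():
    g = Genotype.male(
        YAllele.Y_WT, (WT, WT), shredder=(ShredderAllele.B_WT, ShredderAllele.B_SHRED)
    )
    dist = male_gamete_distribution(g, EditingParams(shred_eff=1.0))
    assert all(not gam.is_x for gam in dist)
    carried = sum(pr for gam, pr in dist.items() if gam.shredder == ShredderAllele.B_SHRED)
    assert carried == pytest.approx(0.5)
    assert sum(dist.values()) == pytest.approx(1.0)


def test_zero_shredding_keeps_even_sex_ratio():
    g = Genotype.male(
        YAllele.Y_WT, (WT, WT), shredder=(ShredderAllele.B_SHRED, ShredderAllele.B_SHRED)
    )
    dist = male_gamete_distribution(g, EditingParams(shred_eff=0.0))
    x_mass = sum(pr for gam, pr in dist.items() if gam.is_x)
    assert x_mass == pytest.approx(0.5)


def _punnett_oracle(mother, father):
    """Brute-force Mendelian cross: uniform over parental allele picks."""
    out = defaultdict(float)
    for tm, tf in itertools.product(mother.target, father.target):
        for sm, sf in itertools.product(mother.shredder, father.shredder):
            for cm, cf in itertools.product(mother.construct, father.construct):
                for sex_pick in (None, father.y):
                    # 2 allele picks per parent per locus x 3 loci x 2 sexes
                    pr = 1.0 / 128.0
                    if sex_pick is None:
                        child = Genotype.female((tm, tf), (sm, sf), (cm, cf))
                    else:
                        child = Genotype.male(sex_pick, (tm, tf), (sm, sf), (cm, cf))
                    out[child] += pr
    return out


def test_zero_editing_matches_punnett_enumeration():
    """With all editing probabilities at zero every cross is exactly Mendelian."""
    loci = LociConfig.base(shredder=True)
    genotypes = enumerate_genotypes(loci)
    females = [g for g in genotypes if g.sex == Sex.FEMALE]
    males = [g for g in genotypes if g.sex == Sex.MALE]
    for mother in females:
        for father in males:
            got = offspring_distribution(mother, father, NO_EDITING)
            expected = _punnett_oracle(mother, father)
            assert set(got) == {g for g, p in expected.items() if p > 0}
            for child, pr in got.items():
                assert pr == pytest.approx(expected[child], abs=1e-12)


def test_transmission_closed_form_matches_monte_carlo():
    """Dominant-allele transmission from a heterozygous editor male equals
    0.5*(1 + C*(1-j)); checked against an independent per-meiosis sampler."""
    params = EditingParams(cleave_het=0.83, nhej_given_cleave=0.21, p_dom_new=0.15)
    closed = 0.5 * (1 + params.cleave_het * (1 - params.nhej_given_cleave))
    rng = np.random.default_rng(20240917)
    n = 100_000
    hits = 0
    for _ in range(n):
        # simulate the germline: cleave the WT homologue, then repair
        alleles = [DOM_R, WT]
        if rng.random() < params.cleave_het:
            if rng.random() < params.nhej_given_cleave:
                alleles[1] = DOM_N if rng.random() < params.p_dom_new else REC
            else:
                alleles[1] = DOM_R
        hits += alleles[rng.integers(2)] == DOM_R
    mc = hits / n
    se = np.sqrt(closed * (1 - closed) / n)
    assert abs(mc - closed) < 3 * se

    g = Genotype.male(YAllele.Y_YLE, (WT, DOM_R))
    dist = male_gamete_distribution(g, params)
    model = sum(pr for gam, pr in dist.items() if gam.target == DOM_R)
    assert model == pytest.approx(closed, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    c=st.floats(0, 1),
    j=st.floats(0, 1),
    d=st.floats(0, 1),
    mu=st.floats(0, 1),
    e=st.floats(0, 1),
)
def test_distributions_normalise_for_random_parameters(c, j, d, mu, e):
    """Gamete and offspring distributions sum to one for every genotype."""
    params = EditingParams(
        cleave_het=c, nhej_given_cleave=j, p_dom_new=d, mut_wtwt=mu, shred_eff=e
    )
    loci = LociConfig.base(dom_n=True, shredder=True)
    genotypes = enumerate_genotypes(loci)
    females = [g for g in genotypes if g.sex == Sex.FEMALE]
    males = [g for g in genotypes if g.sex == Sex.MALE]
    for father in males:
        assert sum(male_gamete_distribution(father, params).values()) == pytest.approx(
            1.0, abs=1e-12
        )
    mother = females[0]
    for father in males[::5]:
        total = sum(offspring_distribution(mother, father, params).values())
        assert total == pytest.approx(1.0, abs=1e-12)


def test_offspring_examples():
    wt_mother = Genotype.female((WT, WT))
    wt_father = Genotype.male(YAllele.Y_WT, (WT, WT))
    dist = offspring_distribution(wt_mother, wt_father, EditingParams())
    assert set(dist) == {wt_mother, wt_father}
    assert dist[wt_father] == pytest.approx(0.5)

    yle_father = Genotype.male(YAllele.Y_YLE, (WT, DOM_R))
    dist = offspring_distribution(wt_mother, yle_father, EditingParams())
    daughters = {g: p for g, p in dist.items() if g.sex == Sex.FEMALE}
    total_d = sum(daughters.values())
    dom_d = sum(p for g, p in daughters.items() if DOM_R in g.target)
    assert dom_d / total_d == pytest.approx(0.945)

    shred_father = Genotype.male(
        YAllele.Y_WT, (WT, WT), shredder=(ShredderAllele.B_WT, ShredderAllele.B_SHRED)
    )
    dist = offspring_distribution(wt_mother, shred_father, EditingParams(shred_eff=1.0))
    assert all(g.sex == Sex.MALE for g in dist)


@pytest.mark.parametrize(
    "target, dom_released, expected",
    [
        ((WT, DOM_R), 1.0, 0.0),
        ((WT, DOM_R), 0.6, 0.4),
        ((WT, REC), 1.0, 1.0),
        ((REC, REC), 1.0, 0.0),
        ((WT, WT), 1.0, 1.0),
        ((REC, DOM_R), 1.0, 0.0),
        ((DOM_R, DOM_R), 1.0, 0.0),
    ],
)
def test_female_fertility_map(target, dom_released, expected):
    phen = PhenotypeParams(dom_released=dom_released)
    assert female_fertility(Genotype.female(target), phen) == pytest.approx(expected)


def test_new_dominant_dominance_coefficient():
    phen = PhenotypeParams(dom_new=0.7)
    assert female_fertility(Genotype.female((WT, DOM_N)), phen) == pytest.approx(0.3)


def test_male_competitiveness_weights():
    phen = PhenotypeParams(yle_male_cost=0.22)
    assert male_competitiveness(Genotype.male(YAllele.Y_WT, (WT, WT)), phen) == 1.0
    assert male_competitiveness(
        Genotype.male(YAllele.Y_YLE, (WT, DOM_R)), phen
    ) == pytest.approx(0.78)
    assert male_competitiveness(
        Genotype.male(YAllele.Y_YLE, (WT, DOM_R)),
        PhenotypeParams(yle_male_cost=0.0),
    ) == pytest.approx(1.0)
    both = Genotype.male(
        YAllele.Y_YLE, (WT, DOM_R), shredder=(ShredderAllele.B_SHRED, ShredderAllele.B_SHRED)
    )
    phen2 = PhenotypeParams(yle_male_cost=0.22, shredder_male_cost=0.22)
    assert male_competitiveness(both, phen2) == pytest.approx(0.78 * 0.78)


def test_dom_n_space_collapses_when_inactive():
    """With no dominant NHEJ products the four-allele space reproduces the
    three-allele cross tensor on the shared genotypes."""
    small = GenotypeSpace(LociConfig.base())
    big = GenotypeSpace(LociConfig.base(dom_n=True))
    p = EditingParams(p_dom_new=0.0)
    T_small = small.cross_tensor(p)
    T_big = big.cross_tensor(p)
    for mother in small.females:
        for father in small.males:
            i_s, j_s = small.female_index(mother), small.male_index(father)
            i_b, j_b = big.female_index(mother), big.male_index(father)
            for child in small.females:
                assert T_big[i_b, j_b, big.female_index(child)] == pytest.approx(
                    T_small[i_s, j_s, small.female_index(child)], abs=1e-14
                )
            for child in small.males:
                assert T_big[i_b, j_b, big.n_f + big.male_index(child)] == pytest.approx(
                    T_small[i_s, j_s, small.n_f + small.male_index(child)], abs=1e-14
                )


def test_dom_n_outside_space_is_reported():
    space = GenotypeSpace(LociConfig.base())
    with pytest.raises(ValueError, match="DOM_N"):
        space.cross_tensor(EditingParams(p_dom_new=0.5))


def test_parameter_range_validation():
    with pytest.raises(ValueError, match="cleave_het"):
        EditingParams(cleave_het=1.2)
    with pytest.raises(ValueError, match="yle_male_cost"):
        PhenotypeParams(yle_male_cost=-0.1)
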