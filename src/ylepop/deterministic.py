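"""Deterministic, infinite-population release model with density dependence.

Discrete non-overlapping generations.  Adult abundances are genotype-resolved
and normalised so that the pre-release equilibrium has one unit of fertile
females and one unit of adult males; release rates are expressed against that
male unit.  Each generation:

1. released males are added to the adult male pool;
2. every fertile female mates once, with matings allocated in proportion to
   male abundance (males mate without depletion); a mating yields a brood
   with probability equal to the sire's competitiveness weight, and failed
   matings are not compensated (females are monandrous);
3. viable egg input ``E`` is the fertility-weighted female abundance times
   the expected brood success of a mating (sterile SIT males soak matings
   but contribute no viable eggs; less competitive males sire
   proportionally fewer broods);
4. offspring genotypes follow the cross tensor of
   :class:`~ylepop.genetics.GenotypeSpace`;
5. a normalised Beverton-Holt survival factor ``s = 1 / (1 + (Rm - 1) E)``
   applies uniformly to all offspring, scaled so a lone female at
   equilibrium exactly replaces herself (``Rm`` daughters before density
   regulation);
6. post-density lethality (RIDL: both sexes, fs-RIDL: females) removes
   construct carriers;
7. survivors are the next generation's adults.

Under these rules a sustained release of sterile males has the classic
fixed-point structure ``(Rm-1)x^2 - (Rm-1)x + r = 0`` with elimination
threshold ``r* = (Rm-1)/4``, which anchors the density-dependence choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genetics import (
    ConstructAllele,
    EditingParams,
    Genotype,
    GenotypeSpace,
    PhenotypeParams,
    Sex,
    ShredderAllele,
    TargetAllele,
    YAllele,
)

__all__ = [
    "DemographyParams",
    "ReleaseSchedule",
    "PopulationState",
    "SimulationResult",
    "step",
    "simulate",
    "required_release_rate",
    "sensitivity_curve",
    "SENSITIVITY_PARAMS",
]


@dataclass(frozen=True)
class DemographyParams:
    """Demography: intrinsic rate of increase and simulation horizon.

    ``rm`` is the expected number of daughters per female in the absence of
    density-dependent mortality; it must exceed 1 for the population to be
    viable.
    """

    rm: float = 6.0
    horizon: int = 36

    def __post_init__(self) -> None:
        if self.rm <= 1.0:
            raise ValueError(f"rm must exceed 1, got {self.rm}")
        if self.horizon < 1:
            raise ValueError(f"horizon must be at least 1, got {self.horizon}")


@dataclass(frozen=True)
class ReleaseSchedule:
    """Male releases: rate per generation relative to pre-release males.

    ``duration=None`` releases in every generation of the simulated horizon;
    ``single_release=True`` releases only in the first generation.
    """

    rate: float
    released_genotype: Genotype
    duration: int | None = None
    single_release: bool = False

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"release rate must be non-negative, got {self.rate}")
        if self.released_genotype.sex != Sex.MALE:
            raise ValueError("released individuals must be male")

    def amount_at(self, generation: int) -> float:
        """Released amount at generation ``generation`` (1-based steps)."""
        if self.single_release:
            return self.rate if generation == 1 else 0.0
        if self.duration is not None and generation > self.duration:
            return 0.0
        return self.rate


@dataclass
class PopulationState:
    """Genotype-resolved adult abundances (females ``F``, males ``M``)."""

    space: GenotypeSpace
    F: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.F.shape != (self.space.n_f,) or self.M.shape != (self.space.n_m,):
            raise ValueError("state vectors do not match the genotype space")
        if (self.F < 0).any() or (self.M < 0).any():
            raise ValueError("abundances must be non-negative")

    @classmethod
    def equilibrium(cls, space: GenotypeSpace) -> "PopulationState":
        """Pre-release wild-type equilibrium: one unit of each sex."""
        F = np.zeros(space.n_f)
        M = np.zeros(space.n_m)
        wt = TargetAllele.WT
        F[space.female_index(Genotype.female((wt, wt)))] = 1.0
        M[space.male_index(Genotype.male(YAllele.Y_WT, (wt, wt)))] = 1.0
        return cls(space, F, M)

    def fertile_females(self, phen: PhenotypeParams) -> float:
        return float(self.F @ self.space.fertility_vector(phen))

    def yle_male_frequency(self) -> float:
        total = self.M.sum()
        return float(self.M[self.space.yle_male_mask].sum() / total) if total > 0 else float("nan")


def _step_arrays(
    F: np.ndarray,
    M: np.ndarray,
    T: np.ndarray,
    fert: np.ndarray,
    comp: np.ndarray,
    sire_ok: np.ndarray,
    surv_f: np.ndarray,
    surv_m: np.ndarray,
    rm: float,
    n_f: int,
    release_amount: float = 0.0,
    release_index: int | None = None,
):
    """One generation on raw arrays; returns (F', M')."""
    M = M.copy()
    if release_amount > 0.0:
        M[release_index] += release_amount
    weight = comp * M
    total_males = M.sum()
    eggs = F * fert
    if weight.sum() <= 0.0 or eggs.sum() <= 0.0:
        return np.zeros(n_f), np.zeros(M.shape[0])
    # matings allocated by abundance; brood success scales with the sire's
    # competitiveness and is zero for sterile sires
    viable = (weight / total_males) * sire_ok
    E = eggs.sum() * viable.sum()
    zygotes = 2.0 * rm * np.einsum("f,m,fmc->c", eggs, viable, T)
    s = 1.0 / (1.0 + (rm - 1.0) * E)
    survivors = zygotes * s
    return survivors[:n_f] * surv_f, survivors[n_f:] * surv_m


def step(
    state: PopulationState,
    editing: EditingParams,
    phen: PhenotypeParams,
    demo: DemographyParams,
    release_amount: float = 0.0,
    released_genotype: Genotype | None = None,
) -> PopulationState:
    """Advance the population by one generation.

    ``release_amount`` adult males of ``released_genotype`` are added before
    mating.  With no releases and no transgenes the wild-type equilibrium is
    a fixed point.
    """
    if release_amount < 0:
        raise ValueError(f"release amount must be non-negative, got {release_amount}")
    space = state.space
    idx = None
    if release_amount > 0.0:
        if released_genotype is None:
            raise ValueError("a released genotype is required when releasing males")
        idx = space.male_index(released_genotype)
    F, M = _step_arrays(
        state.F,
        state.M,
        space.cross_tensor(editing),
        space.fertility_vector(phen),
        space.competitiveness_vector(phen),
        space.fertile_sire_vector(phen),
        space.female_survival_vector(phen),
        space.male_survival_vector(phen),
        demo.rm,
        space.n_f,
        release_amount,
        idx,
    )
    return PopulationState(space, F, M)


@dataclass
class SimulationResult:
    """Per-generation time series of a deterministic run (index 0 = start).

    ``fertile_females`` and ``total_females`` are relative to the
    pre-release equilibrium; allele frequencies are taken over all adults.
    ``resistant_freq`` pools the recessive and NHEJ-derived dominant classes.
    """

    generations: np.ndarray
    fertile_females: np.ndarray
    total_females: np.ndarray
    yle_male_freq: np.ndarray
    dom_r_freq: np.ndarray
    resistant_freq: np.ndarray
    construct_freq: np.ndarray
    shredder_freq: np.ndarray
    final_state: PopulationState = field(repr=False)

    def min_fertile_females(self) -> float:
        """Smallest relative fertile-female abundance after the start."""
        return float(np.min(self.fertile_females[1:]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generations,
                "fertile_females": self.fertile_females,
                "total_females": self.total_females,
                "yle_male_freq": self.yle_male_freq,
                "dom_r_freq": self.dom_r_freq,
                "resistant_freq": self.resistant_freq,
                "construct_freq": self.construct_freq,
                "shredder_freq": self.shredder_freq,
            }
        )


def simulate(
    space: GenotypeSpace,
    editing: EditingParams,
    phen: PhenotypeParams,
    demo: DemographyParams,
    schedule: ReleaseSchedule,
    initial: PopulationState | None = None,
) -> SimulationResult:
    """Run the release model for ``demo.horizon`` generations from equilibrium."""
    state = initial if initial is not None else PopulationState.equilibrium(space)
    T = space.cross_tensor(editing)
    fert = space.fertility_vector(phen)
    comp = space.competitiveness_vector(phen)
    sire_ok = space.fertile_sire_vector(phen)
    surv_f = space.female_survival_vector(phen)
    surv_m = space.male_survival_vector(phen)
    ridx = space.male_index(schedule.released_genotype)

    n_gen = demo.horizon
    fertile = np.empty(n_gen + 1)
    total_f = np.empty(n_gen + 1)
    yle = np.empty(n_gen + 1)
    dom_r = np.empty(n_gen + 1)
    resist = np.empty(n_gen + 1)
    construct = np.empty(n_gen + 1)
    shredder = np.empty(n_gen + 1)

    F, M = state.F.copy(), state.M.copy()

    def record(t: int) -> None:
        fertile[t] = F @ fert
        total_f[t] = F.sum()
        m_tot = M.sum()
        adults = F.sum() + m_tot
        yle[t] = M[space.yle_male_mask].sum() / m_tot if m_tot > 0 else np.nan
        if adults > 0:
            dose = lambda col_f, col_m: (F @ col_f + M @ col_m) / (2.0 * adults)
            dom_r[t] = dose(
                space.target_dosage_f[:, TargetAllele.DOM_R],
                space.target_dosage_m[:, TargetAllele.DOM_R],
            )
            resist[t] = dose(
                space.target_dosage_f[:, TargetAllele.REC]
                + space.target_dosage_f[:, TargetAllele.DOM_N],
                space.target_dosage_m[:, TargetAllele.REC]
                + space.target_dosage_m[:, TargetAllele.DOM_N],
            )
            construct[t] = dose(space.construct_dosage_f, space.construct_dosage_m)
            shredder[t] = dose(space.shredder_dosage_f, space.shredder_dosage_m)
        else:
            dom_r[t] = resist[t] = construct[t] = shredder[t] = np.nan

    record(0)
    for t in range(1, n_gen + 1):
        amount = schedule.amount_at(t)
        F, M = _step_arrays(
            F, M, T, fert, comp, sire_ok, surv_f, surv_m, demo.rm, space.n_f,
            amount, ridx if amount > 0 else None,
        )
        record(t)

    return SimulationResult(
        generations=np.arange(n_gen + 1),
        fertile_females=fertile,
        total_females=total_f,
        yle_male_freq=yle,
        dom_r_freq=dom_r,
        resistant_freq=resist,
        construct_freq=construct,
        shredder_freq=shredder,
        final_state=PopulationState(space, F, M),
    )


def required_release_rate(
    space: GenotypeSpace,
    editing: EditingParams,
    phen: PhenotypeParams,
    demo: DemographyParams,
    released_genotype: Genotype,
    suppression_target: float,
    rate_max: float = 100.0,
    tol: float = 1e-4,
    max_iter: int = 60,
    at_final_generation: bool = False,
) -> float:
    """Smallest sustained per-generation release rate reaching a suppression level.

    Releases of equal size occur in every generation.  The target is met when
    relative fertile females fall to ``1 - suppression_target`` at some
    generation within the horizon (or exactly at the final generation with
    ``at_final_generation=True``).  Bisection on ``[0, rate_max]`` to absolute
    tolerance ``tol``; returns ``math.inf`` if the target is unachievable at
    ``rate_max``.
    """
    if not 0.0 < suppression_target < 1.0:
        raise ValueError(f"suppression_target must lie in (0, 1), got {suppression_target}")
    level = 1.0 - suppression_target
    schedule = lambda rate: ReleaseSchedule(rate, released_genotype, duration=None)

    def achieved(rate: float) -> bool:
        res = simulate(space, editing, phen, demo, schedule(rate))
        if at_final_generation:
            return res.fertile_females[-1] <= level
        return res.min_fertile_females() <= level

    if achieved(0.0):
        return 0.0
    if not achieved(rate_max):
        return math.inf
    lo, hi = 0.0, rate_max
    for _ in range(max_iter):
        if hi - lo <= tol:
            break
        mid = 0.5 * (lo + hi)
        if achieved(mid):
            hi = mid
        else:
            lo = mid
    return hi


#: Sensitivity-analysis parameters: name -> (which bundle, attribute)
SENSITIVITY_PARAMS = {
    "cleave_het": "editing",
    "nhej_given_cleave": "editing",
    "mut_wtwt": "editing",
    "p_dom_new": "editing",
    "yle_male_cost": "phen",
    "dom_released": "phen",
    "dom_new": "phen",
}


def sensitivity_curve(
    param_name: str,
    grid,
    rm_list=(12.0, 6.0, 2.0),
    suppression_target: float = 0.95,
    horizon: int = 36,
    rate_max: float = 100.0,
) -> pd.DataFrame:
    """Required release rate as a function of one editing/phenotype parameter.

    All other parameters stay at the engineered-strain baseline.  The
    genotype space includes the NHEJ-dominant allele class so that the
    ``p_dom_new`` and ``dom_new`` axes are meaningful.  Returns one row per
    (grid point, Rm), plus the baseline point per Rm flagged
    ``is_baseline=True``.
    """
    from .strategies import strategy_preset

    if param_name not in SENSITIVITY_PARAMS:
        raise ValueError(
            f"unknown sensitivity parameter {param_name!r}; "
            f"choose one of {sorted(SENSITIVITY_PARAMS)}"
        )
    base = strategy_preset("yle_dsx_b")
    space = GenotypeSpace(
        replace(base.loci, target_alleles=base.loci.target_alleles + (TargetAllele.DOM_N,))
    )
    which = SENSITIVITY_PARAMS[param_name]
    baseline_value = getattr(base.editing if which == "editing" else base.phen, param_name)

    rows = []
    for rm in rm_list:
        demo = DemographyParams(rm=rm, horizon=horizon)
        for value, is_baseline in [(v, False) for v in grid] + [(baseline_value, True)]:
            editing, phen = base.editing, base.phen
            if which == "editing":
                editing = replace(editing, **{param_name: float(value)})
            else:
                phen = replace(phen, **{param_name: float(value)})
            rate = required_release_rate(
                space, editing, phen, demo, base.released, suppression_target,
                rate_max=rate_max,
            )
            rows.append(
                {
                    "param": param_name,
                    "value": float(value),
                    "rm": rm,
                    "required_rate": rate,
                    "is_baseline": is_baseline,
                }
            )
    return pd.DataFrame(rows)
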