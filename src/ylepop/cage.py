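"""Finite-population stochastic simulator of multigeneration cage trials.

Emulates the laboratory protocol: an initial cage of wild-type females,
wild-type males and released YLE males; every generation the females mate
(sire chosen with probability proportional to competitiveness-weighted male
counts), fertile females' eggs are pooled, and the next generation is a
single multinomial draw of a fixed number of pupae from the pooled expected
offspring genotype mix.  Intersex (sterile) females are counted among the
pupae but lay no eggs.  Mating, fecundity and pupa selection are collapsed
into that one multinomial draw: eggs are sprayed into shared trays and pupae
sampled at random, so there is no per-family bottleneck.

Phenotype classification follows the pupal screen: marker-positive (YLE)
males vs wild-type males, and wild-type-looking females (at least one
functional target allele, no dominant mutation) vs intersex females.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import (
    EditingParams,
    Genotype,
    GenotypeSpace,
    PhenotypeParams,
    TargetAllele,
    YAllele,
)

__all__ = [
    "CageConfig",
    "CageTrajectory",
    "simulate_cage",
    "summarize",
    "ensemble",
    "Ensemble",
    "summaries_from_counts",
    "CAGE_SCHEMA",
    "SUMMARY_STATISTICS",
]

#: Column order of the trajectory table shared with the synthetic-data
#: generator and the ABC fitter.
CAGE_SCHEMA = [
    "cage_id",
    "generation",
    "n_wt_female",
    "n_intersex_female",
    "n_yle_male",
    "n_wt_male",
]

#: Per-generation summary statistics, in fixed order.
SUMMARY_STATISTICS = ["rel_wt_female", "yle_male_freq", "dom_r_freq"]


def _default_released() -> Genotype:
    return Genotype.male(YAllele.Y_YLE, (TargetAllele.WT, TargetAllele.DOM_R))


@dataclass(frozen=True)
class CageConfig:
    """Cage-trial protocol: initial adults, census size, duration."""

    n_wt_females: int = 300
    n_wt_males: int = 300
    n_yle_males: int = 300
    pupae_per_generation: int = 600
    generations: int = 5
    released_genotype: Genotype = field(default_factory=_default_released)

    def __post_init__(self) -> None:
        for name in ("n_wt_females", "n_wt_males", "n_yle_males"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.pupae_per_generation <= 0:
            raise ValueError("pupae_per_generation must be positive")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")


def _initial_counts(space: GenotypeSpace, config: CageConfig):
    wt = TargetAllele.WT
    F0 = np.zeros(space.n_f, dtype=np.int64)
    M0 = np.zeros(space.n_m, dtype=np.int64)
    F0[space.female_index(Genotype.female((wt, wt)))] = config.n_wt_females
    M0[space.male_index(Genotype.male(YAllele.Y_WT, (wt, wt)))] += config.n_wt_males
    if config.n_yle_males:
        M0[space.male_index(config.released_genotype)] += config.n_yle_males
    return F0, M0


def _simulate_counts(
    space: GenotypeSpace,
    T: np.ndarray,
    fert: np.ndarray,
    comp: np.ndarray,
    sire_ok: np.ndarray,
    F0: np.ndarray,
    M0: np.ndarray,
    generations: int,
    pupae: int,
    rng: np.random.Generator,
):
    """Core loop on raw count arrays.

    Returns (female counts, male counts) with one row per recorded
    generation, and the generation index at which the cage went extinct
    (``None`` if it never did).  The trajectory is truncated at extinction.
    """
    n_f = space.n_f
    Fs = [F0.copy()]
    Ms = [M0.copy()]
    Fc, Mc = F0, M0
    extinct_at = None
    for t in range(1, generations + 1):
        weight = comp * Mc
        W = weight.sum()
        eggs = Fc * fert
        if W <= 0 or eggs.sum() <= 0:
            extinct_at = t
            break
        mix = np.einsum("f,m,fmc->c", eggs, (weight / W) * sire_ok, T)
        total = mix.sum()
        if total <= 0:
            extinct_at = t
            break
        counts = rng.multinomial(pupae, mix / total)
        Fc, Mc = counts[:n_f], counts[n_f:]
        Fs.append(Fc)
        Ms.append(Mc)
    return np.array(Fs), np.array(Ms), extinct_at


@dataclass
class CageTrajectory:
    """Genotype-resolved integer counts of one simulated cage.

    Row ``t`` of the count arrays is generation ``t``; generation 0 holds the
    founding adults (which may exceed the pupal census), and every later
    generation sums to ``config.pupae_per_generation``.  ``extinct_at`` marks
    the first generation at which no viable offspring could be produced; the
    arrays are truncated just before it.
    """

    space: GenotypeSpace
    config: CageConfig
    female_counts: np.ndarray
    male_counts: np.ndarray
    extinct_at: int | None = None

    @property
    def n_recorded(self) -> int:
        """Number of recorded generations, including generation 0."""
        return self.female_counts.shape[0]

    @property
    def extinct(self) -> bool:
        return self.extinct_at is not None

    def wt_female_counts(self) -> np.ndarray:
        return self.female_counts @ self.space.wt_pheno_female_mask

    def intersex_female_counts(self) -> np.ndarray:
        return self.female_counts @ (~self.space.wt_pheno_female_mask)

    def yle_male_counts(self) -> np.ndarray:
        return self.male_counts @ self.space.yle_male_mask

    def wt_male_counts(self) -> np.ndarray:
        return self.male_counts @ (~self.space.yle_male_mask)

    def target_allele_counts(self) -> np.ndarray:
        """Per-generation counts of each target allele (columns follow
        :class:`~ylepop.genetics.TargetAllele`)."""
        return (
            self.female_counts @ self.space.target_dosage_f
            + self.male_counts @ self.space.target_dosage_m
        )

    def to_frame(self, cage_id: int = 1) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cage_id": cage_id,
                "generation": np.arange(self.n_recorded),
                "n_wt_female": self.wt_female_counts(),
                "n_intersex_female": self.intersex_female_counts(),
                "n_yle_male": self.yle_male_counts(),
                "n_wt_male": self.wt_male_counts(),
            }
        )[CAGE_SCHEMA]


def simulate_cage(
    config: CageConfig,
    editing: EditingParams,
    phen: PhenotypeParams,
    seed: int,
    space: GenotypeSpace | None = None,
) -> CageTrajectory:
    """Simulate one cage; bit-identical given the same seed."""
    if seed is None:
        raise ValueError("a seed is mandatory for the stochastic cage simulator")
    if space is None:
        space = GenotypeSpace()
    rng = np.random.default_rng(seed)
    F0, M0 = _initial_counts(space, config)
    Fs, Ms, extinct_at = _simulate_counts(
        space,
        space.cross_tensor(editing),
        space.fertility_vector(phen),
        space.competitiveness_vector(phen),
        space.fertile_sire_vector(phen),
        F0,
        M0,
        config.generations,
        config.pupae_per_generation,
        rng,
    )
    return CageTrajectory(space, config, Fs, Ms, extinct_at)


def _stat_arrays(traj: CageTrajectory) -> dict[str, np.ndarray]:
    """Summary statistics per recorded generation (index 0 = founding)."""
    wt_f = traj.wt_female_counts().astype(float)
    yle_m = traj.yle_male_counts().astype(float)
    wt_m = traj.wt_male_counts().astype(float)
    males = yle_m + wt_m
    adults = traj.female_counts.sum(axis=1) + traj.male_counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        yle_freq = np.where(males > 0, yle_m / males, np.nan)
        dom = traj.target_allele_counts()[:, TargetAllele.DOM_R]
        dom_freq = np.where(adults > 0, dom / (2.0 * adults), np.nan)
    n0 = traj.config.n_wt_females
    rel_wt = wt_f / n0 if n0 > 0 else np.full_like(wt_f, np.nan)
    return {"rel_wt_female": rel_wt, "yle_male_freq": yle_freq, "dom_r_freq": dom_freq}


def summarize(traj: CageTrajectory, cage_id: int = 1) -> pd.DataFrame:
    """Long-format summary table for generations 1..configured horizon.

    Columns ``(cage_id, generation, statistic, value)`` with the statistics
    of :data:`SUMMARY_STATISTICS` in fixed order.  Generations lost to
    extinction are present with ``value = NaN`` so that missing data are
    encoded explicitly.
    """
    stats = _stat_arrays(traj)
    rows = []
    for gen in range(1, traj.config.generations + 1):
        for name in SUMMARY_STATISTICS:
            value = stats[name][gen] if gen < traj.n_recorded else np.nan
            rows.append(
                {"cage_id": cage_id, "generation": gen, "statistic": name, "value": value}
            )
    return pd.DataFrame(rows)


def summaries_from_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Convert a cage-schema count table to the long-format summary table.

    Only the two statistics derivable from phenotype counts are produced
    (relative wild-type females against the generation-0 female count, and
    YLE-male frequency); allele frequencies need genotype or read data.
    """
    missing = set(CAGE_SCHEMA) - set(table.columns)
    if missing:
        raise ValueError(f"count table lacks columns: {sorted(missing)}")
    rows = []
    for cage_id, sub in table.groupby("cage_id"):
        sub = sub.sort_values("generation")
        gen0 = sub[sub["generation"] == 0]
        if gen0.empty:
            raise ValueError(f"cage {cage_id} has no generation-0 row")
        n0 = float(gen0["n_wt_female"].iloc[0])
        for _, row in sub[sub["generation"] >= 1].iterrows():
            males = row["n_yle_male"] + row["n_wt_male"]
            rows.append(
                {
                    "cage_id": cage_id,
                    "generation": int(row["generation"]),
                    "statistic": "rel_wt_female",
                    "value": row["n_wt_female"] / n0 if n0 > 0 else np.nan,
                }
            )
            rows.append(
                {
                    "cage_id": cage_id,
                    "generation": int(row["generation"]),
                    "statistic": "yle_male_freq",
                    "value": row["n_yle_male"] / males if males > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class Ensemble:
    """Replicate ensemble of cage simulations.

    ``values[statistic]`` has shape ``(n_replicates, generations + 1)``;
    entries after an extinction are ``NaN``.
    """

    config: CageConfig
    values: dict[str, np.ndarray]
    seeds: np.ndarray

    def mean(self, statistic: str) -> np.ndarray:
        return np.nanmean(self.values[statistic], axis=0)

    def envelope(self, statistic: str, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Central ``level`` envelope (lower, upper) per generation."""
        tail = 100.0 * (1.0 - level) / 2.0
        v = self.values[statistic]
        return (
            np.nanpercentile(v, tail, axis=0),
            np.nanpercentile(v, 100.0 - tail, axis=0),
        )

    def to_frame(self, level: float = 0.95) -> pd.DataFrame:
        rows = []
        for name, v in self.values.items():
            lo, hi = self.envelope(name, level)
            mean = self.mean(name)
            for gen in range(v.shape[1]):
                rows.append(
                    {
                        "statistic": name,
                        "generation": gen,
                        "mean": mean[gen],
                        "lower": lo[gen],
                        "upper": hi[gen],
                    }
                )
        return pd.DataFrame(rows)


def ensemble(
    config: CageConfig,
    editing: EditingParams,
    phen: PhenotypeParams,
    n_replicates: int,
    base_seed: int,
    space: GenotypeSpace | None = None,
    seeds=None,
) -> Ensemble:
    """Simulate ``n_replicates`` cages; replicate ``k`` uses ``base_seed + k``.

    An explicit ``seeds`` sequence overrides the derived ones (it must have
    length ``n_replicates``).  Results are reproducible given the seeds.
    """
    if n_replicates < 2:
        raise ValueError("an ensemble needs at least 2 replicates")
    if space is None:
        space = GenotypeSpace()
    if seeds is None:
        seeds = np.arange(n_replicates, dtype=np.int64) + int(base_seed)
    else:
        seeds = np.asarray(seeds, dtype=np.int64)
        if seeds.shape != (n_replicates,):
            raise ValueError("seeds must have length n_replicates")
    n_gen = config.generations
    values = {
        name: np.full((n_replicates, n_gen + 1), np.nan) for name in SUMMARY_STATISTICS
    }
    for k, seed in enumerate(seeds):
        traj = simulate_cage(config, editing, phen, int(seed), space=space)
        stats = _stat_arrays(traj)
        m = traj.n_recorded
        for name in SUMMARY_STATISTICS:
            values[name][k, :m] = stats[name]
    return Ensemble(config=config, values=values, seeds=seeds)
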