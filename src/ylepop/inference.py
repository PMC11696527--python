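"""Rejection-ABC estimation of the YLE-male fitness cost from cage data.

The stochastic cage simulator is the likelihood-free forward model.  A single
unknown — the fractional reduction in YLE-male mating competitiveness — is
drawn from a uniform prior, a cage is simulated per observed cage, and the
draws whose summary statistics lie closest to the observations (weighted
Euclidean distance) are accepted.  All other parameters are fixed at the
values measured in the phenotypic assays.

Observations enter as a long-format summary table with columns
``(cage_id, generation, statistic, value)``; any subset of the cage summary
statistics at any generations can be supplied, and the simulator is compared
at exactly those coordinates.  This accommodates both full synthetic count
tables (via :func:`ylepop.cage.summarize`) and sparse published per-cage
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cage import CageConfig, SUMMARY_STATISTICS, _initial_counts, _simulate_counts, _stat_arrays, CageTrajectory
from .genetics import EditingParams, GenotypeSpace, PhenotypeParams

__all__ = ["ABCConfig", "Posterior", "distance", "fit", "point_estimate"]


@dataclass(frozen=True)
class ABCConfig:
    """Rejection-ABC settings.

    A uniform prior on ``[prior_low, prior_high]`` for the YLE-male cost;
    ``n_simulations`` parameter draws; the ``acceptance_fraction`` with the
    smallest distances is accepted.  ``weights`` maps statistic names to
    distance weights (unweighted statistics default to 1).
    """

    base_seed: int
    prior_low: float = 0.0
    prior_high: float = 1.0
    n_simulations: int = 20_000
    acceptance_fraction: float = 0.01
    weights: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.prior_low < self.prior_high <= 1.0:
            raise ValueError(
                "prior bounds must satisfy 0 <= low < high <= 1, "
                f"got [{self.prior_low}, {self.prior_high}]"
            )
        if not 0.0 < self.acceptance_fraction <= 1.0:
            raise ValueError(
                f"acceptance_fraction must lie in (0, 1], got {self.acceptance_fraction}"
            )
        if self.n_simulations < 100:
            raise ValueError(f"n_simulations must be at least 100, got {self.n_simulations}")
        if self.base_seed is None:
            raise ValueError("a base seed is mandatory for ABC")


@dataclass
class Posterior:
    """Accepted ABC draws with point estimate and credible interval."""

    draws: np.ndarray
    distances: np.ndarray
    accepted_mask: np.ndarray
    threshold: float

    @property
    def accepted(self) -> np.ndarray:
        return self.draws[self.accepted_mask]

    @property
    def median(self) -> float:
        return float(np.median(self.accepted))

    @property
    def credible_interval(self) -> tuple[float, float]:
        """Equal-tailed 95% credible interval of the accepted draws."""
        lo, hi = np.percentile(self.accepted, [2.5, 97.5])
        return float(lo), float(hi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": np.arange(self.draws.size),
                "cost": self.draws,
                "distance": self.distances,
                "accepted": self.accepted_mask.astype(int),
            }
        )


def distance(obs_summary, sim_summary, weights=None) -> float:
    """Weighted Euclidean distance between two equally ordered summary vectors.

    Zero iff the summaries are equal under positive weights; ``inf`` if the
    simulated summary contains missing values (an extinct cage cannot match
    a surviving one).
    """
    obs = np.asarray(obs_summary, dtype=float)
    sim = np.asarray(sim_summary, dtype=float)
    if obs.shape != sim.shape:
        raise ValueError(
            f"summary length mismatch: observed {obs.shape} vs simulated {sim.shape}"
        )
    if weights is None:
        w = np.ones_like(obs)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != obs.shape:
            raise ValueError("weights must match the summary length")
    if np.isnan(sim).any():
        return float("inf")
    return float(np.sqrt(np.sum(w * (obs - sim) ** 2)))


def point_estimate(posterior: Posterior) -> float:
    """Posterior median of the accepted draws."""
    if posterior.accepted.size == 0:
        raise ValueError("posterior contains no accepted draws")
    return posterior.median


def _coordinates(observed: pd.DataFrame):
    """Validated (cage, generation, statistic) coordinates and observed vector."""
    required = {"cage_id", "generation", "statistic", "value"}
    missing = required - set(observed.columns)
    if missing:
        raise ValueError(f"observed table lacks columns: {sorted(missing)}")
    table = observed.dropna(subset=["value"])
    if table.empty:
        raise ValueError("observed table contains no usable observations")
    unknown = set(table["statistic"]) - set(SUMMARY_STATISTICS)
    if unknown:
        raise ValueError(
            f"unknown summary statistics {sorted(unknown)}; "
            f"valid: {SUMMARY_STATISTICS}"
        )
    table = table.sort_values(["cage_id", "generation", "statistic"], kind="stable")
    coords = list(
        zip(table["cage_id"].tolist(), table["generation"].astype(int).tolist(), table["statistic"].tolist())
    )
    return coords, table["value"].to_numpy(dtype=float)


def fit(
    observed: pd.DataFrame,
    cage_config: CageConfig,
    editing: EditingParams,
    phen: PhenotypeParams,
    abc_config: ABCConfig,
    space: GenotypeSpace | None = None,
) -> Posterior:
    """Rejection-ABC fit of the YLE-male competitiveness cost.

    ``phen.yle_male_cost`` is overridden by each prior draw; everything else
    is held fixed.  One cage is simulated per observed cage id and per draw.
    Reproducible given ``abc_config.base_seed``.
    """
    if space is None:
        space = GenotypeSpace()
    coords, obs_vec = _coordinates(observed)
    cages = sorted({c for c, _, _ in coords})
    max_gen = max(g for _, g, _ in coords)
    if max_gen > cage_config.generations:
        raise ValueError(
            f"observations extend to generation {max_gen} but the cage "
            f"protocol runs {cage_config.generations} generations"
        )
    weight_map = abc_config.weights or {}
    w = np.array([float(weight_map.get(stat, 1.0)) for _, _, stat in coords])

    T = space.cross_tensor(editing)
    fert = space.fertility_vector(phen)
    sire_ok = space.fertile_sire_vector(phen)
    F0, M0 = _initial_counts(space, cage_config)
    yle_mask = space.yle_male_mask
    base_comp = np.ones(space.n_m)
    pupae = cage_config.pupae_per_generation
    gens = cage_config.generations

    rng = np.random.default_rng(abc_config.base_seed)
    n = abc_config.n_simulations
    costs = rng.uniform(abc_config.prior_low, abc_config.prior_high, size=n)
    sim_seeds = rng.integers(0, 2**31 - 1, size=(n, len(cages)))

    dists = np.empty(n)
    for i in range(n):
        comp = base_comp - costs[i] * yle_mask
        per_cage: dict = {}
        for k, cage_id in enumerate(cages):
            sub_rng = np.random.default_rng(int(sim_seeds[i, k]))
            Fs, Ms, extinct_at = _simulate_counts(
                space, T, fert, comp, sire_ok, F0, M0, gens, pupae, sub_rng
            )
            traj = CageTrajectory(space, cage_config, Fs, Ms, extinct_at)
            per_cage[cage_id] = (_stat_arrays(traj), traj.n_recorded)
        sim_vec = np.empty(len(coords))
        for idx, (cage_id, gen, stat) in enumerate(coords):
            stats, n_rec = per_cage[cage_id]
            sim_vec[idx] = stats[stat][gen] if gen < n_rec else np.nan
        dists[i] = distance(obs_vec, sim_vec, w)

    n_accept = max(1, int(round(abc_config.acceptance_fraction * n)))
    order = np.argsort(dists, kind="stable")
    mask = np.zeros(n, dtype=bool)
    mask[order[:n_accept]] = True
    threshold = float(dists[order[n_accept - 1]])
    return Posterior(draws=costs, distances=dists, accepted_mask=mask, threshold=threshold)
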