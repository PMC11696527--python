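"""Synthetic cage observations with known ground truth, plus the published
per-cage summary fixture.

Two kinds of tables are produced so that every pipeline stage can be tested
without any external download:

* cage trajectory tables in the exact schema shared with the stochastic
  simulator and the ABC fitter, generated by the simulator itself under a
  known parameter bundle (the ground truth travels in a sidecar mapping that
  suffices to regenerate the dataset bit-identically); and
* pooled target-locus allele tables emulating amplicon sequencing of pooled
  adults: per generation and allele, read counts drawn binomially at a
  configured depth around the true pooled allele frequency (no PCR-bias
  model).

:func:`empirical_fixture` packages the published per-cage summary numbers
(the generation-1 and generation-5 female counts and YLE-male frequencies,
and the generation-1 and generation-3 dominant-allele frequencies from the
two replicate cages).  It is summary-level — no full counts exist for it —
and generations without a published number are absent rather than
interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cage import CageConfig, CageTrajectory, simulate_cage, summarize
from .deterministic import DemographyParams
from .genetics import (
    EditingParams,
    Genotype,
    PhenotypeParams,
    GenotypeSpace,
    TargetAllele,
    YAllele,
    Lethality,
)
from .strategies import STRAIN_B_EDITING, STRAIN_B_PHENOTYPE

__all__ = [
    "SyntheticSpec",
    "cage_trajectories",
    "generate_cage_dataset",
    "dataset_from_sidecar",
    "generate_pool_allele_table",
    "empirical_fixture",
    "ALLELE_SCHEMA",
]

ALLELE_SCHEMA = ["cage_id", "generation", "allele", "reads", "depth"]

_ALLELE_NAMES = {a: a.name for a in TargetAllele}


@dataclass(frozen=True)
class SyntheticSpec:
    """True parameter bundle and sampling plan for one synthetic dataset."""

    seed: int
    editing: EditingParams = STRAIN_B_EDITING
    phen: PhenotypeParams = STRAIN_B_PHENOTYPE
    demography: DemographyParams = field(default_factory=DemographyParams)
    cage_config: CageConfig = field(default_factory=CageConfig)
    n_cages: int = 2
    read_depth: int = 5000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for synthetic data generation")
        if self.read_depth <= 0:
            raise ValueError(f"read_depth must be positive, got {self.read_depth}")
        if self.n_cages < 1:
            raise ValueError("n_cages must be at least 1")

    def cage_seed(self, cage_id: int) -> int:
        """Replicate cage ``cage_id`` (1-based) uses ``seed + cage_id - 1``."""
        return int(self.seed) + int(cage_id) - 1


def cage_trajectories(spec: SyntheticSpec, space: GenotypeSpace | None = None) -> list[CageTrajectory]:
    """One simulated trajectory per cage, seeded deterministically."""
    if space is None:
        space = GenotypeSpace()
    return [
        simulate_cage(spec.cage_config, spec.editing, spec.phen, spec.cage_seed(k), space=space)
        for k in range(1, spec.n_cages + 1)
    ]


def _sidecar(spec: SyntheticSpec) -> dict:
    cfg = spec.cage_config
    return {
        "seed": int(spec.seed),
        "n_cages": int(spec.n_cages),
        "read_depth": int(spec.read_depth),
        "editing": {
            "cleave_het": spec.editing.cleave_het,
            "nhej_given_cleave": spec.editing.nhej_given_cleave,
            "p_dom_new": spec.editing.p_dom_new,
            "mut_wtwt": spec.editing.mut_wtwt,
            "shred_eff": spec.editing.shred_eff,
        },
        "phenotype": {
            "dom_released": spec.phen.dom_released,
            "dom_new": spec.phen.dom_new,
            "yle_male_cost": spec.phen.yle_male_cost,
            "shredder_male_cost": spec.phen.shredder_male_cost,
            "sterile_males": spec.phen.sterile_males,
            "lethality": spec.phen.lethality.value,
        },
        "demography": {"rm": spec.demography.rm, "horizon": spec.demography.horizon},
        "cage": {
            "n_wt_females": cfg.n_wt_females,
            "n_wt_males": cfg.n_wt_males,
            "n_yle_males": cfg.n_yle_males,
            "pupae_per_generation": cfg.pupae_per_generation,
            "generations": cfg.generations,
        },
    }


def generate_cage_dataset(
    spec: SyntheticSpec, space: GenotypeSpace | None = None
) -> tuple[pd.DataFrame, dict]:
    """Cage trajectory table (shared schema) plus a ground-truth sidecar.

    The sidecar records every true parameter and the seed, and
    :func:`dataset_from_sidecar` regenerates the identical table from it.
    """
    trajectories = cage_trajectories(spec, space=space)
    table = pd.concat(
        [traj.to_frame(cage_id=k) for k, traj in enumerate(trajectories, start=1)],
        ignore_index=True,
    )
    return table, _sidecar(spec)


def dataset_from_sidecar(sidecar: dict, space: GenotypeSpace | None = None) -> pd.DataFrame:
    """Regenerate a synthetic dataset exactly from its ground-truth sidecar."""
    spec = SyntheticSpec(
        seed=sidecar["seed"],
        editing=EditingParams(**sidecar["editing"]),
        phen=PhenotypeParams(
            dom_released=sidecar["phenotype"]["dom_released"],
            dom_new=sidecar["phenotype"]["dom_new"],
            yle_male_cost=sidecar["phenotype"]["yle_male_cost"],
            shredder_male_cost=sidecar["phenotype"].get("shredder_male_cost", 0.0),
            sterile_males=sidecar["phenotype"]["sterile_males"],
            lethality=Lethality(sidecar["phenotype"]["lethality"]),
        ),
        demography=DemographyParams(**sidecar["demography"]),
        cage_config=CageConfig(**sidecar["cage"]),
        n_cages=sidecar["n_cages"],
        read_depth=sidecar["read_depth"],
    )
    table, _ = generate_cage_dataset(spec, space=space)
    return table


def generate_pool_allele_table(
    spec: SyntheticSpec, trajectory: CageTrajectory, cage_id: int = 1
) -> pd.DataFrame:
    """Pooled amplicon-style allele read counts for one trajectory.

    For every recorded generation, adults are pooled and each target allele's
    read count is drawn ``Binomial(depth, true pooled frequency)``
    independently per allele.  Depth-1 sampling therefore yields frequencies
    of exactly 0 or 1.
    """
    if spec.read_depth <= 0:
        raise ValueError(f"read_depth must be positive, got {spec.read_depth}")
    rng = np.random.default_rng([int(spec.seed), int(cage_id), 7919])
    allele_counts = trajectory.target_allele_counts()
    totals = 2.0 * (
        trajectory.female_counts.sum(axis=1) + trajectory.male_counts.sum(axis=1)
    )
    rows = []
    for gen in range(trajectory.n_recorded):
        total = totals[gen]
        for allele in trajectory.space.loci.target_alleles:
            freq = allele_counts[gen, allele] / total if total > 0 else 0.0
            reads = int(rng.binomial(spec.read_depth, freq))
            rows.append(
                {
                    "cage_id": cage_id,
                    "generation": gen,
                    "allele": _ALLELE_NAMES[allele],
                    "reads": reads,
                    "depth": spec.read_depth,
                }
            )
    return pd.DataFrame(rows)[ALLELE_SCHEMA]


#: Published per-cage summary values: (cage, generation, statistic, value).
#: Only generations with a printed number appear.
_EMPIRICAL_ROWS = [
    (1, 1, "rel_wt_female", 0.57),
    (1, 1, "yle_male_freq", 0.49),
    (1, 1, "dom_r_freq", 0.22),
    (1, 3, "dom_r_freq", 0.16),
    (1, 5, "rel_wt_female", 0.86),
    (1, 5, "yle_male_freq", 0.27),
    (2, 1, "rel_wt_female", 0.59),
    (2, 1, "yle_male_freq", 0.43),
    (2, 1, "dom_r_freq", 0.22),
    (2, 3, "dom_r_freq", 0.11),
    (2, 5, "rel_wt_female", 0.87),
    (2, 5, "yle_male_freq", 0.14),
]


def empirical_fixture() -> pd.DataFrame:
    """The published two-cage summary observations as a long-format table.

    Summary-level only (``attrs['level'] == 'summary'``): the underlying full
    counts were not published, so this table cannot be expanded to the cage
    count schema.
    """
    table = pd.DataFrame(
        _EMPIRICAL_ROWS, columns=["cage_id", "generation", "statistic", "value"]
    )
    table.attrs["level"] = "summary"
    return table
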