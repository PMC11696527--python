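"""Strategy-comparison table: required release rates across suppression levels.

Builds the head-to-head comparison of self-limiting strategies: for each
(strategy, suppression level) pair, the smallest sustained per-generation
release rate that suppresses relative fertile females to the target within
the horizon, plus the ratio of that rate to the engineered YLE strain's rate
at the same level.

Rounding convention for printed comparisons: rates to 3 decimals, ratios to
1 decimal; the returned frame keeps full precision.
"""

from __future__ import annotations

import pandas as pd

from .deterministic import DemographyParams, required_release_rate
from .genetics import GenotypeSpace
from .strategies import STRATEGY_NAMES, strategy_preset

__all__ = ["run_table1", "DEFAULT_STRATEGIES"]

DEFAULT_STRATEGIES = STRATEGY_NAMES
_REFERENCE = "yle_dsx_b"


def _rate_for(name: str, level: float, demo: DemographyParams, cache: dict) -> float:
    key = (name, level)
    if key not in cache:
        preset = strategy_preset(name)
        space = GenotypeSpace(preset.loci)
        cache[key] = required_release_rate(
            space, preset.editing, preset.phen, demo, preset.released, level
        )
    return cache[key]


def run_table1(
    strategies=DEFAULT_STRATEGIES,
    suppression_levels=(0.95, 0.99),
    rm: float = 6.0,
    horizon: int = 36,
) -> pd.DataFrame:
    """One row per (strategy, suppression level) with the required rate and
    its ratio to the ``yle_dsx_b`` reference rate at the same level.

    The reference rate is computed even when ``yle_dsx_b`` is not among the
    requested strategies, so a single-strategy table still carries a
    meaningful ratio column.
    """
    demo = DemographyParams(rm=rm, horizon=horizon)
    cache: dict = {}
    rows = []
    for level in suppression_levels:
        ref = _rate_for(_REFERENCE, level, demo, cache)
        for name in strategies:
            rate = _rate_for(name, level, demo, cache)
            rows.append(
                {
                    "strategy": name,
                    "suppression_level": level,
                    "release_rate": rate,
                    "ratio_to_yle_dsx_b": rate / ref if ref > 0 else float("nan"),
                }
            )
    return pd.DataFrame(rows)
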