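"""Flat key-value configuration parsing, validation, and run manifests.

Configurations are flat mappings (YAML files on disk) whose keys are exactly
the parameter field names of the model bundles.  Validation range-checks all
probabilities, fills defaults from the engineered-strain baseline, and
rejects unknown keys.  Every CLI run that writes an output also writes a
manifest (tool version, fully resolved parameters, seeds, input digests,
timestamp); feeding a manifest's parameter block back through validation
reproduces the identical resolved bundle.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .cage import CageConfig
from .deterministic import DemographyParams
from .genetics import EditingParams, Lethality, PhenotypeParams

__all__ = [
    "ConfigError",
    "ResolvedConfig",
    "validate_config",
    "load_config",
    "RunManifest",
    "file_digest",
]


class ConfigError(ValueError):
    """A configuration problem, with a message naming the offending key."""


_PROB_KEYS = {
    "cleave_het",
    "nhej_given_cleave",
    "p_dom_new",
    "mut_wtwt",
    "shred_eff",
    "dom_released",
    "dom_new",
    "yle_male_cost",
    "shredder_male_cost",
}
_EDITING_KEYS = {"cleave_het", "nhej_given_cleave", "p_dom_new", "mut_wtwt", "shred_eff"}
_PHEN_KEYS = {
    "dom_released",
    "dom_new",
    "yle_male_cost",
    "shredder_male_cost",
    "sterile_males",
    "lethality",
}
_DEMO_KEYS = {"rm", "horizon"}
_CAGE_KEYS = {
    "n_wt_females",
    "n_wt_males",
    "n_yle_males",
    "pupae_per_generation",
    "generations",
}
_RELEASE_KEYS = {"release_rate", "duration", "single_release"}
_MISC_KEYS = {"seed"}
_KNOWN_KEYS = _EDITING_KEYS | _PHEN_KEYS | _DEMO_KEYS | _CAGE_KEYS | _RELEASE_KEYS | _MISC_KEYS


@dataclass(frozen=True)
class ResolvedConfig:
    """A fully resolved parameter bundle (defaults filled, ranges checked)."""

    editing: EditingParams
    phen: PhenotypeParams
    demography: DemographyParams
    cage: CageConfig
    release_rate: float = 0.0
    duration: int | None = None
    single_release: bool = False
    seed: int | None = None

    def to_dict(self) -> dict:
        """Flat key-value form; round-trips through :func:`validate_config`."""
        out: dict = {}
        for key in sorted(_EDITING_KEYS):
            out[key] = getattr(self.editing, key)
        for key in ("dom_released", "dom_new", "yle_male_cost", "shredder_male_cost", "sterile_males"):
            out[key] = getattr(self.phen, key)
        out["lethality"] = self.phen.lethality.value
        out["rm"] = self.demography.rm
        out["horizon"] = self.demography.horizon
        for key in sorted(_CAGE_KEYS):
            out[key] = getattr(self.cage, key)
        out["release_rate"] = self.release_rate
        out["duration"] = self.duration
        out["single_release"] = self.single_release
        out["seed"] = self.seed
        return out


def validate_config(raw: dict | None, require_seed: bool = False) -> ResolvedConfig:
    """Resolve a flat configuration mapping against the baseline defaults.

    Raises :class:`ConfigError` with a distinct message for an unknown key,
    an out-of-range probability, or a missing seed when one is required.
    An empty configuration yields the full engineered-strain baseline bundle.
    """
    raw = dict(raw or {})
    for key in raw:
        if key not in _KNOWN_KEYS:
            raise ConfigError(f"unknown configuration key: {key!r}")
    for key in _PROB_KEYS & raw.keys():
        value = raw[key]
        if value is None or not 0.0 <= float(value) <= 1.0:
            raise ConfigError(f"{key} must lie in [0, 1], got {value}")

    def pick(keys):
        return {k: raw[k] for k in keys if k in raw and raw[k] is not None}

    try:
        editing = EditingParams(**{k: float(v) for k, v in pick(_EDITING_KEYS).items()})
        phen_kwargs = pick(_PHEN_KEYS)
        if "lethality" in phen_kwargs:
            phen_kwargs["lethality"] = Lethality(phen_kwargs["lethality"])
        phen = PhenotypeParams(**phen_kwargs)
        demo = DemographyParams(**pick(_DEMO_KEYS))
        cage = CageConfig(**{k: int(v) for k, v in pick(_CAGE_KEYS).items()})
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc

    release_rate = float(raw.get("release_rate") or 0.0)
    if release_rate < 0:
        raise ConfigError(f"release_rate must be non-negative, got {release_rate}")
    duration = raw.get("duration")
    duration = int(duration) if duration is not None else None
    seed = raw.get("seed")
    if require_seed and seed is None:
        raise ConfigError(
            "a seed is required for stochastic commands; set 'seed' (or pass --seed)"
        )
    return ResolvedConfig(
        editing=editing,
        phen=phen,
        demography=demo,
        cage=cage,
        release_rate=release_rate,
        duration=duration,
        single_release=bool(raw.get("single_release", False)),
        seed=int(seed) if seed is not None else None,
    )


def load_config(path: str | Path | None, require_seed: bool = False) -> ResolvedConfig:
    """Read a flat YAML configuration file and validate it."""
    raw = None
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"configuration file {path} must hold a flat mapping")
    return validate_config(raw, require_seed=require_seed)


def file_digest(path: str | Path) -> str:
    """SHA-256 digest of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written alongside every CLI output."""

    command: str
    parameters: dict
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)
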